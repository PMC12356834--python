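"""Readers and writers for the three input formats and the result tables.

Input formats: multi-sample VCF 4.2 (GT/DP/AD), tab-separated sample sheet,
tab-separated annotation table.  Results are written as TSV with
full-precision floats so that ``read_results(write_results(x)) == x``.
"""

from __future__ import annotations

import gzip
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    CONSEQUENCES,
    AnnotationRecord,
    GeneBurdenResult,
    GenotypeMatrix,
    SampleRecord,
    StratumTable,
    VariantRecord,
)

_CONSEQUENCE_ALIASES = {
    "stop_gained": "stop_gained",
    "stopgain": "stop_gained",
    "start_lost": "start_lost",
    "start_loss": "start_lost",
    "startloss": "start_lost",
    "frameshift": "frameshift",
    "frameshift_variant": "frameshift",
    "splice_canonical": "splice_canonical",
    "splice_acceptor": "splice_canonical",
    "splice_donor": "splice_canonical",
    "missense": "missense",
    "missense_variant": "missense",
    "synonymous": "synonymous",
    "synonymous_variant": "synonymous",
    "other": "other",
}


def normalize_consequence(raw: str) -> str:
    key = raw.strip().lower()
    if key not in _CONSEQUENCE_ALIASES:
        raise ValueError(f"unrecognized consequence class: {raw!r}")
    return _CONSEQUENCE_ALIASES[key]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read a multi-sample VCF, decomposing multi-allelic sites.

    Each alternate allele becomes its own :class:`VariantRecord`; siblings
    share ``parent_site_id``.  Dosage comes from GT (unphased counting; a
    genotype with any missing allele is treated as MISSING), depth from DP
    (falling back to the AD sum), and the alternate-read fraction from AD.
    """
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib reports the offending line
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    n = len(sample_ids)

    variants: list[VariantRecord] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    ab_cols: list[np.ndarray] = []

    for site in vcf:
        parent = f"{site.CHROM}:{site.POS}:{site.REF}"
        genos = site.genotypes  # list of [allele1, allele2, ..., phased]
        try:
            ad = site.format("AD")
        except KeyError:
            ad = None
        try:
            dp = site.format("DP")
            dp = None if dp is None else dp.reshape(n).astype(np.int64)
        except KeyError:
            dp = None
        if dp is None and ad is not None:
            dp = np.where(ad < 0, 0, ad).sum(axis=1).astype(np.int64)
        ad_total = None
        if ad is not None:
            ad_clip = np.where(ad < 0, 0, ad)
            ad_total = ad_clip.sum(axis=1).astype(np.float64)

        for j, alt in enumerate(site.ALT, start=1):
            vid = f"{site.CHROM}:{site.POS}:{site.REF}:{alt}"
            vqslod = site.INFO.get("VQSLOD")
            variants.append(
                VariantRecord(
                    chrom=site.CHROM,
                    pos=site.POS,
                    ref=site.REF,
                    alt=alt,
                    variant_id=vid,
                    parent_site_id=parent,
                    vqslod=float(vqslod) if vqslod is not None else None,
                )
            )
            dos = np.empty(n, dtype=np.int8)
            for i, g in enumerate(genos):
                alleles = g[:-1]
                if any(a < 0 for a in alleles):
                    dos[i] = MISSING
                else:
                    dos[i] = sum(1 for a in alleles if a == j)
            dosage_cols.append(dos)
            dcol = (
                dp.copy()
                if dp is not None
                else np.full(n, -1, dtype=np.int64)
            )
            dcol[dcol < 0] = -1 if dp is None else 0
            depth_cols.append(np.where(dcol < 0, 0, dcol))
            if ad_total is not None:
                with np.errstate(invalid="ignore", divide="ignore"):
                    frac = np.where(
                        ad_total > 0, ad_clip[:, j] / ad_total, np.nan
                    )
                frac = np.where(dos == MISSING, np.nan, frac)
            else:
                frac = np.full(n, np.nan)
            ab_cols.append(frac)

    if variants:
        dosage = np.column_stack(dosage_cols)
        depth = np.column_stack(depth_cols)
        ab = np.column_stack(ab_cols)
    else:
        dosage = np.zeros((n, 0), dtype=np.int8)
        depth = np.zeros((n, 0), dtype=np.int32)
        ab = np.zeros((n, 0))
    gm = GenotypeMatrix(
        dosage, depth, ab, sample_ids, [v.variant_id for v in variants]
    )
    return variants, gm


def write_vcf(
    path: str,
    sites: Sequence[dict],
    sample_ids: Sequence[str],
) -> None:
    """Write a plain-text VCF 4.2 with GT/DP/AD.

    ``sites`` entries carry chrom, pos, ref, alts (list), and per-sample
    arrays: gt (n x 2 allele indices, -1 = missing), dp (n,), ad (n x
    (1+len(alts))).
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        contigs = []
        for s in sites:
            if s["chrom"] not in contigs:
                contigs.append(s["chrom"])
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for s in sorted(sites, key=lambda s: (contigs.index(s["chrom"]), s["pos"])):
            alts = ",".join(s["alts"])
            row = [
                s["chrom"],
                str(s["pos"]),
                s.get("id", "."),
                s["ref"],
                alts,
                ".",
                "PASS",
                ".",
                "GT:DP:AD",
            ]
            gt = s["gt"]
            dp = s["dp"]
            ad = s["ad"]
            for i in range(len(sample_ids)):
                a1, a2 = gt[i]
                gts = (
                    "./."
                    if a1 < 0 or a2 < 0
                    else f"{a1}/{a2}"
                )
                ads = ",".join(str(int(x)) for x in ad[i])
                row.append(f"{gts}:{int(dp[i])}:{ads}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def read_samples(path: str) -> list[SampleRecord]:
    """Read the tab-separated sample sheet.

    Required columns: sample_id, stratum, sex, phenotype.  Optional metric
    columns (frac_bases_20x, call_rate, ...) are loaded when present.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "stratum", "sex", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    dupes = df["sample_id"][df["sample_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
    bad = df[~df["phenotype"].isin(("control", "PACG_chronic", "APAC"))]
    if len(bad):
        raise ValueError(
            "unknown phenotype labels at rows "
            f"{list(bad.index)}: {sorted(set(bad['phenotype']))}"
        )
    records = []
    for _, row in df.iterrows():
        kw = {}
        for col in ("frac_bases_20x", "call_rate"):
            if col in df.columns and pd.notna(row[col]):
                kw[col] = float(row[col])
        for col in ("n_het", "n_singletons", "exome_variant_count"):
            if col in df.columns and pd.notna(row[col]):
                kw[col] = int(row[col])
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                stratum=str(row["stratum"]),
                sex=str(row["sex"]),
                phenotype=str(row["phenotype"]),
                **kw,
            )
        )
    return records


def write_samples(samples: Iterable[SampleRecord], path: str) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "stratum": s.stratum,
                "sex": s.sex,
                "phenotype": s.phenotype,
                "frac_bases_20x": s.frac_bases_20x,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(
    path: str, known_variant_ids: Optional[set] = None
) -> list[AnnotationRecord]:
    """Read the tab-separated annotation table.

    Columns: variant_id, gene, consequence, cadd_scaled ('.' or empty for
    absent); any column named ``af_<group>`` becomes an external per-group
    allele frequency.  Missense records lacking a CADD score are kept but
    warned about — they can never qualify.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene": str})
    required = {"variant_id", "gene", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    records = []
    for idx, row in df.iterrows():
        csq = normalize_consequence(str(row["consequence"]))
        cadd = None
        if "cadd_scaled" in df.columns:
            raw = row["cadd_scaled"]
            if pd.notna(raw) and str(raw).strip() not in (".", ""):
                cadd = float(raw)
        if csq == "missense" and cadd is None:
            warnings.warn(
                f"missense record without CADD at row {idx} "
                f"({row['variant_id']}); it will never qualify",
                stacklevel=2,
            )
        ext = None
        if af_cols:
            ext = {
                c[3:]: float(row[c]) for c in af_cols if pd.notna(row[c])
            } or None
        known = (
            known_variant_ids is None
            or str(row["variant_id"]) in known_variant_ids
        )
        records.append(
            AnnotationRecord(
                variant_id=str(row["variant_id"]),
                gene=str(row["gene"]),
                consequence=csq,
                cadd_scaled=cadd,
                external_group_afs=ext,
                known_variant=known,
            )
        )
    return records


def write_annotations(annotations: Iterable[AnnotationRecord], path: str) -> None:
    rows = []
    af_groups: list[str] = []
    anns = list(annotations)
    for a in anns:
        if a.external_group_afs:
            for g in a.external_group_afs:
                if g not in af_groups:
                    af_groups.append(g)
    for a in anns:
        row = {
            "variant_id": a.variant_id,
            "gene": a.gene,
            "consequence": a.consequence,
            "cadd_scaled": "." if a.cadd_scaled is None else repr(a.cadd_scaled),
        }
        for g in af_groups:
            row[f"af_{g}"] = (
                (a.external_group_afs or {}).get(g, np.nan)
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float) and np.isnan(x):
        return "NA"
    return f"{x:.17g}"


def _parse_float(tok: str):
    if tok == "NA":
        return None
    return float(tok)


RESULT_COLUMNS = [
    "gene",
    "or_mh",
    "ci95_low",
    "ci95_high",
    "statistic",
    "p_cmh",
    "p_adjusted",
    "exome_wide_significant",
    "strata",
]


def write_results(results: Sequence[GeneBurdenResult], path: str) -> None:
    """Write per-gene results as TSV; strata cells packed per stratum as
    ``label:a/b/c/d`` joined by ``;``.  Floats keep full precision."""
    if not results:
        raise ValueError("no results to write")
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            strata = ";".join(
                f"{t.stratum}:{t.a}/{t.b}/{t.c}/{t.d}" for t in r.strata
            )
            fh.write(
                "\t".join(
                    [
                        r.gene,
                        _fmt(r.or_mh),
                        _fmt(r.ci95[0]),
                        _fmt(r.ci95[1]),
                        _fmt(r.statistic),
                        _fmt(r.p_cmh),
                        _fmt(r.p_adjusted),
                        "1" if r.exome_wide_significant else "0",
                        strata,
                    ]
                )
                + "\n"
            )


def read_results(path: str) -> list[GeneBurdenResult]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != RESULT_COLUMNS:
            raise ValueError(f"unexpected results header: {header}")
        for line in fh:
            toks = line.rstrip("\n").split("\t")
            strata = []
            if toks[8]:
                for chunk in toks[8].split(";"):
                    label, cells = chunk.rsplit(":", 1)
                    a, b, c, d = (int(x) for x in cells.split("/"))
                    strata.append(StratumTable(label, a, b, c, d))
            def fl(tok):
                v = _parse_float(tok)
                return float("nan") if v is None else v
            out.append(
                GeneBurdenResult(
                    gene=toks[0],
                    strata=strata,
                    or_mh=fl(toks[1]),
                    ci95=(fl(toks[2]), fl(toks[3])),
                    statistic=fl(toks[4]),
                    p_cmh=fl(toks[5]),
                    p_adjusted=_parse_float(toks[6]),
                    exome_wide_significant=toks[7] == "1",
                )
            )
    return out
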