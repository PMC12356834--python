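"""Synthetic multi-cohort case-control exome generator.

Emulates the statistical structure the collapsing analysis assumes:
stratified case-control cohorts, rare-skewed site-frequency spectra,
consequence/CADD annotations, sequencing artifacts (per-call depth,
binomial allelic-balance noise, missingness with optional batch offsets),
ancestry gradients in a common-variant block, and spiked risk genes with a
configurable control carrier burden and odds ratio.

All randomness flows from one integer seed through a single generator
stream: identical seed and config give byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import write_annotations, write_samples, write_vcf
from .model import MISSING, AnnotationRecord, SampleRecord

#: Discovery-style strata: four recruitment countries totalling
#: 4,667 cases and 5,473 controls.
DISCOVERY_STRATA = [
    ("SG", 1167, 1369),
    ("HK", 1167, 1368),
    ("JP", 1167, 1368),
    ("VN", 1166, 1368),
]

DEFAULT_CONSEQUENCE_PROBS = {
    "missense": 0.55,
    "synonymous": 0.25,
    "stop_gained": 0.04,
    "frameshift": 0.04,
    "splice_canonical": 0.03,
    "start_lost": 0.01,
    "other": 0.08,
}

#: Per-consequence CADD scaled-score law: (mean, sd), clipped at 0.
DEFAULT_CADD_LAW = {
    "missense": (15.0, 6.0),
    "stop_gained": (35.0, 8.0),
    "frameshift": (33.0, 8.0),
    "splice_canonical": (28.0, 8.0),
    "start_lost": (24.0, 8.0),
    "synonymous": (5.0, 4.0),
    "other": (8.0, 5.0),
}


@dataclass
class RiskGeneSpec:
    """A spiked risk gene: cumulative qualifying-carrier frequency among
    controls and the target carrier odds ratio for case status."""

    gene: str
    control_carrier_freq: float = 0.01
    odds_ratio: float = 2.0
    per_stratum_or: Optional[dict] = None

    def __post_init__(self) -> None:
        if not (0 < self.control_carrier_freq < 1):
            raise ValueError("control_carrier_freq must lie in (0,1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")


@dataclass
class ArtifactSpec:
    """Sequencing-artifact model: depth law, read-level noise, missingness."""

    depth_mean: float = 60.0
    base_error: float = 0.01  # per-read miscall rate for homozygous calls
    base_missingness: float = 0.002
    stratum_missingness_offsets: dict = field(default_factory=dict)
    phenotype_missingness_offsets: dict = field(default_factory=dict)


@dataclass
class SimulationConfig:
    seed: int = 0
    strata_spec: list = field(default_factory=lambda: list(DISCOVERY_STRATA))
    n_genes: int = 200
    variants_per_gene: float = 8.0
    af_beta: tuple = (0.2, 200.0)  # rare-skewed Beta law for rare-variant AFs
    af_truncate: float = 0.05
    consequence_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_PROBS)
    )
    cadd_law: dict = field(default_factory=lambda: dict(DEFAULT_CADD_LAW))
    risk_genes: list = field(default_factory=list)
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    ancestry_gradient: float = 0.05  # per-stratum common-variant AF shift sd
    n_common_variants: int = 2000
    common_af_range: tuple = (0.05, 0.5)
    ld_duplicate_frac: float = 0.05  # common variants duplicated w/ copy noise
    ld_copy_noise: float = 0.02
    multiallelic_frac: float = 0.02  # rare-variant pairs merged into one site
    sex_case_fraction: float = 0.62  # fraction of cases that are female
    sex_control_fraction: float = 0.50
    apac_fraction: float = 0.31  # fraction of cases with the acute subtype
    n_duplicate_samples: int = 0  # injected duplicates (sample-QC fixture)
    n_low_coverage_samples: int = 0

    def __post_init__(self) -> None:
        total = sum(self.consequence_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("consequence probabilities must sum to 1")
        for spec in self.risk_genes:
            p = case_carrier_prob(
                spec.control_carrier_freq, spec.odds_ratio
            )
            if p >= 1:
                raise ValueError(
                    f"implied case carrier probability >= 1 for {spec.gene}"
                )


def case_carrier_prob(q: float, odds_ratio: float) -> float:
    """Exact odds transform: case carrier probability implied by control
    carrier frequency q and carrier odds ratio."""
    return odds_ratio * q / (1.0 - q + odds_ratio * q)


def carrier_freq_from_afs(afs: Sequence[float]) -> float:
    """Cumulative carrier frequency of independent variants under HWE:
    1 - prod((1 - af)^2)."""
    prod = 1.0
    for af in afs:
        if not (0.0 <= af <= 1.0):
            raise ValueError(f"allele frequency out of [0,1]: {af}")
        prod *= (1.0 - af) ** 2
    return 1.0 - prod


def simulate_carrier_tables(
    strata_spec: Sequence[tuple],
    q: float,
    odds_ratio: float,
    rng: np.random.Generator,
    n_reps: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-stratum carrier 2x2 tables under the generative model.

    Returns arrays a, b, c, d of shape (n_reps, n_strata): case carriers,
    case non-carriers, control carriers, control non-carriers.  Shared by
    the power simulator and parameter-recovery studies.
    """
    p1 = case_carrier_prob(q, odds_ratio)
    n_cases = np.array([s[1] for s in strata_spec])
    n_controls = np.array([s[2] for s in strata_spec])
    a = rng.binomial(n_cases, p1, size=(n_reps, len(strata_spec)))
    c = rng.binomial(n_controls, q, size=(n_reps, len(strata_spec)))
    return a, n_cases - a, c, n_controls - c


# ---------------------------------------------------------------------------
# Full study simulation
# ---------------------------------------------------------------------------

def _make_samples(config: SimulationConfig, rng: np.random.Generator
                  ) -> list[SampleRecord]:
    samples = []
    for label, n_cases, n_controls in config.strata_spec:
        for i in range(n_cases):
            sex = "female" if rng.random() < config.sex_case_fraction \
                else "male"
            pheno = "APAC" if rng.random() < config.apac_fraction \
                else "PACG_chronic"
            samples.append(SampleRecord(
                sample_id=f"{label}_case{i:05d}", stratum=label, sex=sex,
                phenotype=pheno,
                frac_bases_20x=float(rng.uniform(0.90, 0.995)),
            ))
        for i in range(n_controls):
            sex = "female" if rng.random() < config.sex_control_fraction \
                else "male"
            samples.append(SampleRecord(
                sample_id=f"{label}_ctrl{i:05d}", stratum=label, sex=sex,
                phenotype="control",
                frac_bases_20x=float(rng.uniform(0.90, 0.995)),
            ))
    if config.n_low_coverage_samples:
        idx = rng.choice(len(samples), config.n_low_coverage_samples,
                         replace=False)
        for i in idx:
            samples[i].frac_bases_20x = float(rng.uniform(0.5, 0.79))
    return samples


def _simulate_rare_block(config, samples, rng):
    """Per-gene rare variants: AFs, consequences, CADD, dosages.

    Risk genes get exact carrier sampling (controls at q, cases at the
    transformed odds) with carriers assigned one qualifying risk variant;
    decoy non-qualifying variants are drawn independently of phenotype.
    Returns (variant table rows, dosage matrix columns, truth rows).
    """
    n = len(samples)
    is_case = np.array([s.is_case for s in samples])
    strata = np.array([s.stratum for s in samples])
    risk_by_gene = {r.gene: r for r in config.risk_genes}

    gene_names = [r.gene for r in config.risk_genes]
    filler = config.n_genes - len(gene_names)
    gene_names += [f"GENE{i:04d}" for i in range(max(filler, 0))]

    csq_names = list(config.consequence_probs)
    csq_p = np.array([config.consequence_probs[c] for c in csq_names])

    var_rows = []  # dict per variant: gene, consequence, cadd, af
    dosage_cols = []
    truth_rows = []

    for gene in gene_names:
        n_var = 1 + rng.poisson(max(config.variants_per_gene - 1.0, 0.0))
        afs = rng.beta(*config.af_beta, size=n_var)
        afs = np.minimum(afs, config.af_truncate)
        afs = np.maximum(afs, 1e-5)
        csqs = [csq_names[k] for k in rng.choice(
            len(csq_names), size=n_var, p=csq_p)]
        cadds = []
        for csq in csqs:
            mu, sd = config.cadd_law[csq]
            cadds.append(max(float(rng.normal(mu, sd)), 0.0))

        spec = risk_by_gene.get(gene)
        if spec is not None:
            # guarantee a block of qualifying risk variants
            n_risk = max(2, n_var // 2)
            for k in range(n_risk):
                if rng.random() < 0.2:
                    csqs[k] = "stop_gained"
                    cadds[k] = max(float(rng.normal(35.0, 8.0)), 15.0)
                else:
                    csqs[k] = "missense"
                    cadds[k] = float(rng.uniform(15.0, 40.0))
            risk_weights = afs[:n_risk] / afs[:n_risk].sum()
            dos = np.zeros((n, n_var), dtype=np.int8)
            for label, _, _ in config.strata_spec:
                or_s = (spec.per_stratum_or or {}).get(
                    label, spec.odds_ratio)
                q = spec.control_carrier_freq
                p1 = case_carrier_prob(q, or_s)
                in_stratum = strata == label
                p_vec = np.where(is_case[in_stratum], p1, q)
                carrier = rng.random(in_stratum.sum()) < p_vec
                which = rng.choice(n_risk, size=int(carrier.sum()),
                                   p=risk_weights)
                rows = np.flatnonzero(in_stratum)[carrier]
                dos[rows, which] = 1
                truth_rows.append(
                    {"gene": gene, "stratum": label, "q_control": q,
                     "odds_ratio": or_s}
                )
            # decoys beyond the risk block: guaranteed non-qualifying
            # (synonymous / low-CADD missense / other), HWE,
            # phenotype-independent — they exercise the selector without
            # perturbing the spiked carrier frequency
            for k in range(n_risk, n_var):
                u = rng.random()
                if u < 0.5:
                    csqs[k] = "synonymous"
                    cadds[k] = max(float(rng.normal(5.0, 3.0)), 0.0)
                elif u < 0.8:
                    csqs[k] = "missense"
                    cadds[k] = float(rng.uniform(0.0, 9.5))
                else:
                    csqs[k] = "other"
                    cadds[k] = max(float(rng.normal(8.0, 5.0)), 0.0)
                dos[:, k] = rng.binomial(2, afs[k], size=n)
        else:
            dos = rng.binomial(2, afs[None, :], size=(n, n_var)).astype(
                np.int8)
            q_null = carrier_freq_from_afs(afs)
            for label, _, _ in config.strata_spec:
                truth_rows.append(
                    {"gene": gene, "stratum": label, "q_control": q_null,
                     "odds_ratio": 1.0}
                )

        for k in range(n_var):
            var_rows.append({
                "gene": gene, "consequence": csqs[k],
                "cadd": cadds[k], "af": float(afs[k]),
            })
            dosage_cols.append(dos[:, k])
    return var_rows, dosage_cols, truth_rows


def _simulate_common_block(config, samples, rng):
    """Ancestry-informative common variants with per-stratum AF shifts and
    optional duplicated (high-LD) copies."""
    n = len(samples)
    strata = np.array([s.stratum for s in samples])
    labels = [s[0] for s in config.strata_spec]
    m = config.n_common_variants
    base = rng.uniform(*config.common_af_range, size=m)
    shift = rng.normal(0.0, 1.0, size=(len(labels), m))
    dos = np.zeros((n, m), dtype=np.int8)
    for li, lab in enumerate(labels):
        af = np.clip(
            base + config.ancestry_gradient * shift[li], 0.01, 0.99)
        mask = strata == lab
        dos[mask] = rng.binomial(2, af[None, :],
                                 size=(int(mask.sum()), m)).astype(np.int8)
    # LD: duplicate a fraction of columns with copy noise
    n_dup = int(round(config.ld_duplicate_frac * m))
    dup_src = rng.choice(m, size=n_dup, replace=False) if n_dup else []
    dup_cols = []
    for j in dup_src:
        col = dos[:, j].copy()
        flip = rng.random(n) < config.ld_copy_noise
        col[flip] = rng.binomial(2, 0.3, size=int(flip.sum()))
        dup_cols.append(col)
    if dup_cols:
        dos = np.column_stack([dos] + dup_cols)
    return dos


def _apply_artifacts(dosage, strata, phenotypes, spec, rng):
    """Depth, allelic-balance noise and missingness for every call.

    Returns (dosage with missingness, depth, alt_fraction) arrays.
    """
    n, m = dosage.shape
    depth = rng.poisson(spec.depth_mean, size=(n, m)).astype(np.int32)
    alt_reads = np.zeros((n, m), dtype=np.int64)
    hom_ref = dosage == 0
    het = dosage == 1
    hom_alt = dosage == 2
    alt_reads[hom_ref] = rng.binomial(depth[hom_ref], spec.base_error)
    alt_reads[het] = rng.binomial(depth[het], 0.5)
    alt_reads[hom_alt] = depth[hom_alt] - rng.binomial(
        depth[hom_alt], spec.base_error)
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(depth > 0, alt_reads / np.maximum(depth, 1), np.nan)

    miss_p = np.full(n, spec.base_missingness)
    for lab, off in spec.stratum_missingness_offsets.items():
        miss_p[strata == lab] += off
    for ph, off in spec.phenotype_missingness_offsets.items():
        miss_p[phenotypes == ph] += off
    if np.any(miss_p > 1):
        raise ValueError("total missingness probability exceeds 1")
    miss = rng.random((n, m)) < miss_p[:, None]
    out = dosage.copy()
    out[miss] = MISSING
    ab = np.where(miss, np.nan, ab)
    return out, depth, alt_reads, ab


def inject_batch_missingness(
    dosage: np.ndarray,
    labels: np.ndarray,
    offsets: dict,
    rng: np.random.Generator,
) -> np.ndarray:
    """Return a copy of ``dosage`` with extra missingness applied to the
    rows whose label appears in ``offsets`` (batch-artifact fixture)."""
    out = np.asarray(dosage).copy()
    labels = np.asarray(labels)
    for lab, off in offsets.items():
        if not (0 <= off <= 1):
            raise ValueError(f"offset for {lab} outside [0,1]")
        mask = labels == lab
        hit = rng.random((int(mask.sum()), out.shape[1])) < off
        rows = np.flatnonzero(mask)
        sub = out[rows]
        sub[hit] = MISSING
        out[rows] = sub
    return out


def simulate_study(config: SimulationConfig, out_dir: str
                   ) -> dict[str, str]:
    """Generate a full synthetic study and write the pipeline inputs.

    Writes vcf, annotations (TSV), sample sheet (TSV) and a truth table
    (gene, stratum, q_control, odds_ratio) into ``out_dir``; returns the
    four paths.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    samples = _make_samples(config, rng)
    var_rows, dosage_cols, truth_rows = _simulate_rare_block(
        config, samples, rng)
    rare_dos = np.column_stack(dosage_cols) if dosage_cols else \
        np.zeros((len(samples), 0), dtype=np.int8)
    common_dos = _simulate_common_block(config, samples, rng)

    n_rare = rare_dos.shape[1]
    all_dos = np.column_stack([rare_dos, common_dos])
    strata = np.array([s.stratum for s in samples])
    phenos = np.array([s.phenotype for s in samples])
    all_dos, depth, alt_reads, ab = _apply_artifacts(
        all_dos, strata, phenos, config.artifact_spec, rng)

    # --- optional duplicated samples (relatedness fixture) ---------------
    if config.n_duplicate_samples:
        src = rng.choice(len(samples), config.n_duplicate_samples,
                         replace=False)
        for si in src:
            s = samples[si]
            samples.append(SampleRecord(
                sample_id=s.sample_id + "_dup", stratum=s.stratum,
                sex=s.sex, phenotype=s.phenotype,
                frac_bases_20x=s.frac_bases_20x,
            ))
        all_dos = np.vstack([all_dos, all_dos[src]])
        depth = np.vstack([depth, depth[src]])
        alt_reads = np.vstack([alt_reads, alt_reads[src]])
        ab = np.vstack([ab, ab[src]])

    # --- lay variants out as VCF sites -----------------------------------
    bases = ["A", "C", "G", "T"]
    sites = []
    ann_records = []
    j = 0
    pos = 1000
    while j < n_rare:
        chrom = "chr1"
        ref = bases[int(rng.integers(4))]
        # merge a small fraction of adjacent rare-variant pairs into one
        # multi-allelic site (exercises the decomposition path)
        take_two = (
            j + 1 < n_rare
            and var_rows[j]["gene"] == var_rows[j + 1]["gene"]
            and rng.random() < config.multiallelic_frac
        )
        idxs = [j, j + 1] if take_two else [j]
        alts = []
        for _k, _ in enumerate(idxs):
            alt = bases[int(rng.integers(4))]
            while alt == ref or alt in alts:
                alt = bases[(bases.index(alt) + 1) % 4]
            alts.append(alt)
        sites.append(_build_site(chrom, pos, ref, alts,
                                 [all_dos[:, i] for i in idxs],
                                 depth[:, idxs[0]], alt_reads, idxs))
        for k, i in enumerate(idxs):
            vid = f"{chrom}:{pos}:{ref}:{alts[k]}"
            ann_records.append(AnnotationRecord(
                variant_id=vid, gene=var_rows[i]["gene"],
                consequence=var_rows[i]["consequence"],
                cadd_scaled=round(var_rows[i]["cadd"], 3),
            ))
        pos += 10
        j += len(idxs)
    pos = 1000
    for jj in range(n_rare, all_dos.shape[1]):
        chrom = "chr2"
        ref, alt = "A", "G"
        sites.append(_build_site(chrom, pos, ref, [alt],
                                 [all_dos[:, jj]], depth[:, jj],
                                 alt_reads, [jj]))
        pos += 10

    sample_ids = [s.sample_id for s in samples]
    paths = {
        "vcf": str(out / "study.vcf"),
        "annotations": str(out / "annotations.tsv"),
        "samples": str(out / "samples.tsv"),
        "truth": str(out / "truth.tsv"),
    }
    write_vcf(paths["vcf"], sites, sample_ids)
    write_annotations(ann_records, paths["annotations"])
    write_samples(samples, paths["samples"])
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def _build_site(chrom, pos, ref, alts, dos_cols, site_depth, alt_reads,
                col_idx):
    """Assemble one VCF site dict from decomposed per-alt dosage columns."""
    n = len(dos_cols[0])
    gt = np.zeros((n, 2), dtype=np.int64)
    ad = np.zeros((n, 1 + len(alts)), dtype=np.int64)
    dp = site_depth.astype(np.int64).copy()
    for i in range(n):
        alleles = []
        missing = False
        for k, col in enumerate(dos_cols):
            d = col[i]
            if d == MISSING:
                missing = True
                break
            alleles.extend([k + 1] * int(d))
        if missing:
            gt[i] = (-1, -1)
            ad[i] = 0
            continue
        alleles = alleles[:2]
        while len(alleles) < 2:
            alleles.insert(0, 0)
        gt[i] = tuple(sorted(alleles))
        # per-allele read depths from the simulated alt read counts
        total = int(dp[i])
        alt_depths = []
        for k in range(len(alts)):
            ar = int(alt_reads[i, col_idx[k]]) if k < len(col_idx) else 0
            alt_depths.append(min(ar, total))
        ad[i, 1:] = alt_depths
        ad[i, 0] = max(total - sum(alt_depths), 0)
    return {"chrom": chrom, "pos": pos, "ref": ref, "alts": alts,
            "gt": gt, "dp": dp, "ad": ad}
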