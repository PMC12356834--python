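"""Qualifying-variant selection and per-gene dominant collapsing.

A variant qualifies when it is rare (MAF < 1% in every ancestry group) and
either protein-truncating or a missense with CADD scaled score > 10 (both
thresholds strict).  Collapsing is dominant: a sample is a carrier for a
gene if it carries >= 1 alternate allele at >= 1 qualifying variant of that
gene.  A sample whose calls are missing at ALL of a gene's qualifying
variants is UNKNOWN for that gene and excluded from its tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    MISSING,
    PTV_CLASSES,
    AnnotationRecord,
    GenotypeMatrix,
    SampleRecord,
    StratumTable,
)

#: Carrier-matrix cell states.
NON_CARRIER, CARRIER, UNKNOWN = 0, 1, -1


@dataclass
class QualifyingRule:
    """Thresholds defining a qualifying variant (all strict as written)."""

    maf_max: float = 0.01
    ptv_classes: frozenset = PTV_CLASSES
    cadd_min: float = 10.0
    use_external_afs: bool = True


@dataclass
class CarrierMatrix:
    """Genes x samples carrier indicators plus per-gene contributing
    qualifying variant ids.  Cells are CARRIER, NON_CARRIER or UNKNOWN."""

    genes: list
    sample_ids: list
    status: np.ndarray  # int8 genes x samples
    gene_variants: dict = field(default_factory=dict)

    def carrier_status(self, gene: str) -> dict:
        """Per-sample carrier flag for one gene: True/False, None if UNKNOWN."""
        gi = self.genes.index(gene)
        out = {}
        for j, sid in enumerate(self.sample_ids):
            v = self.status[gi, j]
            out[sid] = None if v == UNKNOWN else bool(v)
        return out


# ---------------------------------------------------------------------------
# Group minor-allele frequencies
# ---------------------------------------------------------------------------

def group_maf(
    gm: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    groups: Optional[Sequence[str]] = None,
) -> dict[str, dict[str, float]]:
    """Per-variant minor-allele frequency within each ancestry group.

    ``groups`` defaults to the sample strata (the study's ancestry groups
    are its recruitment countries).  Frequency = alt-allele count over
    2 x non-missing diploids, folded to the minor allele; NaN where a group
    has no called genotypes.
    Returns {variant_id: {group: maf}}.
    """
    by_id = {s.sample_id: s for s in samples}
    labels = np.array([by_id[sid].stratum for sid in gm.sample_ids])
    group_list = sorted(set(labels)) if groups is None else list(groups)
    out: dict[str, dict[str, float]] = {v: {} for v in gm.variant_ids}
    for g in group_list:
        mask = labels == g
        dos = gm.dosage[mask]
        called = dos != MISSING
        n_called = called.sum(axis=0)
        ac = np.where(called, dos, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = ac / (2.0 * n_called)
        maf = np.minimum(af, 1.0 - af)
        for j, vid in enumerate(gm.variant_ids):
            out[vid][g] = float(maf[j]) if n_called[j] > 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# Qualifying-variant selection
# ---------------------------------------------------------------------------

def select_qualifying(
    annotations: Sequence[AnnotationRecord],
    group_mafs: dict[str, dict[str, float]],
    rule: Optional[QualifyingRule] = None,
) -> set[str]:
    """Apply the qualifying rule; returns the set of qualifying variant ids.

    A variant qualifies iff its MAF is < ``maf_max`` in every group where it
    is defined (a variant undefined in ALL groups never qualifies), and its
    consequence is protein-truncating, or missense with CADD > ``cadd_min``.
    External per-group allele frequencies, when present on the annotation,
    are held to the same MAF rule.
    """
    rule = rule or QualifyingRule()
    qualifying: set[str] = set()
    for ann in annotations:
        mafs = group_mafs.get(ann.variant_id)
        if mafs is None:
            continue  # unannotated in genotypes: never qualifies
        defined = [m for m in mafs.values() if not np.isnan(m)]
        if not defined:
            continue  # undefined in all groups -> conservative fail
        if any(
            not np.isnan(m) and m >= rule.maf_max for m in mafs.values()
        ):
            continue
        if rule.use_external_afs and ann.external_group_afs:
            ext = [min(f, 1.0 - f) for f in ann.external_group_afs.values()]
            if any(f >= rule.maf_max for f in ext):
                continue
        if ann.consequence in rule.ptv_classes:
            qualifying.add(ann.variant_id)
        elif (
            ann.consequence == "missense"
            and ann.cadd_scaled is not None
            and ann.cadd_scaled > rule.cadd_min
        ):
            qualifying.add(ann.variant_id)
    return qualifying


# ---------------------------------------------------------------------------
# Dominant collapsing
# ---------------------------------------------------------------------------

def collapse_carriers(
    gm: GenotypeMatrix,
    qualifying_ids: set[str],
    gene_map: dict[str, str],
) -> CarrierMatrix:
    """Collapse qualifying variants to per-gene carrier indicators.

    ``gene_map`` maps variant_id -> gene.  Genes with zero qualifying
    variants are omitted.  Deterministic: output gene order is sorted.
    """
    genes: dict[str, list[str]] = {}
    for vid in sorted(qualifying_ids):
        if vid in gene_map and vid in gm._variant_index:
            genes.setdefault(gene_map[vid], []).append(vid)
    gene_list = sorted(genes)
    status = np.full((len(gene_list), gm.n_samples), UNKNOWN, dtype=np.int8)
    for gi, gene in enumerate(gene_list):
        cols = [gm.variant_index(v) for v in genes[gene]]
        dos = gm.dosage[:, cols]
        called = dos != MISSING
        any_called = called.any(axis=1)
        carrier = (np.where(called, dos, 0) >= 1).any(axis=1)
        status[gi, any_called] = carrier[any_called].astype(np.int8)
    return CarrierMatrix(
        genes=gene_list,
        sample_ids=list(gm.sample_ids),
        status=status,
        gene_variants=genes,
    )


def stratum_tables(
    carriers: CarrierMatrix,
    samples: Sequence[SampleRecord],
    stratify_by: str = "cohort",
) -> dict[str, list[StratumTable]]:
    """Build per-gene, per-stratum carrier 2x2 tables.

    ``stratify_by``: "cohort" (country strata), "cohort_sex" (country x
    sex), or "apac" (country strata with the case column restricted to the
    acute subtype; controls unchanged).  UNKNOWN carriers are excluded;
    strata with zero cases or zero controls are dropped.
    """
    if stratify_by not in ("cohort", "cohort_sex", "apac"):
        raise ValueError(f"unknown stratification: {stratify_by!r}")
    by_id = {s.sample_id: s for s in samples}
    order = [by_id[sid] for sid in carriers.sample_ids]

    def stratum_of(s: SampleRecord) -> Optional[str]:
        if stratify_by == "cohort_sex":
            return f"{s.stratum}|{s.sex}"
        return s.stratum

    def in_analysis(s: SampleRecord) -> bool:
        if stratify_by == "apac" and s.is_case:
            return s.phenotype == "APAC"
        return True

    labels = sorted({stratum_of(s) for s in order})
    out: dict[str, list[StratumTable]] = {}
    for gi, gene in enumerate(carriers.genes):
        tables = []
        for lab in labels:
            a = b = c = d = 0
            for j, s in enumerate(order):
                if stratum_of(s) != lab or not in_analysis(s):
                    continue
                v = carriers.status[gi, j]
                if v == UNKNOWN:
                    continue
                if s.is_case:
                    a += v == CARRIER
                    b += v == NON_CARRIER
                else:
                    c += v == CARRIER
                    d += v == NON_CARRIER
            if a + b > 0 and c + d > 0:
                tables.append(StratumTable(lab, a, b, c, d))
        out[gene] = tables
    return out


def exome_variant_count(gm: GenotypeMatrix) -> dict[str, int]:
    """Per-sample count of variants carried with dosage >= 1 (used as a
    continuous covariate in the adjusted burden model)."""
    carrier = gm.dosage >= 1  # MISSING is -1, excluded automatically
    counts = carrier.sum(axis=1)
    return {sid: int(counts[i]) for i, sid in enumerate(gm.sample_ids)}
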