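"""Core domain types for the collapsing burden analysis.

The analysis operates on three joined tables — variants, genotypes, samples —
plus per-variant functional annotations.  Genotypes are stored as dense numpy
arrays inside :class:`GenotypeMatrix`; a dosage of :data:`MISSING` (-1) marks
a no-call.  All coordinates are VCF-native (1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

#: Exome-wide significance threshold (Bonferroni-style for ~20,000 genes).
ALPHA_EXOME: float = 2.5e-6

#: Closed vocabulary of variant consequence classes.
CONSEQUENCES = (
    "stop_gained",
    "start_lost",
    "frameshift",
    "splice_canonical",
    "missense",
    "synonymous",
    "other",
)

#: Protein-truncating consequence classes (qualify irrespective of CADD).
PTV_CLASSES = frozenset(
    {"stop_gained", "start_lost", "frameshift", "splice_canonical"}
)

PHENOTYPES = ("control", "PACG_chronic", "APAC")
SEXES = ("female", "male", "unknown")


@dataclass
class VariantRecord:
    """One decomposed bi-allelic site.

    Multi-allelic VCF sites are decomposed upstream into one record per
    alternate allele; siblings share ``parent_site_id`` (``chrom:pos:ref``)
    so the "any allele fails -> exclude the whole site" QC rule can be
    applied.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: str
    parent_site_id: str
    site_filters: set = field(default_factory=set)
    vqslod: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) for {self.variant_id}")


@dataclass
class SampleRecord:
    """One study participant with QC metrics filled in as they are computed."""

    sample_id: str
    stratum: str
    sex: str
    phenotype: str
    frac_bases_20x: Optional[float] = None
    call_rate: Optional[float] = None
    n_het: Optional[int] = None
    n_singletons: Optional[int] = None
    pcs: Optional[np.ndarray] = None
    exome_variant_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"unknown phenotype {self.phenotype!r} for {self.sample_id}"
            )
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for {self.sample_id}")

    @property
    def is_case(self) -> bool:
        return self.phenotype in ("PACG_chronic", "APAC")


@dataclass
class AnnotationRecord:
    """Functional annotation linking a variant to a gene."""

    variant_id: str
    gene: str
    consequence: str
    cadd_scaled: Optional[float] = None
    external_group_afs: Optional[dict] = None
    known_variant: bool = True

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {self.consequence!r} for {self.variant_id}"
            )


class GenotypeMatrix:
    """Samples x variants diploid dosages with per-call depth and alt fraction.

    Arrays are laid out samples-by-variants.  ``dosage`` holds 0/1/2 or
    :data:`MISSING`; ``alt_fraction`` is NaN wherever undefined (missing call
    or zero depth).
    """

    def __init__(
        self,
        dosage: np.ndarray,
        depth: Optional[np.ndarray] = None,
        alt_fraction: Optional[np.ndarray] = None,
        sample_ids: Optional[list] = None,
        variant_ids: Optional[list] = None,
    ):
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x variants)")
        self.dosage = dosage
        n, m = dosage.shape
        self.depth = (
            np.asarray(depth, dtype=np.int32)
            if depth is not None
            else np.full((n, m), -1, dtype=np.int32)
        )
        self.alt_fraction = (
            np.asarray(alt_fraction, dtype=np.float64)
            if alt_fraction is not None
            else np.full((n, m), np.nan)
        )
        self.sample_ids = list(sample_ids) if sample_ids is not None else [
            f"S{i}" for i in range(n)
        ]
        self.variant_ids = list(variant_ids) if variant_ids is not None else [
            f"v{j}" for j in range(m)
        ]
        if len(self.sample_ids) != n or len(self.variant_ids) != m:
            raise ValueError("id lists do not match matrix shape")
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._variant_index = {v: j for j, v in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def variant_index(self, variant_id: str) -> int:
        return self._variant_index[variant_id]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosage.copy(),
            self.depth.copy(),
            self.alt_fraction.copy(),
            list(self.sample_ids),
            list(self.variant_ids),
        )

    def subset_variants(self, keep: list) -> "GenotypeMatrix":
        """Return a new matrix restricted to ``keep`` (variant ids, in order)."""
        idx = [self._variant_index[v] for v in keep]
        return GenotypeMatrix(
            self.dosage[:, idx],
            self.depth[:, idx],
            self.alt_fraction[:, idx],
            list(self.sample_ids),
            list(keep),
        )

    def subset_samples(self, keep: list) -> "GenotypeMatrix":
        idx = [self._sample_index[s] for s in keep]
        return GenotypeMatrix(
            self.dosage[idx, :],
            self.depth[idx, :],
            self.alt_fraction[idx, :],
            list(keep),
            list(self.variant_ids),
        )

    def call_rate_per_variant(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=0)

    def call_rate_per_sample(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=1)


@dataclass(frozen=True)
class StratumTable:
    """A carrier/non-carrier x case/control 2x2 table for one stratum.

    ``a`` = case carriers, ``b`` = case non-carriers, ``c`` = control
    carriers, ``d`` = control non-carriers.  This is the atom every
    association statistic is built from.
    """

    stratum: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    def carrier_freq_cases(self) -> float:
        return self.a / self.n_cases if self.n_cases else float("nan")

    def carrier_freq_controls(self) -> float:
        return self.c / self.n_controls if self.n_controls else float("nan")


@dataclass
class GeneBurdenResult:
    """Per-gene stratified association result."""

    gene: str
    strata: list
    or_mh: float
    ci95: tuple
    p_cmh: float
    statistic: float = float("nan")
    p_adjusted: Optional[float] = None
    exome_wide_significant: bool = False
    flags: list = field(default_factory=list)
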