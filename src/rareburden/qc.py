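"""Variant- and sample-level quality control, LD pruning and ancestry PCA.

The variant cascade runs in a fixed, logged order: depth masking, allelic-
balance masking, call-rate filter, per-stratum Hardy-Weinberg exact test,
case/control differential-missingness test, and finally the multi-allelic
sibling rule (if any decomposed allele of a site fails, the whole site
fails).  All variant filters except differential missingness are blind to
phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .model import MISSING, GenotypeMatrix, SampleRecord, VariantRecord

KINSHIP_DUPLICATE = 0.354  # 2^-1.5: monozygotic/duplicate cutoff
KINSHIP_RELATED = 0.0884  # 2^-3.5: first-degree-relative cutoff


@dataclass
class QCThresholds:
    """All QC cutoffs in one place; never hard-coded at call sites."""

    min_depth: int = 10
    min_variant_call_rate: float = 0.95
    hwe_alpha: float = 1e-4
    diff_missing_alpha: float = 1e-3
    ab_low: float = 0.20
    ab_high: float = 0.80
    min_sample_call_rate: float = 0.95
    min_frac_bases_20x: float = 0.80
    ld_r2_max: float = 0.10
    n_pcs: int = 5
    het_outlier_k: float = 4.0
    singleton_outlier_k: float = 4.0
    pca_outlier_k: float = 4.0
    kinship_duplicate: float = KINSHIP_DUPLICATE
    kinship_related: float = KINSHIP_RELATED
    vqslod_min: Optional[float] = None  # pass-through filter for real data

    def __post_init__(self) -> None:
        if not (0 < self.ab_low < self.ab_high < 1):
            raise ValueError("require 0 < ab_low < ab_high < 1")
        for alpha in (self.hwe_alpha, self.diff_missing_alpha):
            if not (0 < alpha < 1):
                raise ValueError("alphas must lie in (0,1)")


@dataclass
class QCReport:
    """Pass/fail flags with ordered failure reasons plus per-step removal
    counts, recorded in execution order."""

    variant_fail: dict = field(default_factory=dict)
    sample_fail: dict = field(default_factory=dict)
    step_counts: list = field(default_factory=list)
    masked_calls: dict = field(default_factory=dict)
    passed_variants: list = field(default_factory=list)
    passed_samples: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def log_step(self, step: str, n_removed: int) -> None:
        self.step_counts.append((step, int(n_removed)))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional Hardy-Weinberg test, two-sided.

    Conditions on the diploid count and minor-allele count; P is the sum of
    probabilities of all heterozygote counts at least as improbable as the
    observed one.  Monomorphic sites return 1.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("no genotyped diploids")
    n_rare = min(2 * n_homref + n_het, 2 * n_homalt + n_het)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    valid = hom_common >= 0
    hets, hom_rare, hom_common = hets[valid], hom_rare[valid], hom_common[valid]
    # log P(het=h | n, n_rare) up to a constant:
    # n! / (hr! h! hc!) * 2^h
    logp = (
        -gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
    )
    logp -= logsumexp(logp)
    obs = np.flatnonzero(hets == n_het)
    if len(obs) == 0:
        raise ValueError("observed het count inconsistent with allele count")
    p_obs = logp[obs[0]]
    # include configurations no more probable than the observed one
    mask = logp <= p_obs + 1e-12
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def differential_missingness_test(
    called_cases: int,
    missing_cases: int,
    called_controls: int,
    missing_controls: int,
) -> float:
    """Two-sided Fisher exact test on called/missing x case/control."""
    if called_cases + missing_cases == 0 or \
            called_controls + missing_controls == 0:
        raise ValueError("both row totals must be positive")
    if (called_cases + called_controls == 0) or \
            (missing_cases + missing_controls == 0):
        return 1.0
    _, p = stats.fisher_exact(
        [[called_cases, missing_cases], [called_controls, missing_controls]],
        alternative="two-sided",
    )
    return float(p)


# ---------------------------------------------------------------------------
# Call-level masking
# ---------------------------------------------------------------------------

def apply_depth_mask(gm: GenotypeMatrix, thresholds: QCThresholds
                     ) -> tuple[GenotypeMatrix, int]:
    """Set calls supported by fewer than ``min_depth`` reads to MISSING.

    Calls with unknown depth (no DP/AD in the source) are left alone.
    """
    out = gm.copy()
    known = out.depth >= 0
    low = known & (out.depth < thresholds.min_depth) & (out.dosage != MISSING)
    out.dosage[low] = MISSING
    out.alt_fraction[low] = np.nan
    return out, int(low.sum())


def apply_allelic_balance(gm: GenotypeMatrix, thresholds: QCThresholds
                          ) -> tuple[GenotypeMatrix, int]:
    """Mask heterozygous calls whose alternate-read fraction falls outside
    the open interval (ab_low, ab_high).  Boundary values are masked
    (strict inequalities).  Calls without a defined alt fraction are
    skipped."""
    out = gm.copy()
    with np.errstate(invalid="ignore"):
        bad = (
            (out.dosage == 1)
            & ~np.isnan(out.alt_fraction)
            & (
                (out.alt_fraction <= thresholds.ab_low)
                | (out.alt_fraction >= thresholds.ab_high)
            )
        )
    out.dosage[bad] = MISSING
    out.alt_fraction[bad] = np.nan
    return out, int(bad.sum())


# ---------------------------------------------------------------------------
# Variant-level cascade
# ---------------------------------------------------------------------------

def variant_qc(
    variants: Sequence[VariantRecord],
    gm: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    thresholds: Optional[QCThresholds] = None,
) -> tuple[QCReport, GenotypeMatrix]:
    """Run the fixed-order variant QC cascade; returns the report and the
    masked genotype matrix restricted to surviving variants."""
    thresholds = thresholds or QCThresholds()
    report = QCReport()
    by_id = {s.sample_id: s for s in samples}
    unknown = [sid for sid in gm.sample_ids if sid not in by_id]
    if unknown:
        raise ValueError(f"VCF samples absent from sample sheet: {unknown}")
    sample_order = [by_id[sid] for sid in gm.sample_ids]
    is_case = np.array([s.is_case for s in sample_order])
    strata = np.array([s.stratum for s in sample_order])

    fail: dict[str, list] = {v.variant_id: [] for v in variants}

    # optional VQSLOD pass-through
    if thresholds.vqslod_min is not None:
        n_v = 0
        for v in variants:
            if v.vqslod is not None and v.vqslod < thresholds.vqslod_min:
                fail[v.variant_id].append("vqslod")
                n_v += 1
        report.log_step("vqslod", n_v)

    gm2, n_depth = apply_depth_mask(gm, thresholds)
    report.masked_calls["depth"] = n_depth
    report.log_step("depth_mask_calls", n_depth)

    gm2, n_ab = apply_allelic_balance(gm2, thresholds)
    report.masked_calls["allelic_balance"] = n_ab
    report.log_step("allelic_balance_mask_calls", n_ab)

    call_rate = gm2.call_rate_per_variant()
    for j, v in enumerate(variants):
        if call_rate[j] <= thresholds.min_variant_call_rate:
            fail[v.variant_id].append("call_rate")
    report.log_step(
        "call_rate", sum("call_rate" in r for r in fail.values())
    )

    # per-stratum HWE on all samples of each country stratum
    n_hwe = 0
    stratum_labels = sorted(set(strata))
    stratum_masks = {lab: strata == lab for lab in stratum_labels}
    for lab, mask in stratum_masks.items():
        if mask.sum() == 0:
            report.warnings.append(f"stratum {lab} empty; HWE skipped")
    for j, v in enumerate(variants):
        if fail[v.variant_id]:
            continue
        col = gm2.dosage[:, j]
        for lab, mask in stratum_masks.items():
            sub = col[mask]
            sub = sub[sub != MISSING]
            if len(sub) == 0:
                continue
            p = hwe_exact_test(
                int((sub == 0).sum()), int((sub == 1).sum()),
                int((sub == 2).sum()),
            )
            if p < thresholds.hwe_alpha:
                fail[v.variant_id].append("hwe")
                n_hwe += 1
                break
    report.log_step("hwe", n_hwe)

    # differential missingness case vs control
    n_dm = 0
    for j, v in enumerate(variants):
        if fail[v.variant_id]:
            continue
        called = gm2.dosage[:, j] != MISSING
        p = differential_missingness_test(
            int(called[is_case].sum()),
            int((~called[is_case]).sum()),
            int(called[~is_case].sum()),
            int((~called[~is_case]).sum()),
        )
        if p < thresholds.diff_missing_alpha:
            fail[v.variant_id].append("differential_missingness")
            n_dm += 1
    report.log_step("differential_missingness", n_dm)

    # multi-allelic sibling rule
    parents_failed = {
        v.parent_site_id for v in variants if fail[v.variant_id]
    }
    n_sib = 0
    for v in variants:
        if not fail[v.variant_id] and v.parent_site_id in parents_failed:
            fail[v.variant_id].append("sibling_allele_failed")
            n_sib += 1
    report.log_step("multiallelic_sibling", n_sib)

    report.variant_fail = {k: r for k, r in fail.items() if r}
    report.passed_variants = [
        v.variant_id for v in variants if not fail[v.variant_id]
    ]
    return report, gm2.subset_variants(report.passed_variants)


# ---------------------------------------------------------------------------
# LD pruning and PCA
# ---------------------------------------------------------------------------

def _pairwise_complete_r2(dos: np.ndarray) -> np.ndarray:
    """Exact pairwise-complete squared Pearson correlation of dosage columns,
    computed with mask matrix products."""
    x = np.where(dos == MISSING, np.nan, dos.astype(float))
    m = (~np.isnan(x)).astype(float)
    x0 = np.nan_to_num(x)
    n = m.T @ m
    s1 = x0.T @ m  # s1[i,j] = sum of x_i over samples complete in (i,j)
    s2 = (x0 * x0).T @ m
    p = x0.T @ x0
    with np.errstate(invalid="ignore", divide="ignore"):
        mi = s1 / n
        mj = mi.T
        cov = p / n - mi * mj
        vi = s2 / n - mi * mi
        vj = vi.T
        r2 = cov * cov / (vi * vj)
    r2 = np.where(n > 1, r2, 0.0)
    np.fill_diagonal(r2, 1.0)
    return np.nan_to_num(r2)


def ld_prune(gm: GenotypeMatrix, r2_max: float = 0.10) -> list[str]:
    """Greedy left-to-right LD pruning on pairwise-complete r^2.

    A variant is dropped if its squared correlation with any already-
    retained variant exceeds ``r2_max``; zero-variance variants are
    excluded up front.  The retained set has all pairwise r^2 <= r2_max.
    """
    dos = gm.dosage
    x = np.where(dos == MISSING, np.nan, dos.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        variances = np.nanvar(x, axis=0)
    usable = np.flatnonzero(np.nan_to_num(variances) > 0)
    if len(usable) == 0:
        return []
    r2 = _pairwise_complete_r2(dos[:, usable])
    retained_local: list[int] = []
    for jj in range(len(usable)):
        if all(r2[jj, kk] <= r2_max for kk in retained_local):
            retained_local.append(jj)
    return [gm.variant_ids[usable[jj]] for jj in retained_local]


def compute_pca(gm: GenotypeMatrix, n_pcs: int = 5
                ) -> tuple[np.ndarray, np.ndarray]:
    """Ancestry PCA on (pruned) common-variant dosages.

    Missing dosages are mean-imputed per variant; variants are centred at
    2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat)).  Returns (scores
    [n_samples x n_pcs], loadings [n_variants x n_pcs]); each component's
    sign is fixed by making its largest-magnitude loading positive.
    """
    dos = np.where(gm.dosage == MISSING, np.nan, gm.dosage.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean = np.nanmean(dos, axis=0)
    p_hat = mean / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    keep = np.flatnonzero(np.nan_to_num(scale) > 0)
    if len(keep) < n_pcs:
        raise ValueError(
            f"need >= {n_pcs} polymorphic variants, have {len(keep)}"
        )
    z = (dos[:, keep] - mean[keep]) / scale[keep]
    z = np.nan_to_num(z)  # mean imputation = zero after standardization
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    loadings = vt[:n_pcs].T
    for k in range(n_pcs):
        jmax = np.argmax(np.abs(loadings[:, k]))
        if loadings[jmax, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return scores, loadings


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def king_kinship(gm: GenotypeMatrix) -> np.ndarray:
    """KING-robust pairwise kinship on diploid dosages.

    phi_ij = (N_het,het - 2*N_opposite_hom) / (N_het(i) + N_het(j)),
    counting only sites called in both samples.  Duplicates score ~0.5,
    first-degree relatives ~0.25, unrelated ~0.
    """
    dos = gm.dosage
    het = (dos == 1).astype(float)
    hom0 = (dos == 0).astype(float)
    hom2 = (dos == 2).astype(float)
    valid = (dos != MISSING).astype(float)
    n11 = het @ het.T
    nopp = hom0 @ hom2.T + hom2 @ hom0.T
    het_i = het @ valid.T  # het in i over sites called in both
    het_j = het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n11 - 2.0 * nopp) / (het_i + het_j)
    np.fill_diagonal(phi, 0.5)
    return phi


def _robust_outliers(values: np.ndarray, k: float, two_sided: bool = True
                     ) -> np.ndarray:
    """|x - median| > k * MAD flags (MAD scaled to sigma for a normal)."""
    med = np.median(values)
    mad = np.median(np.abs(values - med)) * 1.4826
    if mad == 0:
        return np.zeros(len(values), dtype=bool)
    z = (values - med) / mad
    return np.abs(z) > k if two_sided else z > k


# ---------------------------------------------------------------------------
# Sample-level cascade
# ---------------------------------------------------------------------------

def sample_qc(
    samples: Sequence[SampleRecord],
    gm: GenotypeMatrix,
    thresholds: Optional[QCThresholds] = None,
    common_gm: Optional[GenotypeMatrix] = None,
) -> QCReport:
    """Sample-level QC after variant QC.

    Checks: coverage (frac_bases_20x), call rate, robust het-count and
    singleton-count outliers within stratum (both tails for singletons),
    PCA outliers within stratum, and duplicate/first-degree-relative removal
    by KING-robust kinship on the LD-pruned common variants (keep one per
    pair, preferring cases, then higher call rate).  Strata with fewer than
    10 samples skip the robust-outlier steps with a warning.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport()
    by_id = {s.sample_id: s for s in samples}
    order = [by_id[sid] for sid in gm.sample_ids]
    n = len(order)
    fail: dict[str, list] = {s.sample_id: [] for s in order}

    # coverage
    n_cov = 0
    for s in order:
        if s.frac_bases_20x is not None and \
                s.frac_bases_20x < thresholds.min_frac_bases_20x:
            fail[s.sample_id].append("coverage")
            n_cov += 1
    report.log_step("coverage", n_cov)

    # call rate
    call_rate = gm.call_rate_per_sample()
    n_cr = 0
    for i, s in enumerate(order):
        s.call_rate = float(call_rate[i])
        if call_rate[i] < thresholds.min_sample_call_rate:
            fail[s.sample_id].append("call_rate")
            n_cr += 1
    report.log_step("call_rate", n_cr)

    # het and singleton counters
    dos = gm.dosage
    het_counts = (dos == 1).sum(axis=1)
    alt_carrier = dos >= 1
    ac = np.where(dos == MISSING, 0, dos).sum(axis=0)
    singleton_cols = ac == 1
    singleton_counts = (alt_carrier[:, singleton_cols]).sum(axis=1)
    for i, s in enumerate(order):
        s.n_het = int(het_counts[i])
        s.n_singletons = int(singleton_counts[i])
        s.exome_variant_count = int(alt_carrier[i].sum())

    strata = np.array([s.stratum for s in order])
    n_het_out = n_sing_out = 0
    for lab in sorted(set(strata)):
        mask = strata == lab
        if mask.sum() < 10:
            report.warnings.append(
                f"stratum {lab} has <10 samples; outlier steps skipped"
            )
            continue
        het_flags = _robust_outliers(
            het_counts[mask].astype(float), thresholds.het_outlier_k
        )
        sing_flags = _robust_outliers(
            singleton_counts[mask].astype(float),
            thresholds.singleton_outlier_k,
        )
        for idx, (hf, sf) in zip(np.flatnonzero(mask),
                                 zip(het_flags, sing_flags)):
            sid = order[idx].sample_id
            if hf:
                fail[sid].append("het_outlier")
                n_het_out += 1
            if sf:
                fail[sid].append("singleton_outlier")
                n_sing_out += 1
    report.log_step("het_outlier", n_het_out)
    report.log_step("singleton_outlier", n_sing_out)

    # ancestry PCA outliers + kinship (need common variants)
    n_pca = n_kin = 0
    if common_gm is not None:
        pruned = ld_prune(common_gm, thresholds.ld_r2_max)
        pruned_gm = common_gm.subset_variants(pruned)
        if pruned_gm.n_variants >= thresholds.n_pcs:
            scores, _ = compute_pca(pruned_gm, thresholds.n_pcs)
            score_by_id = {
                sid: scores[i] for i, sid in enumerate(common_gm.sample_ids)
            }
            for s in order:
                if s.sample_id in score_by_id:
                    s.pcs = score_by_id[s.sample_id]
            for lab in sorted(set(strata)):
                mask = strata == lab
                if mask.sum() < 10:
                    continue
                sub = np.array(
                    [score_by_id[order[i].sample_id]
                     for i in np.flatnonzero(mask)]
                )
                flagged = np.zeros(mask.sum(), dtype=bool)
                for k in range(sub.shape[1]):
                    flagged |= _robust_outliers(
                        sub[:, k], thresholds.pca_outlier_k
                    )
                for local, idx in enumerate(np.flatnonzero(mask)):
                    if flagged[local]:
                        fail[order[idx].sample_id].append("pca_outlier")
                        n_pca += 1

        phi = king_kinship(pruned_gm)
        common_index = {
            sid: i for i, sid in enumerate(common_gm.sample_ids)
        }
        pairs = []
        ids = common_gm.sample_ids
        iu, ju = np.triu_indices(len(ids), k=1)
        related = phi[iu, ju] > thresholds.kinship_related
        for i, j in zip(iu[related], ju[related]):
            pairs.append((ids[i], ids[j], phi[i, j]))
        removed = set()
        for sid_i, sid_j, k in sorted(pairs, key=lambda p: -p[2]):
            if sid_i in removed or sid_j in removed:
                continue
            si, sj = by_id[sid_i], by_id[sid_j]
            # keep cases over controls, then the better call rate
            keep_i = (si.is_case, si.call_rate or 0.0) >= (
                sj.is_case, sj.call_rate or 0.0
            )
            drop = sid_j if keep_i else sid_i
            reason = (
                "duplicate" if k > thresholds.kinship_duplicate else "related"
            )
            fail[drop].append(reason)
            removed.add(drop)
            n_kin += 1
    report.log_step("pca_outlier", n_pca)
    report.log_step("kinship", n_kin)

    report.sample_fail = {k: v for k, v in fail.items() if v}
    report.passed_samples = [
        s.sample_id for s in order if not fail[s.sample_id]
    ]
    return report
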