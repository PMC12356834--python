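"""Quality control: exact tests against brute-force oracles, call masking,
cascade behavior, LD pruning, PCA and relatedness."""

import math

import numpy as np
import pytest
from scipy import stats

from rareburden import (
    GenotypeMatrix,
    QCThresholds,
    SampleRecord,
    VariantRecord,
    apply_allelic_balance,
    compute_pca,
    differential_missingness_test,
    hwe_exact_test,
    king_kinship,
    ld_prune,
    sample_qc,
    variant_qc,
)
from rareburden.model import MISSING
from rareburden.qc import apply_depth_mask


# ---------------------------------------------------------------------------
# HWE exact test vs integer-arithmetic enumeration
# ---------------------------------------------------------------------------

def hwe_oracle(n_homref, n_het, n_homalt):
    """Exact-rational enumeration of the conditional het distribution."""
    n = n_homref + n_het + n_homalt
    n_rare = min(2 * n_homref + n_het, 2 * n_homalt + n_het)
    if n_rare == 0:
        return 1.0
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hr = (n_rare - h) // 2
        hc = n - h - hr
        if hc < 0:
            continue
        weights[h] = (
            math.factorial(n)
            // (math.factorial(hr) * math.factorial(h) * math.factorial(hc))
            * 2 ** h
        )
    total = sum(weights.values())
    w_obs = weights[n_het]
    return sum(w for w in weights.values() if w <= w_obs) / total


def test_hwe_monomorphic_site_is_one():
    assert hwe_exact_test(100, 0, 0) == 1.0


def test_hwe_small_enumeration_example():
    # 8 minor alleles in 8 diploids: het in {0,2,4,6,8}
    assert hwe_exact_test(2, 4, 2) == pytest.approx(hwe_oracle(2, 4, 2),
                                                    abs=1e-12)


def test_hwe_matches_oracle_on_published_style_counts():
    assert hwe_exact_test(57, 14, 50) == pytest.approx(
        hwe_oracle(57, 14, 50), abs=1e-12)


def test_hwe_exhaustive_up_to_12_diploids():
    # full enumeration of every genotype configuration (deep sweep at N<=30
    # lives in the acceptance suite)
    for n in range(1, 13):
        for hr in range(n + 1):
            for h in range(n - hr + 1):
                ha = n - hr - h
                assert hwe_exact_test(hr, h, ha) == pytest.approx(
                    hwe_oracle(hr, h, ha), abs=1e-12), (hr, h, ha)


def test_hwe_rejects_empty_input():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# differential missingness (Fisher)
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher by hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {x: stats.hypergeom.pmf(x, r1 + r2, c1, r1)
           for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values()
                        if p <= p_obs * (1 + 1e-9)))


def test_no_missingness_gives_p_one():
    assert differential_missingness_test(100, 0, 100, 0) == 1.0


def test_differential_missingness_matches_enumeration():
    assert differential_missingness_test(90, 10, 100, 0) == pytest.approx(
        fisher_oracle(90, 10, 100, 0), rel=1e-9)


def test_differential_missingness_symmetric_in_rows():
    p1 = differential_missingness_test(80, 20, 95, 5)
    p2 = differential_missingness_test(95, 5, 80, 20)
    assert p1 == pytest.approx(p2, rel=1e-12)


# ---------------------------------------------------------------------------
# call-level masking
# ---------------------------------------------------------------------------

def _matrix(dosage, depth=None, ab=None):
    dosage = np.asarray(dosage)
    return GenotypeMatrix(dosage, depth, ab)


def test_allelic_balance_masks_hets_outside_open_window():
    dos = np.array([[1, 1, 1, 1, 2, 0]], dtype=np.int8)
    ab = np.array([[0.50, 0.15, 0.20, 0.80, 0.95, 0.01]])
    depth = np.full((1, 6), 50)
    out, n_masked = apply_allelic_balance(_matrix(dos, depth, ab),
                                          QCThresholds())
    # 0.50 retained; 0.15 masked; boundaries 0.20/0.80 masked (strict);
    # homozygous calls untouched regardless of AB
    assert out.dosage[0].tolist() == [1, MISSING, MISSING, MISSING, 2, 0]
    assert n_masked == 3


def test_depth_mask_below_10x():
    dos = np.array([[1, 1, 0]], dtype=np.int8)
    depth = np.array([[9, 10, 3]])
    out, n = apply_depth_mask(_matrix(dos, depth), QCThresholds())
    assert out.dosage[0].tolist() == [MISSING, 1, MISSING]
    assert n == 2


# ---------------------------------------------------------------------------
# variant cascade
# ---------------------------------------------------------------------------

def _cohort(n_cases=30, n_controls=30, stratum="SG"):
    samples = [SampleRecord(f"c{i}", stratum, "female", "PACG_chronic")
               for i in range(n_cases)]
    samples += [SampleRecord(f"u{i}", stratum, "male", "control")
                for i in range(n_controls)]
    return samples


def _variant(vid, pos=100, parent=None):
    return VariantRecord("chr1", pos, "A", "G"[0] if "G" in vid else "G",
                         vid, parent or f"chr1:{pos}:A")


def test_call_rate_filter_after_masking():
    samples = _cohort(30, 30)
    n = len(samples)
    dos = np.zeros((n, 1), dtype=np.int8)
    dos[:4, 0] = MISSING  # call rate 56/60 = 0.933 < 0.95
    gm = GenotypeMatrix(dos, np.full((n, 1), 50),
                        sample_ids=[s.sample_id for s in samples],
                        variant_ids=["v1"])
    variants = [VariantRecord("chr1", 100, "A", "G", "v1", "chr1:100:A")]
    report, kept = variant_qc(variants, gm, samples)
    assert report.variant_fail["v1"] == ["call_rate"]
    assert kept.n_variants == 0


def test_hwe_failure_detected_per_stratum():
    samples = _cohort(40, 40)
    n = len(samples)
    # all-het variant: gross HWE violation
    dos = np.ones((n, 1), dtype=np.int8)
    gm = GenotypeMatrix(dos, np.full((n, 1), 50),
                        np.full((n, 1), 0.5),
                        [s.sample_id for s in samples], ["v1"])
    variants = [VariantRecord("chr1", 100, "A", "G", "v1", "chr1:100:A")]
    report, _ = variant_qc(variants, gm, samples)
    assert "hwe" in report.variant_fail["v1"]


def test_sibling_allele_failure_removes_whole_site():
    samples = _cohort(40, 40)
    n = len(samples)
    dos = np.zeros((n, 2), dtype=np.int8)
    dos[:, 1] = 1  # second allele fails HWE; first is clean
    dos[0, 0] = 1
    gm = GenotypeMatrix(dos, np.full((n, 2), 50),
                        np.column_stack([np.full(n, 0.5)] * 2),
                        [s.sample_id for s in samples], ["vC", "vT"])
    parent = "chr1:100:A"
    variants = [VariantRecord("chr1", 100, "A", "C", "vC", parent),
                VariantRecord("chr1", 100, "A", "T", "vT", parent)]
    report, kept = variant_qc(variants, gm, samples)
    assert "hwe" in report.variant_fail["vT"]
    assert report.variant_fail["vC"] == ["sibling_allele_failed"]
    assert kept.n_variants == 0


def test_variant_qc_blind_to_phenotype_except_missingness(small_study, rng):
    """Permuting phenotype labels must not change any QC outcome other than
    the differential-missingness step."""
    variants, gm = small_study["variants"], small_study["gm"]
    samples = small_study["samples"]
    report1, _ = variant_qc(variants, gm, samples)

    permuted = []
    phenos = [s.phenotype for s in samples]
    rng.shuffle(phenos)
    for s, ph in zip(samples, phenos):
        permuted.append(SampleRecord(s.sample_id, s.stratum, s.sex, ph,
                                     s.frac_bases_20x))
    report2, _ = variant_qc(variants, gm, permuted)

    def non_dm(report):
        return {v: [r for r in reasons if r != "differential_missingness"]
                for v, reasons in report.variant_fail.items()}

    assert non_dm(report1) == non_dm(report2)


def test_clean_simulation_passes_nearly_all_variants(small_study):
    variants, gm = small_study["variants"], small_study["gm"]
    report, kept = variant_qc(variants, gm, small_study["samples"])
    assert kept.n_variants / gm.n_variants >= 0.99


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def test_ld_prune_keeps_one_of_a_duplicated_pair(rng):
    col = rng.binomial(2, 0.3, size=500).astype(np.int8)
    indep = rng.binomial(2, 0.3, size=500).astype(np.int8)
    gm = GenotypeMatrix(np.column_stack([col, col, indep]),
                        variant_ids=["a", "a_dup", "b"])
    kept = ld_prune(gm, 0.1)
    assert kept == ["a", "b"]


def test_ld_prune_retains_independent_variants_and_bounds_r2(rng):
    n, m = 2000, 60
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(
        np.int8)
    gm = GenotypeMatrix(dos)
    kept = ld_prune(gm, 0.1)
    assert len(kept) >= m - 2  # expected r^2 ~ 1/n for independent sites
    # postcondition: all pairwise r^2 over retained <= threshold
    sub = gm.subset_variants(kept).dosage.astype(float)
    r = np.corrcoef(sub.T)
    np.fill_diagonal(r, 0)
    assert (r ** 2).max() <= 0.1 + 1e-12


def test_ld_prune_drops_monomorphic():
    gm = GenotypeMatrix(np.zeros((50, 1), dtype=np.int8),
                        variant_ids=["mono"])
    assert ld_prune(gm, 0.1) == []


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def _two_pop_dosages(rng, n_per=150, m=300, shift=0.15):
    af = rng.uniform(0.2, 0.5, m)
    af2 = np.clip(af + rng.choice([-shift, shift], m), 0.05, 0.95)
    a = rng.binomial(2, af, size=(n_per, m))
    b = rng.binomial(2, af2, size=(n_per, m))
    return np.vstack([a, b]).astype(np.int8)


def test_pca_separates_populations_with_af_shift(rng):
    dos = _two_pop_dosages(rng)
    scores, _ = compute_pca(GenotypeMatrix(dos), 2)
    g1, g2 = scores[:150, 0], scores[150:, 0]
    sep = abs(g1.mean() - g2.mean())
    spread = (g1.std() + g2.std()) / 2
    assert sep > 3 * spread


def test_pca_no_separation_without_gradient(rng):
    dos = _two_pop_dosages(rng, shift=0.0)
    scores, _ = compute_pca(GenotypeMatrix(dos), 2)
    for k in range(2):
        t, p = stats.ttest_ind(scores[:150, k], scores[150:, k])
        assert p > 1e-3


def test_pca_permutation_equivariance(rng):
    dos = _two_pop_dosages(rng, n_per=60, m=100)
    gm = GenotypeMatrix(dos)
    scores, _ = compute_pca(gm, 3)
    perm = rng.permutation(dos.shape[0])
    scores_p, _ = compute_pca(GenotypeMatrix(dos[perm]), 3)
    assert np.allclose(scores_p, scores[perm], atol=1e-8)


# ---------------------------------------------------------------------------
# relatedness & sample cascade
# ---------------------------------------------------------------------------

def test_king_kinship_of_duplicate_near_half(rng):
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, 2000),
                       size=(30, 2000)).astype(np.int8)
    dos = np.vstack([dos, dos[:1]])  # sample 30 duplicates sample 0
    phi = king_kinship(GenotypeMatrix(dos))
    assert phi[0, 30] == pytest.approx(0.5, abs=0.02)
    # no unrelated pair crosses the first-degree-relative cutoff
    unrelated = phi[np.triu_indices(30, k=1)]
    assert unrelated.max() < 0.0884


def test_sample_qc_coverage_and_duplicates(small_study):
    gm, samples = small_study["gm"], small_study["samples"]
    from rareburden.qc import variant_qc as vqc

    _, gm_clean = vqc(small_study["variants"], gm, samples)
    af = np.where(gm_clean.dosage == MISSING, 0,
                  gm_clean.dosage).sum(0) / (
        2 * (gm_clean.dosage != MISSING).sum(0))
    common_ids = [gm_clean.variant_ids[j]
                  for j in np.flatnonzero(np.minimum(af, 1 - af) >= 0.05)]
    common = gm_clean.subset_variants(common_ids)

    # degrade one sample's coverage metric below the 80% floor
    samples = [SampleRecord(s.sample_id, s.stratum, s.sex, s.phenotype,
                            s.frac_bases_20x) for s in samples]
    samples[0].frac_bases_20x = 0.79
    report = sample_qc(samples, gm_clean, QCThresholds(), common)
    assert "coverage" in report.sample_fail[samples[0].sample_id]
    # exactly one of each injected duplicate pair removed
    dup_ids = [s.sample_id for s in samples if s.sample_id.endswith("_dup")]
    assert len(dup_ids) == 2
    for did in dup_ids:
        orig = did[: -len("_dup")]
        removed = [sid for sid in (did, orig)
                   if "duplicate" in report.sample_fail.get(sid, [])]
        assert len(removed) == 1
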