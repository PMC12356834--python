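"""Stratified association statistics: CMH, Mantel-Haenszel OR, zero-cell
correction, adjusted model, secondary analyses."""

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable

from rareburden import (
    SampleRecord,
    StratumTable,
    adjusted_burden_model,
    carrier_pc_projection,
    cmh_test,
    gene_burden_scan,
    haldane_anscombe_or,
    mh_common_or,
    secondary_analyses,
)


def _random_tables(rng, k, low=1, high=80):
    return [StratumTable(f"s{i}", *map(int, rng.integers(low, high, 4)))
            for i in range(k)]


def _textbook_cmh(tables):
    """Independent direct transcription of the classical formulas."""
    num = 0.0
    den = 0.0
    for t in tables:
        n = t.a + t.b + t.c + t.d
        num += t.a - (t.a + t.b) * (t.a + t.c) / n
        den += ((t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
                / (n ** 2 * (n - 1)))
    return num ** 2 / den


def _textbook_mh_or(tables):
    r = sum(t.a * t.d / t.n for t in tables)
    s = sum(t.b * t.c / t.n for t in tables)
    return r / s


# ---------------------------------------------------------------------------
# CMH
# ---------------------------------------------------------------------------

def test_cmh_single_stratum_equals_pearson_chi_square(rng):
    for _ in range(50):
        t = _random_tables(rng, 1)[0]
        stat, p = cmh_test([t])
        obs = np.array([[t.a, t.b], [t.c, t.d]])
        # Pearson chi-square carries an n/(n-1) factor relative to the
        # hypergeometric-variance CMH statistic
        chi2 = stats.chi2_contingency(obs, correction=False).statistic
        assert stat == pytest.approx(chi2 * (t.n - 1) / t.n, rel=1e-10)


def test_cmh_matches_independent_implementations(rng):
    for _ in range(300):
        tabs = _random_tables(rng, int(rng.integers(1, 5)))
        stat, p = cmh_test(tabs)
        assert stat == pytest.approx(_textbook_cmh(tabs), abs=1e-10)
        st = StratifiedTable(np.dstack(
            [np.array([[t.a, t.c], [t.b, t.d]]) for t in tabs]
        ).astype(float))
        r = st.test_null_odds(correction=False)
        assert stat == pytest.approx(r.statistic, abs=1e-10)
        assert p == pytest.approx(r.pvalue, abs=1e-10)


def test_cmh_null_table_gives_statistic_zero():
    # a = E in every stratum -> statistic 0, P = 1
    tabs = [StratumTable("s1", 10, 10, 10, 10),
            StratumTable("s2", 5, 15, 5, 15)]
    stat, p = cmh_test(tabs)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_cmh_degenerate_strata_flagged_nan():
    stat, p = cmh_test([StratumTable("s", 0, 10, 0, 10)])
    assert np.isnan(stat) and np.isnan(p)


# ---------------------------------------------------------------------------
# MH common OR
# ---------------------------------------------------------------------------

def test_mh_or_matches_independent_implementations(rng):
    for _ in range(300):
        tabs = _random_tables(rng, int(rng.integers(1, 5)))
        orr, ci = mh_common_or(tabs)
        assert orr == pytest.approx(_textbook_mh_or(tabs), abs=1e-10)
        st = StratifiedTable(np.dstack(
            [np.array([[t.a, t.c], [t.b, t.d]]) for t in tabs]
        ).astype(float))
        assert orr == pytest.approx(st.oddsratio_pooled, abs=1e-10)
        lo, hi = st.oddsratio_pooled_confint(0.05)
        assert ci[0] == pytest.approx(lo, rel=1e-6)
        assert ci[1] == pytest.approx(hi, rel=1e-6)


def test_mh_or_single_stratum_equals_crude_cross_product(rng):
    for _ in range(50):
        t = _random_tables(rng, 1)[0]
        orr, _ = mh_common_or([t])
        assert orr == pytest.approx(t.a * t.d / (t.b * t.c), rel=1e-12)


def test_mh_or_unity_when_all_strata_null():
    tabs = [StratumTable("s1", 4, 8, 6, 12), StratumTable("s2", 3, 9, 5, 15)]
    orr, _ = mh_common_or(tabs)
    assert orr == pytest.approx(1.0, rel=1e-12)


def test_mh_or_collapsibility_identical_margins():
    # strata with identical margins and identical OR: pooled OR = stratum OR
    t = StratumTable("s", 20, 80, 10, 90)
    orr, _ = mh_common_or([t, StratumTable("s2", 20, 80, 10, 90)])
    assert orr == pytest.approx(20 * 90 / (80 * 10), rel=1e-12)


# ---------------------------------------------------------------------------
# Haldane-Anscombe
# ---------------------------------------------------------------------------

def test_haldane_anscombe_zero_cell_arithmetic():
    orr, ci = haldane_anscombe_or(StratumTable("s", 1, 9, 0, 10))
    assert orr == pytest.approx((1.5 * 10.5) / (9.5 * 0.5), rel=1e-12)
    assert ci[0] < orr < ci[1]


def test_haldane_anscombe_no_correction_without_zero():
    orr, _ = haldane_anscombe_or(StratumTable("s", 5, 5, 5, 5))
    assert orr == pytest.approx(1.0)


def test_haldane_anscombe_symmetric_zeros_give_unity():
    orr, _ = haldane_anscombe_or(StratumTable("s", 0, 10, 0, 10))
    assert orr == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def test_gene_burden_scan_orders_and_flags(rng):
    gene_strata = {
        "NULLG": [StratumTable("s", 10, 90, 10, 90)],
        "HITG": [StratumTable("s", 60, 40, 10, 90)],
        "EMPTY": [],
    }
    results = gene_burden_scan(gene_strata, alpha_exome=1e-3)
    assert [r.gene for r in results] == ["HITG", "NULLG", "EMPTY"]
    assert results[0].exome_wide_significant
    assert "degenerate" in results[2].flags
    # processing order does not change the statistics
    again = gene_burden_scan(dict(reversed(list(gene_strata.items()))),
                             alpha_exome=1e-3)
    assert [r.gene for r in again] == [r.gene for r in results]
    assert np.allclose([r.p_cmh for r in again],
                       [r.p_cmh for r in results], equal_nan=True)


# ---------------------------------------------------------------------------
# adjusted model
# ---------------------------------------------------------------------------

def test_adjusted_p_close_to_unadjusted_with_orthogonal_covariates(rng):
    n = 2000
    carrier = rng.random(n) < 0.05
    logit = -1 + 1.0 * carrier
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    cov = rng.normal(size=(n, 3))  # independent of carrier and outcome
    fit_adj = adjusted_burden_model(carrier, y, cov)
    fit_unadj = adjusted_burden_model(carrier, y, np.zeros((n, 0)))
    assert fit_adj.log_or == pytest.approx(fit_unadj.log_or, abs=0.05)
    assert np.log10(fit_adj.p_value) == pytest.approx(
        np.log10(fit_unadj.p_value), abs=0.5)


def test_adjustment_removes_confounding(rng):
    # a PC drives both carrier probability and disease risk
    n = 4000
    pc = rng.normal(size=n)
    carrier = rng.random(n) < 1 / (1 + np.exp(-(-3 + 1.5 * pc)))
    y = rng.random(n) < 1 / (1 + np.exp(-(-1 + 1.5 * pc)))  # no true effect
    unadj = adjusted_burden_model(carrier, y, np.zeros((n, 0)))
    adj = adjusted_burden_model(carrier, y, pc[:, None])
    assert abs(adj.log_or) < abs(unadj.log_or)
    assert abs(adj.log_or) < 0.25


def test_separation_triggers_firth_fallback(rng):
    n = 400
    carrier = np.zeros(n, bool)
    carrier[:20] = True
    y = carrier.copy()  # perfect separation
    cov = rng.normal(size=(n, 2))
    fit = adjusted_burden_model(carrier, y, cov)
    assert fit.used_firth
    assert np.isfinite(fit.log_or) and np.isfinite(fit.p_value)


def test_all_zero_carrier_vector_flagged():
    fit = adjusted_burden_model(np.zeros(100), np.ones(100) * 0.0,
                                np.zeros((100, 0)))
    assert not fit.converged
    assert np.isnan(fit.log_or)


# ---------------------------------------------------------------------------
# secondary analyses
# ---------------------------------------------------------------------------

def _cohort_samples(rng, n=400):
    samples = []
    for i in range(n):
        stratum = "SG" if i % 2 else "HK"
        sex = "female" if rng.random() < 0.5 else "male"
        if i < n // 2:
            pheno = "APAC" if rng.random() < 0.4 else "PACG_chronic"
        else:
            pheno = "control"
        samples.append(SampleRecord(f"x{i}", stratum, sex, pheno))
    return samples


def test_secondary_analyses_restrictions(rng):
    samples = _cohort_samples(rng)
    carrier = {s.sample_id: bool(rng.random() < 0.1) for s in samples}
    out = secondary_analyses(carrier, samples)
    # APAC restriction: case column totals = number of APAC cases analyzed
    n_apac = sum(1 for s in samples if s.phenotype == "APAC")
    got_cases = sum(t.a + t.b for t in out["apac_vs_controls"]["strata"])
    assert got_cases == n_apac
    # sex-stratified runs restrict both columns to that sex
    n_female_ctrl = sum(1 for s in samples
                        if s.sex == "female" and not s.is_case)
    got_ctrl = sum(t.c + t.d for t in out["female_only"]["strata"])
    assert got_ctrl == n_female_ctrl
    # equal ORs by sex in the generator: CIs overlap
    f, m = out["female_only"], out["male_only"]
    assert f["ci95"][0] <= m["ci95"][1] and m["ci95"][0] <= f["ci95"][1]


def test_carrier_pc_projection_counts_and_null(rng):
    pcs = {f"x{i}": rng.normal(size=2) for i in range(300)}
    carrier = {f"x{i}": bool(rng.random() < 0.2) for i in range(300)}
    proj = carrier_pc_projection(carrier, pcs)
    n_c = sum(carrier.values())
    assert len(proj["carrier_coords"]) == n_c
    assert len(proj["noncarrier_coords"]) == 300 - n_c
    # carriers drawn uniformly: no location shift expected
    assert proj["location_test_p"]["PC1"] > 1e-3
    assert proj["location_test_p"]["PC2"] > 1e-3
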