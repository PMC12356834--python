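"""Stratified association statistics for the collapsing burden test.

The primary statistic is the Cochran-Mantel-Haenszel chi-square over per-
stratum carrier 2x2 tables, with the Mantel-Haenszel common odds ratio and
a Robins-Breslow-Greenland confidence interval.  Zero-cell tables get the
Haldane-Anscombe 0.5 correction for display odds ratios only — the CMH
statistic itself is always computed on raw counts.  No continuity
correction is applied to the CMH statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import ALPHA_EXOME, GeneBurdenResult, StratumTable

Z975 = 1.959963984540054  # Phi^-1(0.975)


# ---------------------------------------------------------------------------
# CMH test
# ---------------------------------------------------------------------------

def cmh_test(strata: Sequence[StratumTable]) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel chi-square (1 df, no continuity correction).

    statistic = (sum_k (a_k - E_k))^2 / sum_k V_k with E_k the expected case-
    carrier count under the hypergeometric null and V_k its variance.
    Returns (statistic, two-sided P).  Degenerate inputs (all strata with
    zero hypergeometric variance) give (nan, nan).
    """
    a = np.array([t.a for t in strata], dtype=float)
    b = np.array([t.b for t in strata], dtype=float)
    c = np.array([t.c for t in strata], dtype=float)
    d = np.array([t.d for t in strata], dtype=float)
    stat = _cmh_statistic(a, b, c, d)
    if np.isnan(stat):
        return float("nan"), float("nan")
    return float(stat), float(stats.chi2.sf(stat, df=1))


def _cmh_statistic(a, b, c, d):
    """Vectorizable CMH statistic; inputs are arrays whose last axis indexes
    strata."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    with np.errstate(invalid="ignore", divide="ignore"):
        e = (a + b) * (a + c) / n
        v = (a + b) * (c + d) * (a + c) * (b + d) / (n * n * (n - 1.0))
    e = np.where(n > 0, e, 0.0)
    v = np.where(n > 1, v, 0.0)
    num = (a - e).sum(axis=-1) ** 2
    den = v.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out if out.ndim else float(out)


def cmh_pvalues_bulk(a, b, c, d) -> np.ndarray:
    """Two-sided CMH P values for many replicate table sets at once.

    Each input has shape (..., K) over K strata.  Used by the power
    simulator and type-I-error studies.
    """
    stat = _cmh_statistic(a, b, c, d)
    return stats.chi2.sf(stat, df=1)


# ---------------------------------------------------------------------------
# Mantel-Haenszel common odds ratio
# ---------------------------------------------------------------------------

def mh_common_or(
    strata: Sequence[StratumTable],
) -> tuple[float, tuple[float, float]]:
    """Mantel-Haenszel common OR with 95% Robins-Breslow-Greenland CI.

    OR_MH = sum(a_k d_k / n_k) / sum(b_k c_k / n_k).  If either sum is zero
    (all-zero cross products), falls back to pooling the strata into one
    Haldane-Anscombe-corrected table and flags nothing here — callers check
    for the degenerate CI.
    """
    a = np.array([t.a for t in strata], dtype=float)
    b = np.array([t.b for t in strata], dtype=float)
    c = np.array([t.c for t in strata], dtype=float)
    d = np.array([t.d for t in strata], dtype=float)
    n = a + b + c + d
    ok = n > 0
    a, b, c, d, n = a[ok], b[ok], c[ok], d[ok], n[ok]

    R = a * d / n
    S = b * c / n
    sumR, sumS = R.sum(), S.sum()
    if sumR == 0 or sumS == 0:
        pooled = StratumTable(
            "pooled", int(a.sum()), int(b.sum()), int(c.sum()), int(d.sum())
        )
        return haldane_anscombe_or(pooled)

    or_mh = sumR / sumS
    # Robins-Breslow-Greenland variance of log(OR_MH)
    P = (a + d) / n
    Q = (b + c) / n
    var = (
        (P * R).sum() / (2 * sumR**2)
        + ((P * S + Q * R).sum()) / (2 * sumR * sumS)
        + (Q * S).sum() / (2 * sumS**2)
    )
    se = np.sqrt(var)
    lo = or_mh * np.exp(-Z975 * se)
    hi = or_mh * np.exp(Z975 * se)
    return float(or_mh), (float(lo), float(hi))


def haldane_anscombe_or(
    table: StratumTable,
) -> tuple[float, tuple[float, float]]:
    """Single-table odds ratio with Woolf CI; if any cell is zero, 0.5 is
    added to all four cells first (Haldane-Anscombe correction)."""
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(orr), (
        float(orr * np.exp(-Z975 * se)),
        float(orr * np.exp(Z975 * se)),
    )


# ---------------------------------------------------------------------------
# Exome-wide scan
# ---------------------------------------------------------------------------

def gene_burden_scan(
    gene_strata: dict[str, list[StratumTable]],
    alpha_exome: float = ALPHA_EXOME,
) -> list[GeneBurdenResult]:
    """Run cmh_test and mh_common_or for every gene.

    Output is sorted by ascending P with a stable gene-name tiebreak; genes
    whose tables are degenerate (no carriers anywhere, or empty strata) are
    reported with NaN statistics rather than dropped.
    """
    results = []
    for gene, strata in gene_strata.items():
        usable = [t for t in strata if t.n > 0]
        flags: list[str] = []
        if not usable:
            results.append(
                GeneBurdenResult(
                    gene=gene,
                    strata=list(strata),
                    or_mh=float("nan"),
                    ci95=(float("nan"), float("nan")),
                    p_cmh=float("nan"),
                    flags=["degenerate"],
                )
            )
            continue
        stat, p = cmh_test(usable)
        orr, ci = mh_common_or(usable)
        if any(min(t.a, t.b, t.c, t.d) == 0 for t in usable):
            flags.append("zero_cell")
        if np.isnan(stat):
            flags.append("degenerate")
        results.append(
            GeneBurdenResult(
                gene=gene,
                strata=list(strata),
                or_mh=orr,
                ci95=ci,
                statistic=stat,
                p_cmh=p,
                exome_wide_significant=bool(
                    not np.isnan(p) and p < alpha_exome
                ),
                flags=flags,
            )
        )
    results.sort(
        key=lambda r: (
            np.inf if np.isnan(r.p_cmh) else r.p_cmh,
            r.gene,
        )
    )
    return results


# ---------------------------------------------------------------------------
# Covariate-adjusted burden model
# ---------------------------------------------------------------------------

@dataclass
class AdjustedModelSpec:
    """Configuration of the covariate-adjusted logistic burden model."""

    covariates: list = field(
        default_factory=lambda: ["PC1", "PC2", "PC3", "PC4", "PC5",
                                 "exome_variant_count"]
    )
    estimation: str = "maximum-likelihood"
    separation_fallback: bool = True


@dataclass
class AdjustedModelResult:
    log_or: float
    se: float
    p_value: float
    used_firth: bool = False
    converged: bool = True
    message: str = ""


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
                 tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, bool]:
    """Firth-penalized logistic regression (Jeffreys-prior score).

    Returns (beta, cov, converged).  Newton iterations on the modified score
    U*(b) = X'(y - p + h(0.5 - p)) where h is the hat-matrix diagonal.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = p * (1 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return beta, np.full((k, k), np.nan), False
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # step-halving for stability
        lam = 1.0
        while lam > 1e-4 and np.max(np.abs(lam * step)) > 5.0:
            lam /= 2.0
        beta = beta + lam * step
        if np.max(np.abs(step)) < tol:
            eta = X @ beta
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            w = p * (1 - p)
            info = X.T @ (X * w[:, None])
            return beta, np.linalg.inv(info), True
    return beta, np.linalg.inv(info), False


def adjusted_burden_model(
    carrier: np.ndarray,
    is_case: np.ndarray,
    covariates: np.ndarray,
    spec: Optional[AdjustedModelSpec] = None,
) -> AdjustedModelResult:
    """Logistic regression of case status on carrier status plus covariates.

    Wald two-sided P for the carrier coefficient.  On detected separation
    (non-convergence or exploding SE) with ``separation_fallback`` enabled,
    re-fits with Firth penalization and records the switch.
    """
    import statsmodels.api as sm

    spec = spec or AdjustedModelSpec()
    carrier = np.asarray(carrier, dtype=float)
    y = np.asarray(is_case, dtype=float)
    if carrier.std() == 0:
        return AdjustedModelResult(
            log_or=float("nan"), se=float("nan"), p_value=float("nan"),
            converged=False, message="degenerate carrier vector",
        )
    X = np.column_stack([np.ones_like(carrier), carrier,
                         np.asarray(covariates, dtype=float)])

    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta1 = fit.params[1]
        se1 = fit.bse[1]
        if not fit.mle_retvals.get("converged", True) or se1 > 50 or \
                abs(beta1) > 15:
            separation = True
    except Exception:
        separation = True

    if separation and spec.separation_fallback:
        beta, cov, ok = _firth_logit(X, y)
        se1 = float(np.sqrt(cov[1, 1]))
        z = beta[1] / se1
        return AdjustedModelResult(
            log_or=float(beta[1]),
            se=se1,
            p_value=float(2 * stats.norm.sf(abs(z))),
            used_firth=True,
            converged=ok,
            message="separation detected; Firth fallback used",
        )
    if separation:
        return AdjustedModelResult(
            log_or=float("nan"), se=float("nan"), p_value=float("nan"),
            converged=False, message="separation detected, no fallback",
        )
    z = beta1 / se1
    return AdjustedModelResult(
        log_or=float(beta1),
        se=float(se1),
        p_value=float(2 * stats.norm.sf(abs(z))),
    )


# ---------------------------------------------------------------------------
# Secondary stratified analyses
# ---------------------------------------------------------------------------

def secondary_analyses(
    carrier_status: dict[str, Optional[bool]],
    samples: Sequence,
) -> dict[str, dict]:
    """Post-hoc stratified reruns for one gene.

    Restrictions: female-only and male-only (cases AND controls restricted
    to that sex), APAC-vs-controls (only the acute subtype in the case
    column; controls untouched), and female-APAC vs female controls.
    Returns per-restriction {strata, or_mh, ci95, p_cmh}.
    """
    def run(case_pred, control_pred):
        strata_labels = sorted({s.stratum for s in samples})
        tables = []
        for lab in strata_labels:
            a = b = c = d = 0
            for s in samples:
                carr = carrier_status.get(s.sample_id)
                if carr is None or s.stratum != lab:
                    continue
                if s.is_case and case_pred(s):
                    a += carr
                    b += not carr
                elif (not s.is_case) and control_pred(s):
                    c += carr
                    d += not carr
            if a + b > 0 and c + d > 0:
                tables.append(StratumTable(lab, a, b, c, d))
        if not tables:
            return {
                "strata": [], "or_mh": float("nan"),
                "ci95": (float("nan"), float("nan")), "p_cmh": float("nan"),
            }
        stat, p = cmh_test(tables)
        orr, ci = mh_common_or(tables)
        return {"strata": tables, "or_mh": orr, "ci95": ci, "p_cmh": p}

    return {
        "female_only": run(
            lambda s: s.sex == "female", lambda s: s.sex == "female"
        ),
        "male_only": run(
            lambda s: s.sex == "male", lambda s: s.sex == "male"
        ),
        "apac_vs_controls": run(
            lambda s: s.phenotype == "APAC", lambda s: True
        ),
        "female_apac_vs_female_controls": run(
            lambda s: s.phenotype == "APAC" and s.sex == "female",
            lambda s: s.sex == "female",
        ),
    }


def carrier_pc_projection(
    carrier_status: dict[str, Optional[bool]],
    pc_scores: dict[str, np.ndarray],
) -> dict:
    """Project carriers vs non-carriers onto PC1/PC2 (report-only check for
    confounding by ancestry); includes a two-sample location test per axis."""
    carriers, noncarriers = [], []
    for sid, carr in carrier_status.items():
        if carr is None or sid not in pc_scores:
            continue
        (carriers if carr else noncarriers).append(pc_scores[sid][:2])
    carriers = np.array(carriers).reshape(-1, 2)
    noncarriers = np.array(noncarriers).reshape(-1, 2)
    tests = {}
    for axis, name in enumerate(("PC1", "PC2")):
        if len(carriers) >= 2 and len(noncarriers) >= 2:
            stat, p = stats.mannwhitneyu(
                carriers[:, axis], noncarriers[:, axis],
                alternative="two-sided",
            )
            tests[name] = float(p)
        else:
            tests[name] = float("nan")
    return {
        "carrier_coords": carriers,
        "noncarrier_coords": noncarriers,
        "location_test_p": tests,
    }
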