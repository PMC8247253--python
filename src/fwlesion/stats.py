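"""Cohort statistics for regional diffusion metrics.

Covers the analysis battery applied to per-subject regional means: paired t
comparisons (lesion vs normal-appearing WM), one-way MANOVA across the four
FW-quartile subregions with generalized eta squared effect sizes and
Bonferroni-adjusted pairwise post hoc tests, Pearson and partial correlations
with Bonferroni family adjustment, logistic regression with change-in-
estimate (CIE) confounder selection, and Cohen's kappa for rater agreement.

For the one-way between-groups design used here, generalized eta squared
reduces to SS_between / (SS_between + SS_within).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.multivariate.manova import MANOVA

__all__ = [
    "paired_t",
    "bonferroni",
    "ManovaReport",
    "oneway_manova",
    "correlation_suite",
    "partial_correlation",
    "CIEModelReport",
    "logistic_cie",
    "cohens_kappa",
]


def paired_t(x, y) -> tuple[float, int, float]:
    """Classical paired t test; returns (t, df, two-sided p).

    All-zero differences give (0, n-1, 1). Zero variance with a nonzero mean
    difference is reported at the floating-point floor rather than p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired t needs two equal-length vectors of size >= 2")
    d = x - y
    df = d.size - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, float(np.nextafter(0, 1))
    res = sps.ttest_rel(x, y)
    return float(res.statistic), df, float(res.pvalue)


def bonferroni(p, m: int | None = None) -> np.ndarray:
    """min(1, m * p) per element; m defaults to the family size."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    m = p.size if m is None else m
    return np.minimum(1.0, m * p)


@dataclass
class ManovaReport:
    pillai: float
    pillai_p: float
    univariate: pd.DataFrame  # per metric: F, eta2g, p
    posthoc: pd.DataFrame  # per metric and group pair: raw and adjusted p


def _oneway_ss(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    grand = values.mean()
    ss_b = ss_w = 0.0
    for g in np.unique(groups):
        v = values[groups == g]
        ss_b += v.size * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    return ss_b, ss_w


def oneway_manova(long: pd.DataFrame, metrics: list[str], group_col: str = "group") -> ManovaReport:
    """One-way MANOVA across groups (e.g. FWq1..FWq4) on several metrics.

    Reports the multivariate Pillai trace, per-metric univariate F with
    generalized eta squared, and all pairwise two-sample contrasts per metric
    with Bonferroni adjustment over the pairs of each metric.
    """
    groups = np.asarray(long[group_col])
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need at least two groups")
    for g in levels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 observations")
    x = long[metrics].to_numpy(dtype=float)
    resid = np.vstack([x[groups == g] - x[groups == g].mean(axis=0) for g in levels])
    if np.any(resid.std(axis=0) == 0):
        raise ValueError("within-group covariance is singular; drop collinear metrics")

    if len(metrics) > 1:
        work = long[[group_col] + metrics].copy()
        rename = {m: f"m{i}" for i, m in enumerate(metrics)}
        work = work.rename(columns=rename)
        formula = " + ".join(rename.values()) + f" ~ C({group_col})"
        group_means = np.stack([x[groups == g].mean(axis=0) for g in levels])
        if np.allclose(group_means, group_means[0]):
            # degenerate between-group structure: no multivariate effect
            pillai, pillai_p = 0.0, 1.0
        else:
            try:
                mv = MANOVA.from_formula(formula, data=work)
                tbl = mv.mv_test().results[f"C({group_col})"]["stat"]
            except (np.linalg.LinAlgError, ValueError) as exc:
                raise ValueError(
                    "within-group covariance is singular; drop collinear metrics"
                ) from exc
            pillai = float(tbl.loc["Pillai's trace", "Value"])
            pillai_p = float(tbl.loc["Pillai's trace", "Pr > F"])
    else:
        pillai = pillai_p = np.nan  # filled from the univariate test below

    uni_rows = []
    post_rows = []
    k = levels.size
    n = x.shape[0]
    n_pairs = k * (k - 1) // 2
    for j, m in enumerate(metrics):
        ss_b, ss_w = _oneway_ss(x[:, j], groups)
        f_stat = (ss_b / (k - 1)) / (ss_w / (n - k)) if ss_w > 0 else (
            0.0 if ss_b == 0 else np.inf
        )
        eta2g = ss_b / (ss_b + ss_w) if (ss_b + ss_w) > 0 else 0.0
        p = float(sps.f.sf(f_stat, k - 1, n - k)) if np.isfinite(f_stat) else 0.0
        if f_stat == 0.0:
            p = 1.0
        uni_rows.append({"metric": m, "F": f_stat, "eta2g": eta2g, "p": p})
        for a in range(k):
            for b in range(a + 1, k):
                va, vb = x[groups == levels[a], j], x[groups == levels[b], j]
                if np.var(va) == 0 and np.var(vb) == 0:
                    t, praw = (0.0, 1.0) if va.mean() == vb.mean() else (np.inf, 0.0)
                else:
                    t, praw = sps.ttest_ind(va, vb)
                post_rows.append(
                    {
                        "metric": m,
                        "group_a": levels[a],
                        "group_b": levels[b],
                        "t": float(t),
                        "p_raw": float(praw),
                        "p_bonferroni": float(min(1.0, n_pairs * praw)),
                    }
                )
    uni = pd.DataFrame(uni_rows)
    if len(metrics) == 1:
        # with a single response Pillai's trace reduces to eta squared
        pillai = float(uni["eta2g"][0])
        pillai_p = float(uni["p"][0])
    return ManovaReport(pillai, pillai_p, uni, pd.DataFrame(post_rows))


def partial_correlation(x, y, covariates: np.ndarray | None = None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariate columns.

    Residualizes both variables on [1, covariates] by least squares and
    correlates the residuals; df = n - 2 - n_covariates. With no covariates
    this is exactly the Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    ncov = 0
    if covariates is not None and np.size(covariates):
        z = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        ncov = z.shape[1] - 1
        x = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
        y = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant variable: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2 - ncov
    if df <= 0:
        raise ValueError("not enough observations for the covariate count")
    r_ = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def correlation_suite(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    covariates: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson and covariate-adjusted partial correlations for metric pairs.

    The Bonferroni family is the set of tested pairs; both raw and adjusted
    p-values are reported, with significance at ``alpha`` after adjustment.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 complete rows")
    cov = table[covariates].to_numpy(dtype=float) if covariates else None
    rows = []
    m = len(pairs)
    for a, b in pairs:
        sub = table[[a, b] + (covariates or [])].dropna()
        r, p = partial_correlation(sub[a], sub[b], None)
        rp, pp = partial_correlation(
            sub[a], sub[b], sub[covariates].to_numpy(dtype=float) if covariates else None
        )
        rows.append(
            {
                "x": a,
                "y": b,
                "n": len(sub),
                "pearson_r": r,
                "pearson_p": p,
                "partial_r": rp,
                "partial_p": pp,
                "pearson_p_bonferroni": min(1.0, m * p),
                "partial_p_bonferroni": min(1.0, m * pp),
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["partial_p_bonferroni"] < alpha
    return out


@dataclass
class CIEModelReport:
    """Change-in-estimate confounder-selection ledger for one outcome."""

    outcome: str
    exposure: str
    crude_or: float
    crude_ci: tuple[float, float]
    crude_p: float
    ledger: pd.DataFrame  # candidate, pct_change, retained
    retained: list[str]
    final_or: float
    final_ci: tuple[float, float]
    final_p: float
    pseudo_r2: float


def _fit_logit(y, x_df: pd.DataFrame):
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    x = sm.add_constant(x_df, has_constant="add")
    model = sm.Logit(np.asarray(y, dtype=float), x.astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparation* variants
        raise ValueError(f"logistic fit failed ({exc}); check for separation") from exc
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge: " + str(res.mle_retvals))
    # saturated linear predictor = (quasi-)separation, independent of the
    # scale of the design columns
    xb = np.asarray(x, dtype=float) @ res.params
    if np.any(np.abs(xb) > 30):
        raise ValueError(
            "quasi-separation detected (saturated fitted log-odds); "
            "outcome is perfectly predicted for some subjects"
        )
    return res


def _nagelkerke(res, y) -> float:
    n = len(y)
    llf, llnull = res.llf, res.llnull
    cox_snell = 1.0 - np.exp((llnull - llf) * 2.0 / n)
    max_r2 = 1.0 - np.exp(llnull * 2.0 / n)
    return float(cox_snell / max_r2) if max_r2 > 0 else np.nan


def logistic_cie(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    candidates: list[str],
    threshold: float = 0.10,
) -> CIEModelReport:
    """Logistic regression with stepwise change-in-estimate selection.

    Fit the crude model outcome ~ exposure; then, in the given candidate
    order, add each candidate to the current working model and record the
    percent change in the exposure odds ratio. Candidates changing the OR by
    at least ``threshold`` (e.g. 10%) are retained as confounders. Reports
    Wald 95% CIs and Nagelkerke pseudo-R^2 for the final model.
    """
    y = table[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome} has a single class")

    def exposure_stats(cols):
        res = _fit_logit(y, table[cols])
        beta = res.params[exposure]
        se = res.bse[exposure]
        ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
        return res, float(np.exp(beta)), ci, float(res.pvalues[exposure])

    res, crude_or, crude_ci, crude_p = exposure_stats([exposure])
    current_cols = [exposure]
    current_or = crude_or
    rows = []
    retained = []
    for cand in candidates:
        _, or_with, _, _ = exposure_stats(current_cols + [cand])
        pct = abs(or_with - current_or) / current_or
        keep = pct >= threshold
        rows.append({"candidate": cand, "pct_change": 100.0 * pct, "retained": keep})
        if keep:
            retained.append(cand)
            current_cols.append(cand)
            current_or = or_with
    final_res, final_or, final_ci, final_p = exposure_stats([exposure] + retained)
    return CIEModelReport(
        outcome=outcome,
        exposure=exposure,
        crude_or=crude_or,
        crude_ci=crude_ci,
        crude_p=crude_p,
        ledger=pd.DataFrame(rows),
        retained=retained,
        final_or=final_or,
        final_ci=final_ci,
        final_p=final_p,
        pseudo_r2=_nagelkerke(final_res, y),
    )


def cohens_kappa(rater1, rater2) -> tuple[float, tuple[float, float]]:
    """Cohen's kappa for two binary raters with a large-sample 95% CI."""
    r1 = np.asarray(rater1).astype(int)
    r2 = np.asarray(rater2).astype(int)
    if r1.shape != r2.shape or r1.size < 2:
        raise ValueError("need two equal-length rating vectors of size >= 2")
    n = r1.size
    p_obs = float((r1 == r2).mean())
    p_exp = 0.0
    for c in (0, 1):
        p_exp += (r1 == c).mean() * (r2 == c).mean()
    if p_exp >= 1.0 - 1e-15:
        raise ValueError("both raters constant and equal: kappa undefined")
    kappa = (p_obs - p_exp) / (1.0 - p_exp)
    se = np.sqrt(p_obs * (1.0 - p_obs) / n) / (1.0 - p_exp)
    ci = (float(kappa - 1.96 * se), float(min(1.0, kappa + 1.96 * se)))
    return float(kappa), ci
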