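"""Follow-up prediction from latent-variable cognition scores.

Count-like follow-up test scores are square-root transformed and then
mapped onto normal quantiles by a rank-based inverse normal transformation
(Blom offset 3/8). Each transformed score is modelled by OLS as

    followup_score ~ LV1 + LV2 + age + sex + education

with standardized coefficients reported per LV and significance assessed
at a Bonferroni-corrected threshold (alpha / number of tests, strict
inequality). Cohort-comparison helpers reproduce the usual Table-1 style
statistics: Pearson chi-squared on 2x2 proportion tables (no continuity
correction) and Welch two-sample t from summary statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from cortexlv.errors import ConfigError, FitError


def transform_scores(raw: np.ndarray, blom_offset: float = 3.0 / 8.0) -> np.ndarray:
    """sqrt then rank-based inverse normal: Phi^-1((rank - c) / (n + 1 - 2c)).

    With the Blom constant c = 3/8 the denominator is n + 1/4. Ties receive
    average ranks; the map is monotone in the input.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ConfigError("scores must be non-negative for the sqrt transform")
    x = np.sqrt(raw)
    n = x.size
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - blom_offset) / (n + 1.0 - 2.0 * blom_offset))


def apply_bonferroni(
    p_values, m: int, alpha: float = 0.05
) -> tuple[np.ndarray, float]:
    """Strict-inequality Bonferroni flags and the corrected threshold."""
    if m < 1:
        raise ConfigError("m must be >= 1")
    threshold = alpha / m
    p = np.asarray(p_values, dtype=float)
    return p < threshold, threshold


def fit_prediction_model(
    followup: pd.DataFrame,
    lv_scores: pd.DataFrame,
    covariates: pd.DataFrame,
    tests: list[str] | None = None,
    alpha: float = 0.05,
    transform: bool = True,
    extra_covariates: list[str] | None = None,
) -> pd.DataFrame:
    """OLS of each (transformed) follow-up score on LV scores + covariates.

    ``followup`` has one column per test (plus subject_id index or column);
    ``lv_scores`` columns LV1, LV2; ``covariates`` columns age_at_imaging,
    sex, education (and any ``extra_covariates``). Complete cases only
    (listwise deletion); the n used per model is reported.

    Returns a tidy report: test, term, beta (standardized), ci_lo, ci_hi,
    p, significant, n.
    """
    fup = followup.set_index("subject_id") if "subject_id" in followup.columns else followup.copy()
    cov = covariates.set_index("subject_id") if "subject_id" in covariates.columns else covariates.copy()
    if tests is None:
        tests = [c for c in fup.columns if c != "time"]
    cov_terms = ["age_at_imaging", "sex", "education"] + (extra_covariates or [])
    lv_terms = list(lv_scores.columns)
    rows = []
    _, threshold = apply_bonferroni([1.0], m=len(tests), alpha=alpha)
    for test in tests:
        df = pd.concat(
            [fup[test].rename("y"), lv_scores, cov[cov_terms]], axis=1, join="inner"
        ).dropna()
        y = df["y"].to_numpy(float)
        if transform:
            y = transform_scores(y)
        Xdf = df[lv_terms + cov_terms].astype(float)
        X = sm.add_constant(Xdf.to_numpy())
        if np.linalg.cond(X) > 1e8:
            raise FitError(f"{test}: collinear design (condition number > 1e8)")
        fit = sm.OLS(y, X).fit()
        sd_y = float(np.std(y, ddof=1))
        names = ["const"] + list(Xdf.columns)
        ci = fit.conf_int()
        for j, name in enumerate(names):
            if name == "const":
                continue
            sd_x = float(Xdf[name].std(ddof=1))
            scale = sd_x / sd_y
            rows.append(
                {
                    "test": test,
                    "term": name,
                    "beta": fit.params[j] * scale,
                    "ci_lo": ci[j, 0] * scale,
                    "ci_hi": ci[j, 1] * scale,
                    "p": fit.pvalues[j],
                    "significant": bool(fit.pvalues[j] < threshold)
                    if name in lv_terms
                    else np.nan,
                    "n": int(df.shape[0]),
                }
            )
    report = pd.DataFrame(rows)
    report.attrs["bonferroni_alpha"] = threshold
    report.attrs["n_tests"] = len(tests)
    return report


# ---------------------------------------------------------------------------
# cohort comparison statistics


def chi_squared_proportions(
    count_a: int, n_a: int, count_b: int, n_b: int
) -> tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) on the 2x2 table."""
    if count_a > n_a or count_b > n_b:
        raise ConfigError("count cannot exceed group size")
    if min(n_a, n_b) <= 0:
        raise ConfigError("group sizes must be positive")
    obs = np.array([[count_a, n_a - count_a], [count_b, n_b - count_b]], float)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def welch_t_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float, float]:
    """Welch two-sample t from summary statistics, sign = group_b - group_a."""
    if sd_a <= 0 or sd_b <= 0:
        raise ConfigError("SDs must be positive")
    res = stats.ttest_ind_from_stats(
        mean_b, sd_b, n_b, mean_a, sd_a, n_a, equal_var=False
    )
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(res.statistic), float(res.pvalue), float(df)


def cohort_comparison(rows: list[dict]) -> pd.DataFrame:
    """Table-1 style comparison from summary rows.

    Each row dict has a ``variable`` name and either counts
    (count_a, n_a, count_b, n_b) -> chi-squared, or summary moments
    (mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> Welch t.
    """
    out = []
    for row in rows:
        if "count_a" in row:
            stat, p = chi_squared_proportions(
                row["count_a"], row["n_a"], row["count_b"], row["n_b"]
            )
            out.append(
                {
                    "variable": row["variable"],
                    "statistic": "chi_squared",
                    "value": stat,
                    "df": 1.0,
                    "p": p,
                }
            )
        else:
            t, p, df = welch_t_from_summary(
                row["mean_a"], row["sd_a"], row["n_a"],
                row["mean_b"], row["sd_b"], row["n_b"],
            )
            out.append(
                {
                    "variable": row["variable"],
                    "statistic": "welch_t",
                    "value": t,
                    "df": df,
                    "p": p,
                }
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# demographic associations of LV scores


def education_on_lv(education: np.ndarray, lv_scores: pd.DataFrame) -> pd.DataFrame:
    """Standardized OLS coefficients of education on the LV scores."""
    y = np.asarray(education, float)
    X = sm.add_constant(lv_scores.to_numpy(float))
    fit = sm.OLS(y, X).fit()
    sd_y = np.std(y, ddof=1)
    rows = []
    for j, name in enumerate(lv_scores.columns, start=1):
        sd_x = float(lv_scores[name].std(ddof=1))
        rows.append(
            {"term": name, "beta": fit.params[j] * sd_x / sd_y, "p": fit.pvalues[j]}
        )
    return pd.DataFrame(rows)


def lv_by_moca_group(
    lv_score: np.ndarray, moca: np.ndarray, threshold: int = 26
) -> tuple[float, float, float]:
    """Welch t of one LV score between MOCA >= threshold and below."""
    lv_score = np.asarray(lv_score, float)
    moca = np.asarray(moca, float)
    lo = lv_score[moca < threshold]
    hi = lv_score[moca >= threshold]
    if lo.size < 2 or hi.size < 2:
        raise FitError("both MOCA groups need at least 2 subjects")
    res = stats.ttest_ind(lo, hi, equal_var=False)
    va, vb = lo.var(ddof=1) / lo.size, hi.var(ddof=1) / hi.size
    df = (va + vb) ** 2 / (
        va**2 / (lo.size - 1) + vb**2 / (hi.size - 1)
    )
    return float(res.statistic), float(res.pvalue), float(df)
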