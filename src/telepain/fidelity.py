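"""Statistical fidelity of a generated cohort against a reference cohort.

Univariate real-vs-fake comparisons variable by variable: Pearson
chi-squared (no continuity correction) for categoricals, Wilcoxon rank-sum
(normal approximation, tie-corrected) and Welch t-tests for numerics, plus a
pooled logistic check that the age effect on the odds of >1 tele-visit is
the same in both data sources (Wald test on the age x source interaction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .cohort import summarize

CATEGORICAL_VARS = ("gender", "site", "bone_mets", "btcp", "neuropathic", "med_gt60")
NUMERIC_VARS = ("age", "ecog", "n_televisits")
REPORT_VARS = ("age", "gender", "ecog", "site", "bone_mets", "btcp", "neuropathic", "med_gt60", "n_televisits")


def chi2_test(table) -> tuple[float, float]:
    """Pearson chi-squared on a 2xk (or rxk) contingency table, without
    Yates continuity correction; returns (statistic, p)."""
    table = np.asarray(table, float)
    if (table < 0).any() or not np.allclose(table, np.rint(table)):
        raise ValueError("table must contain non-negative integer counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    stat, p, _, _ = st.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test; returns (U statistic, p).

    Small samples (pooled n <= 16) use the exact tie-aware permutation
    distribution; larger ones the tie-corrected normal approximation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if len(x) + len(y) <= 16:
        method = st.PermutationMethod(n_resamples=500_000)
    else:
        method = "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mean_test(x, y) -> float:
    """Welch two-sided t-test p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if np.allclose(x.mean(), y.mean()):
            return 1.0
        raise ValueError("both samples degenerate with different means")
    return float(st.ttest_ind(x, y, equal_var=False).pvalue)


@dataclass
class AgeEffect:
    odds_ratio_per_year: float  # exp(age coefficient), pooled
    or_ci: tuple
    age_p: float
    interaction_p: float  # Wald p for age x source


def age_effect(pooled: pd.DataFrame, source_col: str = "source") -> AgeEffect:
    """Logistic fit of outcome on age, data source and their interaction.

    ``pooled`` needs columns age, outcome (one/more) and a binary source
    indicator column (e.g. real vs generated).  Returns the pooled per-year
    odds ratio and the Wald p-value of the interaction (a non-significant
    value means the age effect does not differ by type of data).
    """
    sources = pooled[source_col].unique()
    if len(sources) != 2:
        raise ValueError("pooled cohort must contain exactly two sources")
    y = (pooled["outcome"] == "more").astype(float).to_numpy()
    age = pooled["age"].to_numpy(float)
    src = (pooled[source_col] == sources[1]).astype(float).to_numpy()
    X = sm.add_constant(np.column_stack([age - age.mean(), src, (age - age.mean()) * src]))
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # perfect separation and kin
        raise ValueError(
            "logistic fit failed (possible separation); pool more data or "
            "check the outcome distribution"
        ) from exc
    beta_age = fit.params[1]
    lo, hi = fit.conf_int()[1]
    return AgeEffect(
        odds_ratio_per_year=float(np.exp(beta_age)),
        or_ci=(float(np.exp(lo)), float(np.exp(hi))),
        age_p=float(fit.pvalues[1]),
        interaction_p=float(fit.pvalues[3]),
    )


def _site_table(real: pd.DataFrame, fake: pd.DataFrame) -> np.ndarray | None:
    """Real-vs-fake site contingency table, dropping sites empty in both
    cohorts or absent from one entirely (sparse categories such as kidney and
    melanoma/skin may have zero columns); None if untestable."""
    levels = sorted(set(real["site"]) | set(fake["site"]))
    counts = np.array(
        [[(real["site"] == s).sum() for s in levels], [(fake["site"] == s).sum() for s in levels]],
        dtype=float,
    )
    keep = (counts > 0).all(axis=0)
    counts = counts[:, keep]
    if counts.shape[1] < 2:
        return None
    return counts


def compare_cohorts(real: pd.DataFrame, fake: pd.DataFrame) -> pd.DataFrame:
    """Variable-by-variable comparison report (one row per variable).

    Categorical variables get a Pearson chi-squared test on the real-vs-fake
    contingency table; numerics get a rank-sum test and a Welch t-test (the
    rank-sum p is the primary p-value, the t-test p is reported alongside).
    The per-cohort summary tables are attached as ``report.attrs``.
    """
    for col in REPORT_VARS + ("outcome",):
        if col not in real.columns or col not in fake.columns:
            raise ValueError(f"cohort schema mismatch: missing column {col!r}")
    rows = []
    for var in REPORT_VARS:
        if var in NUMERIC_VARS:
            stat, p = rank_sum_test(real[var], fake[var])
            p_t = mean_test(real[var], fake[var])
            rows.append(
                {"variable": var, "test": "rank-sum", "statistic": stat, "p": p, "p_ttest": p_t}
            )
        elif var == "site":
            tab = _site_table(real, fake)
            if tab is None:
                rows.append({"variable": var, "test": "chi2", "statistic": np.nan, "p": np.nan, "p_ttest": np.nan})
            else:
                stat, p = chi2_test(tab)
                rows.append({"variable": var, "test": "chi2", "statistic": stat, "p": p, "p_ttest": np.nan})
        else:
            levels = sorted(set(real[var]) | set(fake[var]))
            tab = [
                [(real[var] == lev).sum() for lev in levels],
                [(fake[var] == lev).sum() for lev in levels],
            ]
            if len(levels) < 2:
                stat, p = 0.0, 1.0  # identical constant variable in both cohorts
            else:
                stat, p = chi2_test(tab)
            rows.append({"variable": var, "test": "chi2", "statistic": stat, "p": p, "p_ttest": np.nan})
    report = pd.DataFrame(rows)
    report.attrs["summary_real"] = summarize(real)
    report.attrs["summary_fake"] = summarize(fake)
    return report


def format_report(report: pd.DataFrame) -> str:
    """Plain-text rendering of a comparison report."""
    lines = [f"{'variable':<14}{'test':<10}{'statistic':>10}  {'p':>7}"]
    for _, r in report.iterrows():
        stat = "" if np.isnan(r["statistic"]) else f"{r['statistic']:.3f}"
        p = "" if np.isnan(r["p"]) else f"{r['p']:.3f}"
        lines.append(f"{r['variable']:<14}{r['test']:<10}{stat:>10}  {p:>7}")
    return "\n".join(lines)
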