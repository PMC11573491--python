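"""Shared statistical contracts: FDR correction, repeated-measures ANOVA with
Greenhouse-Geisser correction, and thin pinned wrappers over the standard
tests used throughout the pipeline (paired/two-sample t, Wilcoxon rank-sum
and signed-rank, two-sample Kolmogorov-Smirnov, Holm-Sidak).

All wrappers are two-sided; rank tests switch from the exact to the normal
approximation at n = 25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Sample size at which rank tests switch to the normal approximation.
EXACT_TO_NORMAL_N = 25


@dataclass
class TestResult:
    statistic: float
    df: float | tuple
    p_raw: float
    p_adjusted: float | None
    method: str
    correction: str | None = None

    def __post_init__(self) -> None:
        for p in (self.p_raw, self.p_adjusted):
            if p is not None and not (0.0 <= p <= 1.0 or np.isnan(p)):
                raise ValueError(f"p-value {p} outside [0, 1]")


def fdr_by(pvals, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Yekutieli step-up FDR adjustment (valid under arbitrary
    dependence between tests). Returns adjusted p-values, same order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), alpha=alpha, method="fdr_by")[1].reshape(p.shape)


def holm_sidak(pvals, alpha: float = 0.05) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    return multipletests(p.ravel(), alpha=alpha, method="holm-sidak")[1].reshape(p.shape)


def rm_anova_gg(data: pd.DataFrame, dv: str, within, subject: str) -> pd.DataFrame:
    """Repeated-measures ANOVA with Greenhouse-Geisser sphericity correction.

    ``within`` is one factor name or a list of two; the design must be
    balanced (every subject observed in every cell). Returns a tidy table
    with per-effect F, uncorrected and GG-corrected dfs and p-values.
    """
    import pingouin as pg

    if isinstance(within, str):
        within = [within]
    cells = data.groupby([subject, *within], observed=True)[dv].count()
    n_cells = data.groupby(within, observed=True).ngroups
    per_subject = cells.groupby(level=0).count()
    if cells.nunique() > 1 or cells.min() < 1 or per_subject.nunique() > 1 \
            or per_subject.iloc[0] != n_cells:
        raise ValueError("unbalanced design: every subject needs every factor cell")
    # pingouin's internal pivot/melt chokes on short dv/subject names; remap
    work = data[[subject, *within, dv]].rename(
        columns={dv: "dv_value__", subject: "subject_id__"}
    )
    aov = pg.rm_anova(
        data=work, dv="dv_value__", within=list(within), subject="subject_id__",
        correction=True, detailed=True,
    )
    aov.columns = [c.replace("-", "_") for c in aov.columns]
    # one-way detailed output carries dfs as a DF column plus an Error row
    if "ddof1" not in aov.columns:
        err_df = float(aov.loc[aov["Source"] == "Error", "DF"].iloc[0])
        aov = aov[aov["Source"] != "Error"].copy()
        aov["ddof1"] = aov["DF"].astype(float)
        aov["ddof2"] = err_df
    rows = []
    for _, r in aov.iterrows():
        eps = float(r["eps"]) if "eps" in r and np.isfinite(r.get("eps", np.nan)) else 1.0
        df1, df2 = float(r["ddof1"]), float(r["ddof2"])
        p_gg = r.get("p_GG_corr", np.nan)
        if p_gg is None or not np.isfinite(p_gg):
            p_gg = r["p_unc"]  # two-level factor: epsilon = 1, no correction needed
            eps = 1.0
        rows.append(
            {
                "effect": r["Source"],
                "F": float(r["F"]),
                "df1": df1,
                "df2": df2,
                "df1_gg": eps * df1,
                "df2_gg": eps * df2,
                "eps_gg": eps,
                "p_unc": float(r["p_unc"]),
                "p_gg": float(p_gg),
            }
        )
    return pd.DataFrame(rows)


def paired_t(x, y) -> TestResult:
    t, p = sps.ttest_rel(x, y)
    return TestResult(float(t), float(len(np.asarray(x)) - 1), float(p), None, "paired t")


def two_sample_t(x, y) -> TestResult:
    t, p = sps.ttest_ind(x, y)
    return TestResult(float(t), float(len(x) + len(y) - 2), float(p), None, "two-sample t")


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney); exact for small samples."""
    method = "exact" if min(len(x), len(y)) < EXACT_TO_NORMAL_N else "asymptotic"
    try:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:  # ties make the exact method unavailable
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float("nan"), float(res.pvalue), None, "rank-sum")


def wilcoxon_signed_rank(x, y) -> TestResult:
    d = np.asarray(x, float) - np.asarray(y, float)
    if np.allclose(d, 0):
        return TestResult(0.0, float("nan"), 1.0, None, "signed-rank")
    method = "exact" if len(d) < EXACT_TO_NORMAL_N else "approx"
    try:
        res = sps.wilcoxon(x, y, zero_method="wilcox", method=method)
    except ValueError:
        res = sps.wilcoxon(x, y, zero_method="wilcox", method="approx")
    return TestResult(float(res.statistic), float("nan"), float(res.pvalue), None, "signed-rank")


def ks_two_sample(x, y) -> TestResult:
    res = sps.ks_2samp(x, y)
    return TestResult(float(res.statistic), float("nan"), float(res.pvalue), None, "two-sample KS")


def scheffe_pairwise(groups: dict) -> pd.DataFrame:
    """Scheffe post-hoc pairwise comparisons across k independent groups.

    For each pair, ``F_s = (mean_i - mean_j)^2 / (MSE (1/n_i + 1/n_j))``
    is referred to ``(k - 1) F(k-1, N-k)``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    k = len(arrays)
    N = sum(a.size for a in arrays)
    grand = np.concatenate(arrays)
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    mse = sse / (N - k)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            num = (a.mean() - b.mean()) ** 2
            den = mse * (1.0 / a.size + 1.0 / b.size)
            stat = num / den / (k - 1) if den > 0 else np.inf
            p = float(sps.f.sf(stat, k - 1, N - k))
            rows.append({"group_a": names[i], "group_b": names[j], "F": float(stat), "p": p})
    _ = grand  # grand mean not needed beyond SSE bookkeeping
    return pd.DataFrame(rows)
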