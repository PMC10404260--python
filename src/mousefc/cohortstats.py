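"""Cohort-level statistics tying biochemistry to connectivity.

Three-group comparisons of assay values (IDUA enzyme activity, GAG
concentration) and of the global connectivity strength: one-way ANOVA
where its assumptions hold, the tie-corrected Kruskal-Wallis test where
they do not (the mutant IDUA values are all tied at the detection floor,
which both breaks normality/equal variance and exercises the tie
correction), rank-based (Dunn) or Welch post hoc pairwise contrasts, and
the Pearson correlation between cohort-mean GAG and connectivity
strength.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .types import GroupSummary, StatResult


def _as_groups(groups):
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    return gs


def one_way_anova(groups) -> StatResult:
    """Classical one-way ANOVA (pooled within-group variance).

    F = MS_between / MS_within with df = (k-1, N-k).  When every group is
    internally constant but means differ, F is infinite and flagged.
    """
    gs = _as_groups(groups)
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    k = len(gs)
    N = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, N - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return StatResult("one-way ANOVA", 0.0, (df1, df2), 1.0,
                              notes="all values identical")
        return StatResult("one-way ANOVA", float("inf"), (df1, df2),
                          np.finfo(float).tiny,
                          notes="zero within-group variance; infinite F")
    F = (ss_between / df1) / (ss_within / df2)
    return StatResult("one-way ANOVA", float(F), (df1, df2),
                      f_upper_tail(F, df1, df2))


def f_upper_tail(F: float, df1: int, df2: int) -> float:
    """Upper-tail (survival) probability of the F distribution.

    For df1 = 2 this equals the closed form (1 + 2F/df2)^(-df2/2), a
    useful analytic cross-check.
    """
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("need F >= 0 and dfs >= 1")
    return float(stats.f.sf(F, df1, df2))


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail probability of chi-squared; exp(-x/2) when df = 2."""
    if x < 0:
        raise ValueError("need x >= 0")
    return float(stats.chi2.sf(x, df))


def kruskal_wallis(groups) -> StatResult:
    """Kruskal-Wallis H with mid-rank ties and the standard correction
    divisor 1 - sum(t^3 - t)/(N^3 - N); p from chi-squared with k-1 df."""
    gs = _as_groups(groups)
    N = sum(len(g) for g in gs)
    if N < 3:
        raise ValueError("need at least 3 observations in total")
    k = len(gs)
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return StatResult("Kruskal-Wallis", 0.0, (k - 1,), 1.0,
                          notes="all values identical")
    H, p = stats.kruskal(*gs)
    return StatResult("Kruskal-Wallis", float(H), (k - 1,), float(p))


def assumption_gate(groups, alpha: float = 0.05) -> StatResult:
    """Choose ANOVA or Kruskal-Wallis from the data.

    Shapiro-Wilk per group and Levene across groups at ``alpha``; any
    violation (including a zero-variance group, for which normality is
    untestable and homoscedasticity fails by construction) routes to the
    nonparametric branch.  The decision and its reasons are returned in
    ``notes`` and the chosen test's result is embedded in ``posthoc``.
    """
    gs = _as_groups(groups)
    reasons = []
    small = any(len(g) < 3 for g in gs)
    if small:
        reasons.append("group with n < 3: defaulting to Kruskal-Wallis")
    else:
        for i, g in enumerate(gs):
            if np.var(g) == 0.0:
                reasons.append(f"group {i}: zero variance")
                continue
            if stats.shapiro(g).pvalue < alpha:
                reasons.append(f"group {i}: Shapiro-Wilk p < {alpha}")
        if not any(np.var(g) == 0.0 for g in gs):
            if stats.levene(*gs).pvalue < alpha:
                reasons.append(f"Levene p < {alpha}")
    if reasons:
        chosen = kruskal_wallis(gs)
    else:
        chosen = one_way_anova(gs)
    decision = "kruskal_wallis" if reasons else "anova"
    return StatResult(f"assumption_gate:{decision}", chosen.statistic,
                      chosen.df, chosen.p, posthoc={"result": chosen},
                      notes="; ".join(reasons) or "assumptions satisfied")


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def dunn_posthoc(groups) -> dict:
    """Dunn's rank-based pairwise z-tests with pooled tie-corrected
    variance; two-sided p-values, uncorrected."""
    gs = _as_groups(groups)
    N = sum(len(g) for g in gs)
    pooled = np.concatenate(gs)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    pos = 0
    for g in gs:
        mean_ranks.append(ranks[pos:pos + len(g)].mean())
        sizes.append(len(g))
        pos += len(g)
    var_term = (N * (N + 1) / 12.0) - _tie_term(pooled) / (12.0 * (N - 1))
    out = {}
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0.0:
                out[(i, j)] = 1.0
                continue
            z = (mean_ranks[i] - mean_ranks[j]) / se
            out[(i, j)] = float(2.0 * stats.norm.sf(abs(z)))
    return out


def pairwise_posthoc(groups, method: str = "dunn") -> dict:
    """All k(k-1)/2 pairwise contrasts: ``"dunn"`` (rank-based, the
    companion of Kruskal-Wallis) or ``"pairwise-welch"`` t-tests."""
    gs = _as_groups(groups)
    if any(len(g) == 0 for g in gs):
        raise ValueError("empty group")
    if method == "dunn":
        return dunn_posthoc(gs)
    if method == "pairwise-welch":
        out = {}
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                if np.var(gs[i]) == 0.0 and np.var(gs[j]) == 0.0:
                    p = 1.0 if gs[i].mean() == gs[j].mean() else 0.0
                else:
                    p = float(stats.ttest_ind(gs[i], gs[j],
                                              equal_var=False).pvalue)
                out[(i, j)] = p
        return out
    raise ValueError("method must be 'dunn' or 'pairwise-welch'")


def correlation_r2(x, y):
    """Pearson r and R^2 (e.g. cohort-mean GAG vs connectivity strength)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise ValueError("zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def group_summary(values, cohort: str = "") -> GroupSummary:
    """Mean and SEM (sample SD with n-1 denominator over sqrt(n))."""
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    if n < 2:
        return GroupSummary(cohort=cohort, n=n,
                            mean=float(v.mean()) if n else float("nan"),
                            sem=float("nan"))
    return GroupSummary(cohort=cohort, n=n, mean=float(v.mean()),
                        sem=float(v.std(ddof=1) / np.sqrt(n)))
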