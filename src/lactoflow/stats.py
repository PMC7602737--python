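"""Univariate statistics: diet x period two-way ANOVA with Tukey/Sidak
post-hocs, residual diagnostics, t-tests, Pearson correlation, and
percent-change summaries.

Post-hoc conventions follow common practice for a 2 x 3 (diet x period)
design: Tukey's HSD compares the three periods within each diet and
Sidak-adjusted pooled-MSE t-tests compare the two diets within each
period; both use the residual mean square of the full two-way model.
Cells are annotated with letters (diets: a/b within period) and digits
(periods: 1/2/3 within diet) so that groups sharing a symbol do not
differ at alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "two_way_anova",
    "posthoc_tests",
    "assign_letters",
    "diagnostics",
    "students_t",
    "students_t_from_summary",
    "pearson_corr",
    "percent_change",
]

ALPHA = 0.05


@dataclass
class AnovaResult:
    """Two-way ANOVA effects for a single response variable."""

    f_diet: float
    f_period: float
    f_interaction: float
    p_diet: float
    p_period: float
    p_interaction: float
    mse: float
    df_resid: float
    residuals: np.ndarray = field(repr=False, default=None)
    cell_means: pd.Series = field(repr=False, default=None)
    cell_n: pd.Series = field(repr=False, default=None)
    degenerate: bool = False


@dataclass
class PosthocResult:
    """Pairwise post-hoc p-values and per-cell significance symbols."""

    tukey_period: dict[str, pd.DataFrame]  # diet -> period x period p matrix
    sidak_diet: pd.Series  # per period, Sidak-adjusted diet-contrast p
    diet_letters: pd.Series  # (diet, period) -> 'a'/'b'
    period_digits: pd.Series  # (diet, period) -> '1'/'2'/'12'...


def _as_frame(values, diet_labels, period_labels) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "diet": np.asarray(diet_labels),
            "period": np.asarray(period_labels),
        }
    )
    counts = df.groupby(["diet", "period"], observed=True).size()
    full = pd.MultiIndex.from_product([df["diet"].unique(), df["period"].unique()])
    empty = [c for c in full if c not in counts.index or counts.get(c, 0) == 0]
    if empty:
        raise ValueError(f"empty design cell(s): {empty}")
    if (counts < 2).any():
        raise ValueError(
            f"need >= 2 observations per cell; short cells: {list(counts[counts < 2].index)}"
        )
    return df


def two_way_anova(values, diet_labels, period_labels) -> AnovaResult:
    """Diet x period two-way ANOVA with type-II sums of squares.

    Type-II handles the unbalanced Inv1 cells without imposing an ordering
    of the factors.  A fully degenerate response (zero variance anywhere)
    is flagged and returns p = 1 for every effect.
    """
    df = _as_frame(values, diet_labels, period_labels)
    if np.ptp(df["value"].to_numpy()) == 0:
        grp = df.groupby(["diet", "period"], observed=True)["value"]
        return AnovaResult(
            f_diet=0.0, f_period=0.0, f_interaction=0.0,
            p_diet=1.0, p_period=1.0, p_interaction=1.0,
            mse=0.0, df_resid=len(df) - df["diet"].nunique() * df["period"].nunique(),
            residuals=np.zeros(len(df)), cell_means=grp.mean(), cell_n=grp.size(),
            degenerate=True,
        )
    model = smf.ols("value ~ C(diet) * C(period)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    grp = df.groupby(["diet", "period"], observed=True)["value"]
    return AnovaResult(
        f_diet=float(table.loc["C(diet)", "F"]),
        f_period=float(table.loc["C(period)", "F"]),
        f_interaction=float(table.loc["C(diet):C(period)", "F"]),
        p_diet=float(table.loc["C(diet)", "PR(>F)"]),
        p_period=float(table.loc["C(period)", "PR(>F)"]),
        p_interaction=float(table.loc["C(diet):C(period)", "PR(>F)"]),
        mse=float(model.mse_resid),
        df_resid=float(model.df_resid),
        residuals=np.asarray(model.resid),
        cell_means=grp.mean(),
        cell_n=grp.size(),
    )


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment of a raw p-value over m comparisons."""
    return float(1.0 - (1.0 - p) ** m)


def posthoc_tests(values, diet_labels, period_labels, alpha: float = ALPHA) -> PosthocResult:
    """Tukey (periods within diet) and Sidak (diets within period) post-hocs.

    Both families use the pooled residual mean square and residual degrees
    of freedom of the full two-way model (Tukey-Kramer standard errors for
    unequal cell sizes).  The Sidak family size is the number of periods.
    """
    anova = two_way_anova(values, diet_labels, period_labels)
    means, ns = anova.cell_means, anova.cell_n
    diets = sorted(means.index.get_level_values(0).unique())
    periods = sorted(means.index.get_level_values(1).unique())
    mse, dfr = anova.mse, anova.df_resid
    k = len(periods)

    tukey: dict[str, pd.DataFrame] = {}
    for diet in diets:
        pmat = pd.DataFrame(np.ones((k, k)), index=periods, columns=periods)
        for p1, p2 in itertools.combinations(periods, 2):
            if anova.degenerate:
                p = 1.0
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / ns[(diet, p1)] + 1.0 / ns[(diet, p2)]))
                q = abs(means[(diet, p1)] - means[(diet, p2)]) / se
                p = float(sps.studentized_range.sf(q, k, dfr))
            pmat.loc[p1, p2] = pmat.loc[p2, p1] = p
        tukey[diet] = pmat

    if len(diets) != 2:
        raise ValueError("diet post-hoc expects exactly 2 diet levels")
    d1, d2 = diets
    sidak = {}
    for period in periods:
        if anova.degenerate:
            sidak[period] = 1.0
            continue
        se = np.sqrt(mse * (1.0 / ns[(d1, period)] + 1.0 / ns[(d2, period)]))
        t = (means[(d2, period)] - means[(d1, period)]) / se
        raw = 2.0 * sps.t.sf(abs(t), dfr)
        sidak[period] = sidak_adjust(min(raw, 1.0), k)
    sidak = pd.Series(sidak, name="p_sidak")

    diet_letters = {}
    for period in periods:
        distinct = sidak[period] < alpha
        diet_letters[(d1, period)] = "a"
        diet_letters[(d2, period)] = "b" if distinct else "a"
    diet_letters = pd.Series(diet_letters)

    period_digits = {}
    for diet in diets:
        groups = assign_letters(tukey[diet], alpha=alpha, symbols="123456789")
        for period in periods:
            period_digits[(diet, period)] = groups[period]
    period_digits = pd.Series(period_digits)

    return PosthocResult(tukey_period=tukey, sidak_diet=sidak,
                         diet_letters=diet_letters, period_digits=period_digits)


def assign_letters(p_matrix: pd.DataFrame, alpha: float = ALPHA,
                   symbols: str = "abcdefgh") -> dict[str, str]:
    """Compact letter display from a symmetric pairwise p-value matrix.

    Groups sharing a symbol are not significantly different (p >= alpha).
    Uses the insert-and-absorb algorithm over the non-significance graph.
    """
    levels = list(p_matrix.index)
    same = lambda a, b: a == b or p_matrix.loc[a, b] >= alpha
    # enumerate maximal cliques of the "not different" graph (few levels)
    cliques: list[set[str]] = []
    for r in range(len(levels), 0, -1):
        for combo in itertools.combinations(levels, r):
            s = set(combo)
            if all(same(a, b) for a, b in itertools.combinations(combo, 2)):
                if not any(s <= c for c in cliques):
                    cliques.append(s)
    cliques.sort(key=lambda c: min(levels.index(lv) for lv in c))
    out = {lv: "" for lv in levels}
    for sym, clique in zip(symbols, cliques):
        for lv in levels:
            if lv in clique:
                out[lv] += sym
    return out


def diagnostics(residuals, groups) -> tuple[float, float]:
    """Shapiro-Wilk p on pooled residuals and Brown-Forsythe p across groups.

    Brown-Forsythe is the median-centered Levene test, robust to
    non-normality when checking variance homogeneity.
    """
    residuals = np.asarray(residuals, dtype=float)
    groups = np.asarray(groups)
    if residuals.size < 3:
        raise ValueError("need >= 3 residuals for diagnostics")
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need >= 2 groups for the variance test")
    shapiro_p = float(sps.shapiro(residuals).pvalue)
    by_group = [residuals[groups == g] for g in labels]
    if all(np.ptp(g) == 0 for g in by_group if g.size):
        return shapiro_p, 1.0  # identical groups: statistic is 0 by construction
    bf_p = float(sps.levene(*by_group, center="median").pvalue)
    return shapiro_p, bf_p


def students_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def students_t_from_summary(
    mean_a: float, sem_a: float, n_a: int,
    mean_b: float, sem_b: float, n_b: int,
) -> tuple[float, float]:
    """Pooled-variance t-test from published mean +/- SEM summaries."""
    res = sps.ttest_ind_from_stats(
        mean_a, sem_a * np.sqrt(n_a), n_a,
        mean_b, sem_b * np.sqrt(n_b), n_b,
        equal_var=True,
    )
    return float(res.statistic), float(res.pvalue)


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson correlation with the two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def sidak_null_fwer(
    n_sims: int = 2000,
    n_per_cell: int = 6,
    n_periods: int = 3,
    alpha: float = ALPHA,
    seed: int = 0,
) -> float:
    """Observed family-wise error of the Sidak diet post-hocs under the null.

    Simulates ``n_sims`` balanced 2 x n_periods designs with no effects and
    runs the ANOVA + Sidak chain vectorized (identical formulas to
    :func:`posthoc_tests` for balanced data: pooled-MSE t within period,
    Sidak family size = number of periods).  Returns the fraction of
    simulations with at least one adjusted p below alpha — the rate the
    Sidak correction is meant to cap at alpha.
    """
    rng = np.random.default_rng(seed)
    y = rng.standard_normal((n_sims, 2, n_periods, n_per_cell))
    cell_means = y.mean(axis=3)
    ss_within = ((y - cell_means[..., None]) ** 2).sum(axis=(1, 2, 3))
    df_resid = 2 * n_periods * (n_per_cell - 1)
    mse = ss_within / df_resid
    se = np.sqrt(mse[:, None] * 2.0 / n_per_cell)
    t = (cell_means[:, 1] - cell_means[:, 0]) / se
    raw = 2.0 * sps.t.sf(np.abs(t), df_resid)
    adj = 1.0 - (1.0 - raw) ** n_periods
    return float((adj < alpha).any(axis=1).mean())


def percent_change(reference_mean: float, treated_mean: float) -> float:
    """(treated - reference) / reference * 100."""
    if reference_mean == 0:
        raise ValueError("reference mean must be nonzero")
    return (treated_mean - reference_mean) / reference_mean * 100.0
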