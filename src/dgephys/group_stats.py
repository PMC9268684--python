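"""Group-level statistics with normality gating.

The workflow mirrors standard practice for per-neuron firing-rate
comparisons: each group is screened with the D'Agostino–Pearson omnibus
normality test; when all groups look Gaussian, a one-way ANOVA with
Bonferroni-corrected pairwise post hoc t-tests (pooled within-group
variance) is used, otherwise the Kruskal–Wallis test with Dunn's multiple
comparison z-tests (Bonferroni-adjusted).  Two-factor designs use a
two-way ANOVA with type-II sums of squares (robust default for unbalanced
data); repeated measures are handled by adding the subject as a blocking
factor.

The unit of analysis is the neuron; per-animal nesting is reported in the
inputs but not modeled (no mixed effects).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ParameterError, SmallSampleError

__all__ = [
    "PosthocComparison",
    "ComparisonResult",
    "normality_gate",
    "one_way_anova_bonferroni",
    "kruskal_dunn",
    "two_way_anova",
    "compare_firing_by_group",
]

ALPHA_DEFAULT = 0.05
_NORMALITY_MIN_N = 8  # the omnibus test needs n >= 8 per group


@dataclass(frozen=True)
class PosthocComparison:
    """One pairwise post hoc comparison with raw and adjusted p."""

    pair: tuple
    statistic: float
    p_raw: float
    p_adj: float


@dataclass(frozen=True)
class ComparisonResult:
    """Omnibus test plus post hoc comparisons for one measurement."""

    test_name: str
    statistic: float
    p_value: float
    posthoc: list = field(default_factory=list)
    normality_ps: dict | None = None
    alpha: float = ALPHA_DEFAULT
    effects: dict | None = None  # two-way ANOVA: term -> (F, p)

    def posthoc_p(self, a, b) -> float:
        """Adjusted p for the (a, b) pair, order-insensitive."""
        for cmp_ in self.posthoc:
            if set(cmp_.pair) == {a, b}:
                return cmp_.p_adj
        raise KeyError((a, b))


def _split_groups(values, group_labels) -> dict:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ParameterError("values and group_labels must be parallel 1-D series")
    if not np.all(np.isfinite(values)):
        raise ParameterError("values must be finite")
    groups = {g: values[labels == g] for g in pd.unique(labels)}
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    for g, arr in groups.items():
        if arr.size < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 values")
    return groups


def normality_gate(values, group_labels, alpha: float = ALPHA_DEFAULT) -> tuple[dict, bool]:
    """D'Agostino–Pearson omnibus normality p per group; gate passes iff all ≥ alpha.

    Raises :class:`SmallSampleError` when any group has n < 8; callers route
    such data to the nonparametric branch.
    """
    groups = _split_groups(values, group_labels)
    ps = {}
    for g, arr in groups.items():
        if arr.size < _NORMALITY_MIN_N:
            raise SmallSampleError(f"group {g!r} has n={arr.size} < {_NORMALITY_MIN_N}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # kurtosistest small-n warning
            ps[g] = float(stats.normaltest(arr).pvalue)
    return ps, all(p >= alpha for p in ps.values())


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def one_way_anova_bonferroni(
    values, group_labels, alpha: float = ALPHA_DEFAULT, normality_ps: dict | None = None
) -> ComparisonResult:
    """One-way ANOVA with Bonferroni-corrected pairwise post hoc t-tests.

    Post hoc t statistics use the pooled within-group variance (the ANOVA
    mean square error) with N − k degrees of freedom; raw p-values are
    multiplied by the number of pairs and capped at 1.
    """
    groups = _split_groups(values, group_labels)
    arrays = list(groups.values())
    if all(np.ptp(a) == 0 for a in arrays):
        raise DegenerateDataError("zero within-group variance in every group")
    f_stat, p = stats.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_w = n_total - k
    msw = ssw / df_w
    pairs = list(itertools.combinations(groups.keys(), 2))
    posthoc = []
    for a_name, b_name in pairs:
        a, b = groups[a_name], groups[b_name]
        se = np.sqrt(msw * (1.0 / a.size + 1.0 / b.size))
        t = (a.mean() - b.mean()) / se if se > 0 else np.inf * np.sign(a.mean() - b.mean())
        p_raw = 2.0 * stats.t.sf(abs(t), df_w)
        posthoc.append(
            PosthocComparison((a_name, b_name), float(t), float(p_raw), _bonferroni(p_raw, len(pairs)))
        )
    return ComparisonResult(
        "one_way_anova_bonferroni", float(f_stat), float(p), posthoc, normality_ps, alpha
    )


def kruskal_dunn(
    values, group_labels, alpha: float = ALPHA_DEFAULT, normality_ps: dict | None = None
) -> ComparisonResult:
    """Kruskal–Wallis H (tie-corrected) with Dunn's post hoc z-tests.

    Dunn's z for groups i, j compares mean ranks over the pooled sample,

        z = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − Σ(t³−t)/(12(N−1))] (1/n_i + 1/n_j)),

    with two-sided normal p-values Bonferroni-adjusted over all pairs.
    """
    groups = _split_groups(values, group_labels)
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all values identical; ranks are degenerate")
    h_stat, p = stats.kruskal(*groups.values())
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    offsets = np.cumsum([0] + [a.size for a in groups.values()])
    mean_ranks = {
        g: ranks[offsets[i] : offsets[i + 1]].mean() for i, g in enumerate(groups)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_core = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(groups.keys(), 2))
    posthoc = []
    for a_name, b_name in pairs:
        n_a, n_b = groups[a_name].size, groups[b_name].size
        se = np.sqrt(var_core * (1.0 / n_a + 1.0 / n_b))
        z = (mean_ranks[a_name] - mean_ranks[b_name]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        posthoc.append(
            PosthocComparison((a_name, b_name), float(z), float(p_raw), _bonferroni(p_raw, len(pairs)))
        )
    return ComparisonResult("kruskal_dunn", float(h_stat), float(p), posthoc, normality_ps, alpha)


def two_way_anova(
    values,
    factor_a,
    factor_b,
    alpha: float = ALPHA_DEFAULT,
    subject=None,
    posthoc_pairs: list | None = None,
) -> ComparisonResult:
    """Two-way ANOVA (type-II sums of squares) with optional subject blocking.

    Both factors must be fully crossed with at least 2 observations per cell.
    ``effects`` in the result maps each term (factor_a, factor_b,
    interaction) to its (F, p).  The headline statistic/p is the interaction.
    Optional Bonferroni post hoc t-tests on requested cell pairs use the
    pooled residual mean square.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "fa": np.asarray(factor_a), "fb": np.asarray(factor_b)}
    )
    if not np.all(np.isfinite(df["y"])):
        raise ParameterError("values must be finite")
    cells = df.groupby(["fa", "fb"], observed=True).size()
    n_a, n_b = df["fa"].nunique(), df["fb"].nunique()
    if n_a < 2 or n_b < 2:
        raise ParameterError("each factor needs at least 2 levels")
    if len(cells) < n_a * n_b:
        raise ParameterError("empty cell in the two-factor design")
    if (cells < 2).any():
        raise ParameterError("every cell needs at least 2 observations")
    formula = "y ~ C(fa) * C(fb)"
    if subject is not None:
        df["subj"] = np.asarray(subject)
        formula += " + C(subj)"
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    effects = {}
    name_map = {"C(fa)": "factor_a", "C(fb)": "factor_b", "C(fa):C(fb)": "interaction"}
    for term, nice in name_map.items():
        effects[nice] = (float(table.loc[term, "F"]), float(table.loc[term, "PR(>F)"]))
    posthoc = []
    if posthoc_pairs:
        mse = float(fit.mse_resid)
        df_resid = float(fit.df_resid)
        cell_groups = {k: g["y"].to_numpy() for k, g in df.groupby(["fa", "fb"], observed=True)}
        for cell_a, cell_b in posthoc_pairs:
            a, b = cell_groups[tuple(cell_a)], cell_groups[tuple(cell_b)]
            se = np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
            t = (a.mean() - b.mean()) / se
            p_raw = 2.0 * stats.t.sf(abs(t), df_resid)
            posthoc.append(
                PosthocComparison(
                    (tuple(cell_a), tuple(cell_b)), float(t), float(p_raw),
                    _bonferroni(p_raw, len(posthoc_pairs)),
                )
            )
    f_int, p_int = effects["interaction"]
    return ComparisonResult("two_way_anova", f_int, p_int, posthoc, None, alpha, effects)


def compare_firing_by_group(
    labeled_units: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    classes=None,
    value_col: str = "rate_hz",
    group_col: str = "group",
    class_col: str = "cell_class",
) -> tuple[dict, pd.DataFrame]:
    """Per-class group comparison of firing rates with normality routing.

    For each cell class the groups are screened with the normality gate;
    Gaussian-looking data go to ANOVA/Bonferroni, everything else (including
    any group with n < 8) to Kruskal–Wallis/Dunn.  Classes with fewer than
    two represented groups are skipped with a warning.

    Returns (class → ComparisonResult, tidy long-format results table).
    """
    needed = {value_col, group_col, class_col}
    if not needed <= set(labeled_units.columns):
        raise ParameterError(f"labeled table missing columns: {sorted(needed - set(labeled_units.columns))}")
    results: dict = {}
    rows = []
    for cls, sub in labeled_units.groupby(class_col, observed=True):
        sub = sub[np.isfinite(sub[value_col])]
        counts = sub[group_col].value_counts()
        ok_groups = counts[counts >= 2].index
        sub = sub[sub[group_col].isin(ok_groups)]
        if sub[group_col].nunique() < 2:
            warnings.warn(f"class {cls!r}: fewer than 2 groups represented; skipped", stacklevel=2)
            continue
        vals = sub[value_col].to_numpy()
        labels = sub[group_col].to_numpy()
        try:
            normality_ps, gaussian = normality_gate(vals, labels, alpha)
        except SmallSampleError:
            normality_ps, gaussian = None, False
        if gaussian:
            res = one_way_anova_bonferroni(vals, labels, alpha, normality_ps)
        else:
            res = kruskal_dunn(vals, labels, alpha, normality_ps)
        results[cls] = res
        rows.append(
            {"cell_class": cls, "comparison": "omnibus", "test_name": res.test_name,
             "statistic": res.statistic, "p": res.p_value, "p_adj": res.p_value}
        )
        for cmp_ in res.posthoc:
            rows.append(
                {"cell_class": cls, "comparison": f"{cmp_.pair[0]} vs {cmp_.pair[1]}",
                 "test_name": res.test_name, "statistic": cmp_.statistic,
                 "p": cmp_.p_raw, "p_adj": cmp_.p_adj}
            )
    return results, pd.DataFrame(rows)
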