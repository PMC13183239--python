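"""Trait variation across the cultivar hierarchy.

Nested random-effects variance partitioning (REML, with a balanced nested
ANOVA method-of-moments fallback), one-way ANOVA across cultivars with
Tukey HSD post-hoc comparisons, and cultivar mean tables.

The hierarchy is treated as strictly nested: planting row within cultivar
within grape colour (red/white) within origin class. Rows are coded unique
per cultivar so that "row 1" of two cultivars never pools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "AnovaResult",
    "fit_variance_components",
    "anova_tukey",
    "cultivar_means",
]

#: Hierarchy level -> trait-table column holding its labels.
LEVEL_COLUMNS = {
    "origin": "origin",
    "red_white": "colour",
    "cultivar": "cultivar",
    "row": "row",
}

DEFAULT_NESTING = ("origin", "red_white", "cultivar", "row")


@dataclass
class VarianceComponents:
    """Proportion of trait variance per hierarchy level plus residual.

    Proportions are non-negative (negative REML/moment estimates are
    truncated at zero) and normalised to sum to 1.
    """

    trait: str
    proportions: dict[str, float]
    residual: float
    method: str = "reml"
    variances: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {**self.proportions, "residual": self.residual}


def _nested_codes(table: pd.DataFrame, nesting: tuple[str, ...]) -> pd.DataFrame:
    """Recode each level's labels so nesting is explicit (child id prefixed
    by all ancestor ids)."""
    codes = pd.DataFrame(index=table.index)
    prefix = pd.Series("", index=table.index)
    for level in nesting:
        col = LEVEL_COLUMNS[level]
        if col not in table.columns:
            raise KeyError(f"trait table lacks metadata column {col!r} for level {level!r}")
        codes[level] = prefix + table[col].astype(str)
        prefix = codes[level] + "/"
    return codes


def _moments_nested(y: np.ndarray, codes: pd.DataFrame, nesting: tuple[str, ...]) -> dict:
    """Method-of-moments variance components for a (near-)balanced nested design.

    Classical nested ANOVA: mean squares top-down, expected-mean-squares
    solved with average replication numbers. Adequate as a fallback and as
    an independent cross-check on REML; exact for balanced designs.
    """
    df = codes.copy()
    df["_y"] = y
    n = len(df)
    levels = list(nesting)
    # sums of squares between groups at each level, using group means
    ss = {}
    dfree = {}
    grand = df["_y"].mean()
    prev_groups = 1
    for level in levels:
        g = df.groupby(level)["_y"]
        means, counts = g.mean(), g.size()
        # SS of this level's group means around their parent-level means
        if level == levels[0]:
            parent_mean = pd.Series(grand, index=means.index)
        else:
            parent = levels[levels.index(level) - 1]
            pmap = df.drop_duplicates(level).set_index(level)[parent]
            parent_means = df.groupby(parent)["_y"].mean()
            parent_mean = pmap.map(parent_means)
        ss[level] = float((counts * (means - parent_mean.loc[means.index]) ** 2).sum())
        dfree[level] = max(len(means) - prev_groups, 1)
        prev_groups = len(means)
    deepest = levels[-1]
    within = df.groupby(deepest)["_y"]
    ss["residual"] = float(((df["_y"] - within.transform("mean")) ** 2).sum())
    dfree["residual"] = max(n - df[deepest].nunique(), 1)

    ms = {k: ss[k] / dfree[k] for k in ss}
    # average number of observations per unit at each level
    counts = {level: n / codes[level].nunique() for level in levels}
    counts["residual"] = 1.0
    var = {"residual": ms["residual"]}
    # solve EMS bottom-up: MS_level = sigma2_resid + sum_{deeper} n_deeper*sigma2 + n_level*sigma2_level
    order = levels[::-1]
    for i, level in enumerate(order):
        acc = var["residual"]
        for deeper in order[:i]:
            acc += counts[deeper] * var[deeper]
        var[level] = max((ms[level] - acc) / counts[level], 0.0)
    return var


def _reml_nested(y: np.ndarray, codes: pd.DataFrame, nesting: tuple[str, ...]) -> dict:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    data = codes.copy()
    data["_y"] = y
    levels = list(nesting)
    top = levels[0]
    vc = {lvl: f"0 + C({lvl})" for lvl in levels[1:]}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        if vc:
            md = smf.mixedlm("_y ~ 1", data, groups=top, re_formula="1", vc_formula=vc)
        else:
            md = smf.mixedlm("_y ~ 1", data, groups=top, re_formula="1")
        res = md.fit(reml=True)
        if not res.converged:
            # near-flat restricted likelihoods (variances at the zero
            # boundary) defeat the default BFGS; Powell is derivative-free
            # and handles the boundary reliably
            res = md.fit(reml=True, method="powell", maxiter=2000)
        if not res.converged:
            raise FloatingPointError("REML did not converge")
    var = {top: max(float(np.asarray(res.cov_re)[0, 0]), 0.0)}
    vc_names = list(md.exog_vc.names) if vc else []
    for name, v in zip(vc_names, np.asarray(res.vcomp, dtype=float)):
        var[name] = max(float(v), 0.0)
    var["residual"] = max(float(res.scale), 0.0)
    return var


def fit_variance_components(
    table: pd.DataFrame,
    trait: str,
    nesting: tuple[str, ...] = DEFAULT_NESTING,
    method: str = "reml",
) -> VarianceComponents:
    """Partition a trait's variance over the nested cultivar hierarchy.

    ``method='reml'`` fits a random-intercept model per level by restricted
    maximum likelihood; ``'moments'`` uses the nested-ANOVA expected mean
    squares estimator. REML falls back to moments if the optimiser fails.
    Negative estimates are truncated at zero before normalisation, so the
    reported proportions always sum to 1.
    """
    sub = table.dropna(subset=[trait])
    if len(sub) < 10:
        raise ValueError(f"trait {trait!r}: need >= 10 observed values")
    y = sub[trait].to_numpy(dtype=float)
    codes = _nested_codes(sub, nesting)

    # drop degenerate levels (a single unit carries no between-unit variance)
    usable = tuple(l for l in nesting if codes[l].nunique() >= 2)
    if not usable:
        resid = float(np.var(y, ddof=1))
        return VarianceComponents(trait, {l: 0.0 for l in nesting}, 1.0, "degenerate",
                                  {"residual": resid})
    codes = codes[list(usable)]

    used = method
    if method == "reml":
        try:
            var = _reml_nested(y, codes, usable)
            if not all(np.isfinite(v) for v in var.values()):
                raise FloatingPointError("non-finite REML estimate")
        except Exception:
            var = _moments_nested(y, codes, usable)
            used = "moments-fallback"
    elif method == "moments":
        var = _moments_nested(y, codes, usable)
    else:
        raise ValueError(f"unknown method {method!r}")

    total = sum(var.values())
    if total <= 0:
        props = {l: 0.0 for l in nesting}
        return VarianceComponents(trait, props, 1.0, used, var)
    props = {l: var.get(l, 0.0) / total for l in nesting}
    residual = var["residual"] / total
    # normalise exactly (dropped levels contribute 0)
    s = sum(props.values()) + residual
    props = {l: v / s for l, v in props.items()}
    return VarianceComponents(trait, props, residual / s, used, var)


@dataclass
class AnovaResult:
    """One-way ANOVA across cultivars with Tukey HSD pairwise comparisons."""

    trait: str
    f_statistic: float
    p_value: float
    group_means: pd.DataFrame          # cultivar, n, mean, se
    pairwise: pd.DataFrame             # group1, group2, meandiff, p_adj, lower, upper, reject
    degenerate: bool = False


def anova_tukey(table: pd.DataFrame, trait: str, group: str = "cultivar",
                alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA of a trait across cultivars plus Tukey HSD post-hoc.

    The Tukey family is all pairwise cultivar comparisons for this single
    trait (no cross-trait correction). Groups with zero within-group
    variance everywhere yield ``degenerate=True``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sub = table.dropna(subset=[trait])
    groups = [g[trait].to_numpy(dtype=float) for _, g in sub.groupby(group)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 cultivars with >= 2 leaves each")

    gm = (
        sub.groupby(group)[trait]
        .agg(n="count", mean="mean", sd=lambda v: np.std(v, ddof=1))
        .reset_index()
    )
    gm["se"] = gm["sd"] / np.sqrt(gm["n"])
    gm = gm.drop(columns="sd")

    if all(np.ptp(g) == 0 for g in groups):
        pairwise = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"]
        )
        return AnovaResult(trait, float("nan"), float("nan"), gm, pairwise, degenerate=True)

    f, p = stats.f_oneway(*groups)
    tk = pairwise_tukeyhsd(sub[trait].to_numpy(dtype=float),
                           sub[group].to_numpy(), alpha=alpha)
    pairwise = pd.DataFrame(
        tk.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"],
    )
    pairwise["p_adj"] = tk.pvalues  # full precision, not the rounded summary
    return AnovaResult(trait, float(f), float(p), gm, pairwise)


def cultivar_means(table: pd.DataFrame, traits: list[str] | None = None,
                   group: str = "cultivar") -> pd.DataFrame:
    """Per-cultivar mean and standard error for every trait, missing-aware.

    WUE-type ratio traits are averaged over per-leaf ratios (never computed
    as a ratio of cultivar means). A cultivar with a single leaf reports a
    missing standard error.
    """
    from .traits import METADATA_COLUMNS

    if traits is None:
        traits = [c for c in table.columns if c not in METADATA_COLUMNS]
    rows = []
    for cult, g in table.groupby(group):
        for t in traits:
            x = g[t].dropna().to_numpy(dtype=float)
            rows.append(
                {
                    group: cult,
                    "trait": t,
                    "n": x.size,
                    "mean": float(np.mean(x)) if x.size else float("nan"),
                    "se": float(np.std(x, ddof=1) / np.sqrt(x.size))
                    if x.size >= 2
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)
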