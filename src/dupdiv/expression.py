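"""Expression–trait divergence statistics for cultivar panels.

Replicate-level rows are always collapsed to cultivar means first (the
measurements emulate per-cultivar qRT-PCR with technical replicates).  The
module provides per-gene Pearson correlations, an ordinary least squares fit
of trait ~ three gene main effects + three pairwise interaction products,
an LMG relative-importance partition of the trait variance over the main
effects (the average, over all predictor orderings, of each gene's
sequential R^2 increment — reported as percentages), and promoter-genotype
group summaries with pairwise rank-sum comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import TraitTable

__all__ = [
    "CorrelationResult",
    "ModelFit",
    "ContributionResult",
    "pearson_correlation",
    "correlate_expression",
    "fit_trait_model",
    "contribution_partition",
    "genotype_group_summary",
]


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    r: float
    r_squared: float
    n: int
    p_value: float
    defined: bool = True


def pearson_correlation(x, y, label: str = "") -> CorrelationResult:
    """Pearson r with a two-sided t-test p-value.

    Zero-variance input yields a flagged undefined result, not an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 observations for a correlation, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(label, math.nan, math.nan, n, math.nan, defined=False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(label, float(r), float(r) ** 2, n, float(p))


def correlate_expression(table: TraitTable) -> list[CorrelationResult]:
    """Per-gene Pearson correlation of cultivar-mean expression with the trait."""
    means = table.cultivar_means()
    y = means[table.trait].to_numpy()
    return [pearson_correlation(means[g].to_numpy(), y, label=g) for g in table.genes]


@dataclass(frozen=True)
class ModelFit:
    """OLS fit of trait ~ mains + pairwise interactions on cultivar means."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    r_squared: float
    residual_variance: float
    n: int
    terms: list[str]


def _design(means: pd.DataFrame, genes: list[str]) -> tuple[pd.DataFrame, list[str]]:
    X = pd.DataFrame(index=means.index)
    for g in genes:
        X[g] = means[g]
    for a, b in combinations(genes, 2):
        X[f"{a}:{b}"] = means[a] * means[b]
    terms = list(X.columns)
    X.insert(0, "intercept", 1.0)
    return X, terms


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    cols = [c for c in X.columns if c != "intercept"]
    bad = []
    for c in cols:
        others = X.drop(columns=[c]).to_numpy()
        target = X[c].to_numpy()
        resid = target - others @ np.linalg.lstsq(others, target, rcond=None)[0]
        denom = np.linalg.norm(target) or 1.0
        if np.linalg.norm(resid) / denom < 1e-8:
            bad.append(c)
    return bad


def fit_trait_model(table: TraitTable) -> ModelFit:
    """Fit the 7-parameter interaction model by ordinary least squares.

    Requires more cultivars than parameters (>= 8 for 3 genes); a
    rank-deficient design raises an error naming the collinear columns.
    """
    means = table.cultivar_means()
    genes = table.genes
    n_params = 1 + len(genes) + len(genes) * (len(genes) - 1) // 2
    if len(means) <= n_params:
        raise ValueError(
            f"need more cultivars than parameters ({n_params}); got {len(means)}"
        )
    X, terms = _design(means, genes)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"rank-deficient design; collinear columns: {_collinear_columns(X)}")
    y = means[table.trait].to_numpy()
    fit = sm.OLS(y, X).fit()
    resid = y - fit.fittedvalues
    return ModelFit(
        coefficients={k: float(v) for k, v in fit.params.items()},
        std_errors={k: float(v) for k, v in fit.bse.items()},
        r_squared=float(fit.rsquared),
        residual_variance=float(resid @ resid / fit.df_resid),
        n=len(means),
        terms=terms,
    )


@dataclass(frozen=True)
class ContributionResult:
    """LMG variance partition over the main effects.

    contributions are percentages of trait variance per gene; they sum to
    100 x the main-effects-model R^2.  full_model_r2 is the R^2 of the model
    including pairwise interactions, reported separately.
    """

    contributions: dict[str, float]
    main_effects_r2: float
    full_model_r2: float
    n: int
    method: str = "lmg"


def _subset_r2(X: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> float:
    if not cols:
        return 0.0
    design = np.column_stack([np.ones(len(y))] + [X[:, j] for j in cols])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0


def contribution_partition(table: TraitTable) -> ContributionResult:
    """LMG relative importance of each gene's expression for the trait.

    For each of the 3! orderings of the genes, each gene's increment in R^2
    when added after its predecessors is recorded; the LMG share is the mean
    increment over orderings, so the shares telescope to the main-effects R^2.
    """
    means = table.cultivar_means()
    genes = table.genes
    y = means[table.trait].to_numpy(dtype=float)
    X = means[genes].to_numpy(dtype=float)
    full = fit_trait_model(table)  # also validates n and rank

    k = len(genes)
    r2_cache: dict[tuple[int, ...], float] = {}

    def r2(cols: tuple[int, ...]) -> float:
        key = tuple(sorted(cols))
        if key not in r2_cache:
            r2_cache[key] = _subset_r2(X, y, key)
        return r2_cache[key]

    shares = np.zeros(k)
    orders = list(permutations(range(k)))
    for order in orders:
        so_far: tuple[int, ...] = ()
        for j in order:
            inc = r2(so_far + (j,)) - r2(so_far)
            shares[j] += inc
            so_far = so_far + (j,)
    shares /= len(orders)
    return ContributionResult(
        contributions={g: float(100.0 * s) for g, s in zip(genes, shares)},
        main_effects_r2=r2(tuple(range(k))),
        full_model_r2=full.r_squared,
        n=len(means),
    )


def genotype_group_summary(table: TraitTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genotype means/dispersions plus pairwise rank-sum p-values.

    Returns (summary, pairwise): summary has one row per genotype group with
    mean and SD of trait and each gene's expression; pairwise has one row per
    group pair and measured column with the two-sided Mann-Whitney p-value
    (descriptive output; no selection among comparisons is performed).
    """
    if table.genotype is None:
        raise ValueError("trait table has no genotype column")
    means = table.cultivar_means()
    counts = means.groupby(table.genotype)["cultivar"].count()
    groups = [g for g, c in counts.items() if c >= 2]
    if len(groups) < 2:
        raise ValueError("need at least 2 genotype groups with >= 2 cultivars each")
    cols = [table.trait, *table.genes]
    summary = means[means[table.genotype].isin(groups)].groupby(table.genotype)[cols].agg(
        ["mean", "std", "count"]
    )
    rows = []
    for a, b in combinations(groups, 2):
        for col in cols:
            xa = means.loc[means[table.genotype] == a, col]
            xb = means.loc[means[table.genotype] == b, col]
            stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append({"group_a": a, "group_b": b, "measure": col,
                         "statistic": float(stat), "p_value": float(p)})
    return summary, pd.DataFrame(rows)
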