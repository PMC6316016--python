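"""Sliding-window selective-sweep scan over three populations.

Statistics follow the frequency-based, phase-free definitions standard for
windowed scans of resequencing panels:

* per-site nucleotide diversity uses the unbiased estimator
  h = (n/(n-1)) * 2p(1-p) over the n non-missing allele copies; windowed pi
  divides the summed site diversities by the full window length in bp;
* pi ratios contrast an ancestral/background population against the derived
  one (wild vs landrace for domestication, landrace vs improved for
  improvement), so a sweep in the derived population yields a HIGH ratio
  under the default "ancestral-over-derived" orientation;
* Fst is the Hudson ratio-of-sums estimator: 1 - sum(within)/sum(between),
  with within = mean unbiased heterozygosity of the two populations and
  between = p_a(1-p_b) + p_b(1-p_a), summed over sites before dividing;
* outlier tiers are empirical genome-wide quantiles (top 1% / top 5%) over
  all evaluated windows, with >= comparison at the cutoff; a gene region's
  tier per contrast is the highest tier among windows overlapping it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneRegion, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Window",
    "SweepCall",
    "Thresholds",
    "sliding_windows",
    "nucleotide_diversity",
    "pi_ratio",
    "fst_hudson",
    "outlier_thresholds",
    "scan_windows",
    "classify_gene",
    "classify_genes",
    "write_window_stats",
    "write_sweep_calls",
]

DEFAULT_POPULATIONS = ("wild", "landrace", "improved")
TIER_ORDER = {"none": 0, "top5": 1, "top1": 2}


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int


def sliding_windows(chrom_length: int, size: int = 20_000, step: int = 2_000,
                    chrom: str = "chr") -> list[Window]:
    """Tile [0, chrom_length) with windows [k*step, k*step + size).

    Yields floor((L - size)/step) + 1 windows; a chromosome shorter than one
    window yields the single truncated window [0, L).
    """
    if chrom_length <= 0 or size <= 0 or step <= 0:
        raise ValueError("chrom_length, size and step must be positive")
    if chrom_length < size:
        return [Window(chrom, 0, chrom_length)]
    n = (chrom_length - size) // step + 1
    return [Window(chrom, k * step, k * step + size) for k in range(n)]


def _site_stats(matrix: GenotypeMatrix, pop: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (allele copies n, alt frequency p, unbiased heterozygosity h)."""
    idx = matrix.sample_indices(pop)
    calls = matrix.calls[:, idx].astype(np.float64)
    missing = calls < 0
    n = 2.0 * (~missing).sum(axis=1)
    ac = np.where(missing, 0.0, calls).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, ac / np.maximum(n, 1.0), np.nan)
        h = np.where(n >= 2, (n / np.maximum(n - 1.0, 1.0)) * 2.0 * p * (1.0 - p), 0.0)
    return n, p, np.nan_to_num(h)


def _window_slice(positions: np.ndarray, window: Window) -> slice:
    lo = int(np.searchsorted(positions, window.start, side="left"))
    hi = int(np.searchsorted(positions, window.end, side="left"))
    return slice(lo, hi)


def nucleotide_diversity(matrix: GenotypeMatrix, population: str, window: Window) -> float:
    """Windowed pi: summed per-site unbiased diversity over window length in bp.

    Sites where fewer than 2 allele copies are callable in the population are
    skipped (contribute 0).
    """
    _, _, h = _site_stats(matrix, population)
    sl = _window_slice(matrix.positions, window)
    return float(h[sl].sum()) / (window.end - window.start)


def pi_ratio(pi_num: float, pi_den: float, pseudocount: float = 1e-6) -> float:
    """(pi_num + c)/(pi_den + c); NaN when both are zero and c = 0."""
    if pi_num < 0 or pi_den < 0:
        raise ValueError("pi values must be non-negative")
    if pi_num + pseudocount == 0 and pi_den + pseudocount == 0:
        return float("nan")
    if pi_den + pseudocount == 0:
        return float("inf")
    return (pi_num + pseudocount) / (pi_den + pseudocount)


def fst_hudson(matrix: GenotypeMatrix, pop_a: str, pop_b: str, window: Window) -> float:
    """Hudson ratio-of-sums Fst for one window; NaN when no usable sites.

    May be slightly negative near zero differentiation.
    """
    n_a, p_a, h_a = _site_stats(matrix, pop_a)
    n_b, p_b, h_b = _site_stats(matrix, pop_b)
    sl = _window_slice(matrix.positions, window)
    usable = (n_a[sl] >= 2) & (n_b[sl] >= 2)
    if not usable.any():
        return float("nan")
    within = ((h_a[sl] + h_b[sl]) / 2.0)[usable]
    between = (p_a[sl] * (1.0 - p_b[sl]) + p_b[sl] * (1.0 - p_a[sl]))[usable]
    den = float(between.sum())
    if den == 0.0:
        return float("nan")
    return 1.0 - float(within.sum()) / den


@dataclass(frozen=True)
class Thresholds:
    """Empirical quantile cutoffs over evaluated windows (linear interpolation)."""

    cutoffs: dict[float, float]
    n_windows: int
    degenerate: bool
    method: str = "linear"


def outlier_thresholds(stat_values, quantiles=(0.95, 0.99), min_windows: int = 20) -> Thresholds:
    """Genome-wide empirical cutoffs; a window is an outlier if stat >= cutoff.

    An all-equal distribution is flagged degenerate: no outlier calls should
    be emitted from it.
    """
    values = np.asarray(stat_values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < min_windows:
        raise ValueError(
            f"need at least {min_windows} evaluated windows for empirical thresholds, "
            f"got {len(values)}"
        )
    degenerate = bool(values.max() == values.min())
    cutoffs = {float(q): float(np.quantile(values, q, method="linear")) for q in quantiles}
    return Thresholds(cutoffs=cutoffs, n_windows=len(values), degenerate=degenerate)


def scan_windows(
    matrix: GenotypeMatrix,
    window_size: int = 20_000,
    step: int = 2_000,
    populations: tuple[str, str, str] = DEFAULT_POPULATIONS,
    min_snps: int = 3,
    pseudocount: float = 1e-6,
    orientation: str = "ancestral-over-derived",
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Compute per-window pi, pi ratios and pairwise Fst for the whole scan.

    populations is ordered (ancestral, intermediate, derived) — by default
    (wild, landrace, improved).  Windows with fewer than min_snps SNPs are
    flagged evaluated=False and excluded from downstream ranking.
    """
    if orientation not in ("ancestral-over-derived", "derived-over-ancestral"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if chrom_length is None:
        chrom_length = matrix.chrom_length
    if chrom_length is None:
        chrom_length = int(matrix.positions[-1]) + 1 if matrix.n_sites else 1
    windows = sliding_windows(chrom_length, window_size, step, chrom=matrix.chrom)
    anc, mid, der = populations
    stats = {pop: _site_stats(matrix, pop) for pop in populations}

    pos = matrix.positions
    # cumulative per-site quantities for O(1) window sums
    def cum(x: np.ndarray) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(x)])

    h_cum = {pop: cum(stats[pop][2]) for pop in populations}
    fst_parts = {}
    for pa, pb in ((anc, mid), (mid, der)):
        n_a, p_a, h_a = stats[pa]
        n_b, p_b, h_b = stats[pb]
        usable = (n_a >= 2) & (n_b >= 2)
        within = np.where(usable, (h_a + h_b) / 2.0, 0.0)
        between = np.where(usable, p_a * (1.0 - p_b) + p_b * (1.0 - p_a), 0.0)
        fst_parts[(pa, pb)] = (cum(np.nan_to_num(within)), cum(np.nan_to_num(between)))

    starts = np.array([w.start for w in windows])
    ends = np.array([w.end for w in windows])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="left")
    n_snps = hi - lo
    lengths = (ends - starts).astype(float)

    out = pd.DataFrame({
        "chrom": matrix.chrom,
        "start": starts,
        "end": ends,
        "n_snps": n_snps,
    })
    pis = {}
    for pop in populations:
        pi = (h_cum[pop][hi] - h_cum[pop][lo]) / lengths
        pis[pop] = pi
        out[f"pi_{pop}"] = pi

    if orientation == "ancestral-over-derived":
        ratio_dom = (pis[anc] + pseudocount) / (pis[mid] + pseudocount)
        ratio_imp = (pis[mid] + pseudocount) / (pis[der] + pseudocount)
    else:
        ratio_dom = (pis[mid] + pseudocount) / (pis[anc] + pseudocount)
        ratio_imp = (pis[der] + pseudocount) / (pis[mid] + pseudocount)
    out["ratio_dom"] = ratio_dom
    out["ratio_imp"] = ratio_imp

    for (pa, pb), (w_cum, b_cum) in fst_parts.items():
        within = w_cum[hi] - w_cum[lo]
        between = b_cum[hi] - b_cum[lo]
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = np.where(between > 0, 1.0 - within / np.where(between > 0, between, 1.0), np.nan)
        out[f"fst_{pa}_{pb}"] = fst

    out["evaluated"] = n_snps >= min_snps
    out.attrs["orientation"] = orientation
    out.attrs["pseudocount"] = pseudocount
    out.attrs["populations"] = populations
    return out


@dataclass(frozen=True)
class SweepCall:
    """Selection classification for one gene region.

    Tiers are per contrast: domestication uses the wild-vs-landrace pi ratio,
    improvement the landrace-vs-improved ratio.  top1 implies top5.
    """

    gene: GeneRegion
    domestication_tier: str
    improvement_tier: str
    n_windows: int
    supporting: dict[str, list[int]] = field(default_factory=dict)


def _tier(values: np.ndarray, thresholds: Thresholds) -> tuple[str, list[int], list[int]]:
    if thresholds.degenerate or len(values) == 0:
        return "none", [], []
    qs = sorted(thresholds.cutoffs)  # e.g. [0.95, 0.99]
    top5_idx = [int(i) for i in np.where(values >= thresholds.cutoffs[qs[0]])[0]]
    top1_idx = [int(i) for i in np.where(values >= thresholds.cutoffs[qs[-1]])[0]]
    if top1_idx:
        return "top1", top1_idx, top5_idx
    if top5_idx:
        return "top5", top1_idx, top5_idx
    return "none", [], []


def classify_gene(
    gene: GeneRegion,
    window_stats: pd.DataFrame,
    thresholds_dom: Thresholds,
    thresholds_imp: Thresholds,
) -> SweepCall:
    """Classify one gene: highest tier among evaluated windows overlapping it."""
    mask = (
        (window_stats["chrom"] == gene.chrom)
        & (window_stats["start"] < gene.end)
        & (window_stats["end"] > gene.start)
        & window_stats["evaluated"]
    )
    overlapping = window_stats.loc[mask]
    if overlapping.empty:
        logger.warning("gene %s: no overlapping evaluated window", gene.name)
        return SweepCall(gene, "none", "none", 0)
    idx = overlapping.index.to_numpy()
    dom_tier, dom1, dom5 = _tier(overlapping["ratio_dom"].to_numpy(), thresholds_dom)
    imp_tier, imp1, imp5 = _tier(overlapping["ratio_imp"].to_numpy(), thresholds_imp)
    supporting = {
        "dom_top1": [int(idx[i]) for i in dom1],
        "dom_top5": [int(idx[i]) for i in dom5],
        "imp_top1": [int(idx[i]) for i in imp1],
        "imp_top5": [int(idx[i]) for i in imp5],
    }
    return SweepCall(gene, dom_tier, imp_tier, len(overlapping), supporting)


def classify_genes(
    window_stats: pd.DataFrame,
    genes: list[GeneRegion],
    top: tuple[float, float] = (0.01, 0.05),
) -> list[SweepCall]:
    """Derive genome-wide thresholds and classify each gene region.

    top gives the outlier fractions (default top 1% and top 5%), converted to
    the empirical quantiles 1 - fraction.
    """
    quantiles = tuple(sorted(1.0 - f for f in top))
    evaluated = window_stats.loc[window_stats["evaluated"]]
    thr_dom = outlier_thresholds(evaluated["ratio_dom"], quantiles)
    thr_imp = outlier_thresholds(evaluated["ratio_imp"], quantiles)
    return [classify_gene(g, window_stats, thr_dom, thr_imp) for g in genes]


def write_window_stats(window_stats: pd.DataFrame, path) -> None:
    window_stats.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_sweep_calls(calls: list[SweepCall], path) -> None:
    rows = [
        {
            "gene": c.gene.name,
            "chrom": c.gene.chrom,
            "start": c.gene.start,
            "end": c.gene.end,
            "domestication_tier": c.domestication_tier,
            "improvement_tier": c.improvement_tier,
            "n_windows": c.n_windows,
        }
        for c in calls
    ]
    columns = ["gene", "chrom", "start", "end", "domestication_tier",
               "improvement_tier", "n_windows"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
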