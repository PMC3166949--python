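"""Two-group SAM significance analysis for very small replicate numbers.

The statistic is the relative difference d = (mean2 - mean1) / (s + s0),
where s is the Tusher-form pooled scatter

    s = sqrt( (1/n1 + 1/n2) / (n1 + n2 - 2) * (SS1 + SS2) )

(SS = within-group sum of squared deviations) and s0 is a small positive
"fudge factor" that stabilizes d for genes whose scatter happens to be
tiny.  The null distribution is generated by permuting the group labels —
exhaustively whenever the number of distinct relabelings is small (a
duplicate-vs-duplicate design has only C(4,2) = 6, identity included) —
and significance is declared by the Delta-threshold rule on the sorted d
versus the permutation-averaged order statistics, with the false
discovery rate estimated as the median null exceedance count over the
number of genes called.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "S0Method",
    "SamConfig",
    "SamResult",
    "InsufficientReplicatesError",
    "DegenerateScatterError",
    "pooled_scatter",
    "relative_difference",
    "estimate_s0",
    "permutation_null",
    "call_significant",
    "choose_delta",
    "sam_two_group",
]


class InsufficientReplicatesError(ValueError):
    """SAM needs at least two members per group."""


class DegenerateScatterError(ValueError):
    """s + s0 = 0 with unequal means: d is undefined."""


class S0Method(Enum):
    CV_MINIMIZING_PERCENTILE = "cv_minimizing_percentile"
    FIXED_PERCENTILE = "fixed_percentile"
    MEDIAN = "median"


@dataclass(frozen=True)
class SamConfig:
    """Tunables for the SAM run.

    s0_percentile_grid : candidate percentiles of the s distribution tried
        by the CV-minimizing search (default 0, 0.05, ..., 1.0).
    fixed_percentile : the single percentile used by FIXED_PERCENTILE.
    delta : the call threshold; None lets the run pick the smallest grid
        value reaching ``target_fdr``.
    max_enumerated_permutations : exhaustive enumeration is used when the
        number of distinct relabelings is at most this; beyond it, that
        many relabelings are sampled uniformly with ``seed``.
    log2_input : compute d on log2(signal + 1) instead of the signal scale.
    """

    s0_method: S0Method = S0Method.CV_MINIMIZING_PERCENTILE
    s0_percentile_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))
    fixed_percentile: float = 0.05
    delta: float | None = None
    target_fdr: float = 0.05
    max_enumerated_permutations: int = 1000
    seed: int = 0
    log2_input: bool = False

    def __post_init__(self) -> None:
        if self.delta is not None and self.delta < 0:
            raise ValueError("delta must be non-negative")
        if any(not 0 <= p <= 1 for p in self.s0_percentile_grid):
            raise ValueError("s0 percentile grid values must lie in [0, 1]")


@dataclass
class SamResult:
    """Per-gene d and s, the chosen s0 and Delta, the permutation null,
    the called set and its estimated FDR."""

    d: pd.Series
    s: pd.Series
    s0: float
    delta: float
    null_expected: np.ndarray        # mean i-th order statistic of null d
    null_d: np.ndarray               # (n_permutations, n_genes) null d values
    called: pd.Series
    estimated_fdr: float
    cutoff_low: float
    cutoff_up: float

    @property
    def n_called(self) -> int:
        return int(self.called.sum())


# --- elementary statistics -------------------------------------------------

def pooled_scatter(group1: Sequence[float], group2: Sequence[float]) -> float:
    """Tusher-form pooled scatter of two groups (gene-specific s)."""
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError(
            f"SAM requires >=2 replicates per group, got {n1} and {n2}"
        )
    ss = np.sum((x1 - x1.mean()) ** 2) + np.sum((x2 - x2.mean()) ** 2)
    return math.sqrt((1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2) * ss)


def relative_difference(
    group1: Sequence[float], group2: Sequence[float], s0: float
) -> float:
    """Relative difference d = (mean2 - mean1) / (s + s0)."""
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    diff = x2.mean() - x1.mean()
    s = pooled_scatter(group1, group2)
    denom = s + s0
    if denom == 0:
        if diff == 0:
            return 0.0
        raise DegenerateScatterError("zero scatter and zero s0 with unequal means")
    return float(diff / denom)


def _scatter_vector(block1: np.ndarray, block2: np.ndarray) -> np.ndarray:
    """Per-gene pooled scatter for (genes x replicates) blocks."""
    n1, n2 = block1.shape[1], block2.shape[1]
    ss = ((block1 - block1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((block2 - block2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2) * ss)


def _d_vector(block1: np.ndarray, block2: np.ndarray, s0: float) -> np.ndarray:
    diff = block2.mean(axis=1) - block1.mean(axis=1)
    denom = _scatter_vector(block1, block2) + s0
    d = np.zeros_like(diff)
    ok = denom > 0
    d[ok] = diff[ok] / denom[ok]
    if np.any(~ok & (diff != 0)):
        raise DegenerateScatterError(
            "zero scatter with zero s0 and unequal means for some gene"
        )
    return d


# --- fudge factor ----------------------------------------------------------

def estimate_s0(
    scatters: Sequence[float],
    diffs: Sequence[float] | None = None,
    config: SamConfig | None = None,
) -> float:
    """Pick the fudge factor s0 from the distribution of per-gene scatters.

    CV_MINIMIZING_PERCENTILE (default) follows the classic recipe: for
    each candidate percentile of the s distribution, compute d with that
    s0, measure the spread (MAD) of d within quantile windows of s, and
    keep the candidate that minimizes the coefficient of variation of
    those spreads — i.e. the s0 that makes the scale of d most uniform
    across the scatter range.  Ties break toward the smallest percentile.
    Requires ``diffs`` (per-gene mean differences).
    """
    config = config or SamConfig()
    s = np.asarray(scatters, dtype=float)
    if s.size == 0:
        raise ValueError("empty scatter list")
    if config.s0_method is S0Method.MEDIAN:
        return float(np.median(s))
    if config.s0_method is S0Method.FIXED_PERCENTILE:
        return float(np.quantile(s, config.fixed_percentile))
    if diffs is None:
        raise ValueError("CV-minimizing s0 estimation requires the per-gene mean differences")
    diff = np.asarray(diffs, dtype=float)
    if diff.shape != s.shape:
        raise ValueError("diffs and scatters must have equal length")
    if np.allclose(s, s[0]):
        return float(s[0])
    grid = sorted(config.s0_percentile_grid)
    best_s0 = float(np.quantile(s, grid[0]))
    best_cv = np.inf
    edges = _window_edges(s)
    for alpha in grid:
        candidate = float(np.quantile(s, alpha))
        cv = _window_cv(diff, s, candidate, edges)
        if cv < best_cv - 1e-12:
            best_cv = cv
            best_s0 = candidate
    return best_s0


def _window_edges(s: np.ndarray, n_windows: int = 0) -> np.ndarray:
    """Quantile-window edges over the s distribution (about 20 genes/window,
    at most 100 windows)."""
    if n_windows <= 0:
        n_windows = int(min(100, max(2, s.size // 20)))
    return np.quantile(s, np.linspace(0.0, 1.0, n_windows + 1))


def _window_cv(diff: np.ndarray, s: np.ndarray, s0: float, edges: np.ndarray) -> float:
    d = np.where(s + s0 > 0, diff / np.where(s + s0 > 0, s + s0, 1.0), 0.0)
    idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, len(edges) - 2)
    mads = []
    for w in range(len(edges) - 1):
        dw = d[idx == w]
        if dw.size == 0:
            continue
        mads.append(np.median(np.abs(dw - np.median(dw))) / 0.6745)
    mads = np.asarray(mads)
    mean = mads.mean()
    if mean == 0:
        return np.inf
    return float(mads.std(ddof=1) / mean) if mads.size > 1 else np.inf


# --- permutation null ------------------------------------------------------

def _label_splits(
    n1: int, n2: int, config: SamConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """All (or sampled) assignments of the pooled columns to a group of
    size n1 and a group of size n2; the identity split comes first."""
    n = n1 + n2
    total = math.comb(n, n1)
    indices = np.arange(n)
    if total <= config.max_enumerated_permutations:
        splits = []
        for combo in combinations(range(n), n1):
            g1 = np.asarray(combo)
            g2 = np.asarray([i for i in indices if i not in combo])
            splits.append((g1, g2))
        return splits
    rng = np.random.default_rng(config.seed)
    splits = [(indices[:n1], indices[n1:])]  # identity labelling always included
    for _ in range(config.max_enumerated_permutations - 1):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[:n1]), np.sort(perm[n1:])))
    return splits


def permutation_null(
    block1: np.ndarray, block2: np.ndarray, s0: float, config: SamConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation null for the relative difference.

    ``block1``/``block2`` are (genes x replicates) arrays.  Returns
    ``(expected, null_d)``: ``expected[i]`` is the mean of the i-th order
    statistic of d across relabelings, and ``null_d`` holds the unsorted
    per-permutation d values, one row per relabeling.
    """
    config = config or SamConfig()
    n1, n2 = block1.shape[1], block2.shape[1]
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError(
            f"permutation null requires >=2 replicates per group, got {n1} and {n2}"
        )
    pooled = np.concatenate([block1, block2], axis=1)
    splits = _label_splits(n1, n2, config)
    null_d = np.empty((len(splits), pooled.shape[0]))
    for k, (g1, g2) in enumerate(splits):
        null_d[k] = _d_vector(pooled[:, g1], pooled[:, g2], s0)
    expected = np.sort(null_d, axis=1).mean(axis=0)
    return expected, null_d


# --- Delta-threshold calls -------------------------------------------------

def _cutoffs(
    d: np.ndarray, expected: np.ndarray, delta: float
) -> tuple[float, float]:
    """Find the lower/upper d cutoffs for a given Delta.

    Observed d is sorted and paired with the null order-statistic
    expectations; the upper cutoff is the smallest positive d(i) whose
    excess d(i) - dbar(i) reaches Delta, the lower cutoff the largest
    negative d(i) whose deficit reaches Delta.
    """
    order = np.argsort(d, kind="stable")
    ds = d[order]
    excess = ds - expected
    up_candidates = ds[(ds > 0) & (excess >= delta)]
    cutoff_up = float(up_candidates.min()) if up_candidates.size else np.inf
    low_candidates = ds[(ds < 0) & (-excess >= delta)]
    cutoff_low = float(low_candidates.max()) if low_candidates.size else -np.inf
    return cutoff_low, cutoff_up


def call_significant(
    d: Sequence[float],
    null_expected: np.ndarray,
    null_d: np.ndarray,
    delta: float,
) -> tuple[np.ndarray, float, float, float]:
    """Apply the Delta-threshold rule.

    Returns ``(called, estimated_fdr, cutoff_low, cutoff_up)``.  Genes
    beyond either cutoff are called; the FDR estimate is the median, over
    permutations, of the count of null d values beyond the cutoffs,
    divided by the number called (0 by convention when nothing is called).
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] != null_expected.shape[0]:
        raise ValueError("d and null expectations must have equal length")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    cutoff_low, cutoff_up = _cutoffs(d, null_expected, delta)
    called = (d >= cutoff_up) | (d <= cutoff_low)
    n_called = int(called.sum())
    if n_called == 0:
        return called, 0.0, cutoff_low, cutoff_up
    null_counts = ((null_d >= cutoff_up) | (null_d <= cutoff_low)).sum(axis=1)
    fdr = float(np.median(null_counts)) / n_called
    return called, fdr, cutoff_low, cutoff_up


def choose_delta(
    d: Sequence[float],
    null_expected: np.ndarray,
    null_d: np.ndarray,
    target_fdr: float = 0.05,
    n_grid: int = 60,
) -> float:
    """Smallest Delta on an even grid whose estimated FDR is at most
    ``target_fdr``.  The grid spans [0, max |d(i) - dbar(i)|]; if no grid
    value qualifies, the grid maximum (which calls nothing) is returned.
    """
    d = np.asarray(d, dtype=float)
    order = np.argsort(d, kind="stable")
    max_gap = float(np.max(np.abs(d[order] - null_expected))) if d.size else 0.0
    grid = np.linspace(0.0, max_gap * (1 + 1e-9), n_grid)
    for delta in grid:
        _, fdr, *_ = call_significant(d, null_expected, null_d, float(delta))
        if fdr <= target_fdr:
            return float(delta)
    return float(grid[-1]) if grid.size else 0.0


# --- end-to-end ------------------------------------------------------------

def sam_two_group(
    matrix: ExpressionMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    config: SamConfig | None = None,
) -> SamResult:
    """Run the full SAM procedure between two sample-column groups.

    d is positive when group2's mean exceeds group1's.  By default d is
    computed on the signal scale (downstream factors are ratio-based);
    set ``log2_input`` to analyse log2(signal + 1) instead.
    """
    config = config or SamConfig()
    missing = [sid for sid in [*group1, *group2] if sid not in matrix.data.columns]
    if missing:
        raise KeyError(f"samples not in matrix: {missing}")
    block1 = matrix.data[list(group1)].to_numpy(dtype=float)
    block2 = matrix.data[list(group2)].to_numpy(dtype=float)
    if config.log2_input:
        block1 = np.log2(block1 + 1.0)
        block2 = np.log2(block2 + 1.0)
    if block1.shape[1] < 2 or block2.shape[1] < 2:
        raise InsufficientReplicatesError(
            "SAM requires >=2 replicates per group; use factor-only analysis otherwise"
        )
    s = _scatter_vector(block1, block2)
    diffs = block2.mean(axis=1) - block1.mean(axis=1)
    s0 = estimate_s0(s, diffs, config)
    d = _d_vector(block1, block2, s0)
    null_expected, null_d = permutation_null(block1, block2, s0, config)
    delta = config.delta
    if delta is None:
        delta = choose_delta(d, null_expected, null_d, config.target_fdr)
    called, fdr, cutoff_low, cutoff_up = call_significant(d, null_expected, null_d, delta)
    genes = matrix.data.index
    logger.info(
        "SAM: s0=%.4g delta=%.4g called %d/%d genes (est. FDR %.3g)",
        s0, delta, int(called.sum()), len(genes), fdr,
    )
    return SamResult(
        d=pd.Series(d, index=genes, name="d"),
        s=pd.Series(s, index=genes, name="s"),
        s0=s0,
        delta=float(delta),
        null_expected=null_expected,
        null_d=null_d,
        called=pd.Series(called, index=genes, name="called"),
        estimated_fdr=fdr,
        cutoff_low=cutoff_low,
        cutoff_up=cutoff_up,
    )
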