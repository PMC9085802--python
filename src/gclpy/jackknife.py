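"""Jackknife re-sampling of the GCL and its stability analysis.

Because a single GCL value carries no uncertainty, the statistic is
re-computed on ``s`` random subsets of ``k`` cells, yielding a stability
distribution. The standard deviation sigma(GCL) of that distribution
decays like 1/k while subsets barely overlap (the finite-size regime) and
collapses rapidly as k approaches the cohort size M (the overlap regime);
the crossover k* between the two regimes — empirically about 75% of M —
is the recommended subset size.  A gene-wise shuffled copy of the data
provides the no-coordination null (GCL = 0 on average).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import gcl, make_partitions
from .matrix import ExpressionMatrix

__all__ = [
    "JackknifeDistribution",
    "SigmaCurve",
    "jackknife_gcl",
    "shuffle_expression",
    "sigma_vs_k",
    "estimate_kstar",
]


@dataclass
class JackknifeDistribution:
    """GCL values of s random k-cell subsets of one cohort."""

    values: np.ndarray
    k: int
    s: int
    m: int
    fraction: float
    seed: object = None

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sigma(self) -> float:
        """Sample standard deviation (ddof=1) of the subset GCL values."""
        if self.s < 2 or np.all(self.values == self.values[0]):
            return 0.0  # identical subsets (k = M): exactly zero, no float dust
        return float(self.values.std(ddof=1))

    @property
    def stderr(self) -> float:
        return self.sigma / np.sqrt(self.s)


@dataclass
class SigmaCurve:
    """sigma(GCL) and mean GCL per jackknife subset size k."""

    k_grid: np.ndarray
    sigma: np.ndarray
    mean_gcl: np.ndarray
    M: int


def jackknife_gcl(
    X: ExpressionMatrix, k: int, s: int = 100, m: int = 50, rng=None
) -> JackknifeDistribution:
    """GCL distribution over ``s`` random subsets of ``k`` cells.

    Subsets are drawn independently of each other (a cell may recur
    across subsets) but without replacement within a subset, so no subset
    contains duplicate cells.  All subsets share one set of ``m`` random
    gene divisions: with k = M every subset is then the full cohort and
    the distribution collapses to a single value.
    """
    if not 4 <= k <= X.n_cells:
        raise ValueError(f"k must be in [4, {X.n_cells}], got {k}")
    if s < 1:
        raise ValueError("s must be >= 1")
    rng = np.random.default_rng(rng)
    rng_subsets, rng_divisions = rng.spawn(2)
    partitions = make_partitions(X.n_genes, m, rng_divisions)
    values = np.empty(s)
    for idx in range(s):
        subset = rng_subsets.choice(X.n_cells, size=k, replace=False)
        values[idx] = gcl(X.select_cells(np.sort(subset)), partitions=partitions).gcl
    return JackknifeDistribution(
        values=values, k=k, s=s, m=m, fraction=k / X.n_cells, seed=rng
    )


def shuffle_expression(X: ExpressionMatrix, rng=None) -> ExpressionMatrix:
    """Gene-wise permutation null: shuffle each gene independently across cells.

    Destroys every gene-gene relationship while preserving each gene's
    marginal value multiset exactly; the GCL of the result averages 0.
    """
    rng = np.random.default_rng(rng)
    shuffled = X.values.copy()
    for g in range(X.n_genes):
        shuffled[g] = shuffled[g, rng.permutation(X.n_cells)]
    return ExpressionMatrix(shuffled, X.gene_ids.copy(), X.cell_ids.copy())


def sigma_vs_k(
    X: ExpressionMatrix, k_grid, s: int = 100, m: int = 50, rng=None
) -> SigmaCurve:
    """Jackknife sigma(GCL) and mean GCL across a grid of subset sizes."""
    rng = np.random.default_rng(rng)
    k_grid = np.asarray(sorted(int(k) for k in k_grid))
    if k_grid[0] < 4 or k_grid[-1] > X.n_cells:
        raise ValueError("k_grid must lie within [4, M]")
    sigma = np.empty(len(k_grid))
    mean = np.empty(len(k_grid))
    for i, (k, child) in enumerate(zip(k_grid, rng.spawn(len(k_grid)))):
        dist = jackknife_gcl(X, int(k), s=s, m=m, rng=child)
        sigma[i] = dist.sigma
        mean[i] = dist.mean
    return SigmaCurve(k_grid=k_grid, sigma=sigma, mean_gcl=mean, M=X.n_cells)


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS fit y = a + b x; returns (a, b, sse)."""
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def estimate_kstar(curve: SigmaCurve) -> tuple[int, float]:
    """Crossover subset size k* of the sigma(GCL) decay, with the left slope.

    Fits a two-segment piecewise-linear model in (log k, log sigma) by
    exhaustive search over interior breakpoints (the breakpoint belongs
    to both segments), minimizing the total squared error. Returns the
    breakpoint k* and the slope of the left (finite-size) segment —
    expected near -1.  Grid points with non-positive sigma are dropped
    with a warning.
    """
    keep = curve.sigma > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} grid point(s) with non-positive sigma",
            stacklevel=2,
        )
    logk = np.log(curve.k_grid[keep].astype(float))
    logs = np.log(curve.sigma[keep])
    n = len(logk)
    if n < 6:
        raise ValueError("need at least 6 usable grid points to fit a breakpoint")
    best = None
    for j in range(2, n - 2):  # breakpoint shared by both segments
        _, slope_l, sse_l = _fit_line(logk[: j + 1], logs[: j + 1])
        _, _, sse_r = _fit_line(logk[j:], logs[j:])
        sse = sse_l + sse_r
        if best is None or sse < best[0]:
            best = (sse, j, slope_l)
    _, j, slope_left = best
    return int(round(np.exp(logk[j]))), slope_left
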