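"""Bias-corrected distance correlation and the GCL statistic.

The Global Coordination Level (GCL) of an expression matrix is the mean
bias-corrected distance correlation (bcdCorr) between two random
complementary halves of the gene set, averaged over ``m`` independent
random bisections.  bcdCorr is the unbiased-dCov refinement of the
Szekely--Rizzo distance correlation: under independence it fluctuates
around zero (it may be negative), and it is unbiased with respect to the
dimensionality of either block, so unequal halves for odd gene counts are
valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .matrix import ExpressionMatrix

__all__ = [
    "DegenerateBlockError",
    "GenePartition",
    "GCLResult",
    "bcdcorr",
    "random_bisection",
    "make_partitions",
    "gcl",
]


class DegenerateBlockError(ValueError):
    """A block whose distance covariance with itself is not positive.

    Raised instead of silently returning NaN: a degenerate block (for
    example one whose columns are all identical) makes the correlation
    undefined, and a silent NaN would poison jackknife means downstream.
    """


@dataclass(frozen=True)
class GenePartition:
    """A random bisection of gene indices into two complementary groups.

    ``group_g`` holds floor(N/2) indices, ``group_gbar`` the remaining
    ceil(N/2); the two are disjoint and together cover every gene.
    """

    group_g: np.ndarray
    group_gbar: np.ndarray


@dataclass
class GCLResult:
    """GCL value together with its per-division bcdCorr values."""

    gcl: float
    per_division: np.ndarray
    m: int
    seed: object = None


def _ucentered(dist: np.ndarray) -> np.ndarray:
    """Bias-corrected U-centering of a pairwise distance matrix.

    Off-diagonal: (M/(M-1)) * (A_ij - a_ij/M) with A the double-centered
    matrix; diagonal: (M/(M-1)) * (row_mean_i - grand_mean).
    """
    m = dist.shape[0]
    row = dist.mean(axis=1)
    grand = dist.mean()
    a_centered = dist - row[:, None] - row[None, :] + grand
    out = (m / (m - 1.0)) * (a_centered - dist / m)
    np.fill_diagonal(out, (m / (m - 1.0)) * (row - grand))
    return out


def _dcov(astar: np.ndarray, bstar: np.ndarray) -> float:
    """Unbiased distance covariance from two U-centered matrices."""
    m = astar.shape[0]
    total = float(np.sum(astar * bstar))
    diag = float(np.sum(np.diagonal(astar) * np.diagonal(bstar)))
    return (total - (m / (m - 2.0)) * diag) / (m * (m - 3.0))


def _pairwise(block: np.ndarray) -> np.ndarray:
    # columns are samples
    return squareform(pdist(block.T, metric="euclidean"))


def bcdcorr(block_x: np.ndarray, block_y: np.ndarray) -> float:
    """Bias-corrected distance correlation between two multivariate samples.

    Parameters
    ----------
    block_x, block_y
        Arrays of shape ``(p, M)`` and ``(q, M)``: ``M`` joint observations
        of a p- and a q-dimensional variable, stored column-wise. ``p`` and
        ``q`` need not be equal.

    Returns
    -------
    float
        dCov(X, Y) / sqrt(dCov(X, X) * dCov(Y, Y)) built from the unbiased
        dCov estimator. Bounded above by 1 (up to rounding); may be
        slightly negative under independence.

    Raises
    ------
    ValueError
        If fewer than 4 samples are given (the estimator divides by M-3),
        if the column counts differ, or entries are not finite.
    DegenerateBlockError
        If either block's self distance covariance is not positive.
    """
    block_x = np.atleast_2d(np.asarray(block_x, dtype=float))
    block_y = np.atleast_2d(np.asarray(block_y, dtype=float))
    if block_x.shape[1] != block_y.shape[1]:
        raise ValueError("blocks must share the number of samples (columns)")
    m = block_x.shape[1]
    if m < 4:
        raise ValueError("insufficient samples for unbiased estimator (need M >= 4)")
    if not (np.all(np.isfinite(block_x)) and np.all(np.isfinite(block_y))):
        raise ValueError("blocks must not contain non-finite entries")

    astar = _ucentered(_pairwise(block_x))
    bstar = _ucentered(_pairwise(block_y))
    dxy = _dcov(astar, bstar)
    dxx = _dcov(astar, astar)
    dyy = _dcov(bstar, bstar)
    if dxx <= 0 or dyy <= 0:
        raise DegenerateBlockError(
            "undefined correlation: degenerate block with non-positive "
            f"self distance covariance (dCov(X,X)={dxx:.3e}, dCov(Y,Y)={dyy:.3e})"
        )
    return dxy / np.sqrt(dxx * dyy)


def random_bisection(n_genes: int, rng: np.random.Generator) -> GenePartition:
    """Uniformly random split of ``n_genes`` indices into two halves.

    The first group gets floor(N/2) genes, the second the rest; no gene is
    dropped for odd N (the estimator is dimension-unbiased, so unequal
    blocks are valid).
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes to bisect")
    perm = rng.permutation(n_genes)
    half = n_genes // 2
    return GenePartition(np.sort(perm[:half]), np.sort(perm[half:]))


def make_partitions(n_genes: int, m: int, rng) -> list[GenePartition]:
    """Draw ``m`` independent random bisections, one RNG substream each."""
    rng = np.random.default_rng(rng)
    return [random_bisection(n_genes, child) for child in rng.spawn(m)]


def gcl(
    X: ExpressionMatrix | np.ndarray,
    m: int = 50,
    rng=None,
    partitions: list[GenePartition] | None = None,
) -> GCLResult:
    """Global Coordination Level of an expression matrix.

    Computes bcdCorr between the two halves of ``m`` independent random
    gene bisections and returns their mean.  Pass ``partitions`` to reuse
    a fixed division set (e.g. to compare cohorts under identical
    divisions and suppress division-sampling noise).

    Parameters
    ----------
    X
        Expression matrix (genes x cells) with at least 2 genes and 4 cells.
    m
        Number of random gene bisections to average over.
    rng
        Seed or ``numpy.random.Generator``; required unless ``partitions``
        is given. Results are reproducible per division: division k uses
        an independently spawned substream.
    partitions
        Optional pre-drawn bisections; overrides ``m`` and ``rng``.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    n_genes, n_cells = values.shape
    if n_cells < 4:
        raise ValueError("GCL needs at least 4 cells")
    if partitions is None:
        if m < 1:
            raise ValueError("m must be >= 1")
        partitions = make_partitions(n_genes, m, rng)
    per_division = np.empty(len(partitions))
    for k, part in enumerate(partitions):
        try:
            per_division[k] = bcdcorr(values[part.group_g], values[part.group_gbar])
        except (ValueError, DegenerateBlockError) as err:
            raise type(err)(f"division {k}: {err}") from err
    return GCLResult(
        gcl=float(per_division.mean()),
        per_division=per_division,
        m=len(partitions),
        seed=rng,
    )
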