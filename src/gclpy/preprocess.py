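"""Cohort pre-processing for GCL analysis.

Implements the recommended pipeline around the GCL statistic: selection of
the top expressed genes, Spearman-dissimilarity geometry between cells,
outlier/inlier detection via the 2-standard-deviation rule, per-cell
influence on the GCL, synthetic cell interpolation, and cluster detection
with silhouette-based selection of the cluster count.

The GCL is meant for homogeneous cohorts: a few abnormal cells (outliers
far from everything, or "inliers" — near-duplicate pairs) or the presence
of distinct clusters spuriously inflate it (a Simpson's-paradox effect),
so these are detected and removed first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, spearmanr
from sklearn.cluster import KMeans

from .core import gcl, make_partitions
from .matrix import ExpressionMatrix

__all__ = [
    "DissimilarityMatrix",
    "AbnormalCellReport",
    "ClusterAssignment",
    "DeltaGCLRecord",
    "filter_top_genes",
    "spearman_dissimilarity",
    "detect_abnormal_cells",
    "delta_gcl",
    "interpolate_cell",
    "kmeans_spearman",
    "silhouette",
    "optimal_clusters",
]

#: relative tolerance for the a_i == b_i silhouette branch
_SIL_TOL = 1e-12


@dataclass
class DissimilarityMatrix:
    """Symmetric cell-to-cell Spearman dissimilarity, d = 1 - rho, in [0, 2]."""

    values: np.ndarray
    cell_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (unordered pair) distances as a flat vector."""
        iu = np.triu_indices(self.n_cells, k=1)
        return self.values[iu]


@dataclass
class AbnormalCellReport:
    """Outcome of the 2-SD outlier/inlier screen."""

    min_distance: np.ndarray
    mean_distance: float
    sd_distance: float
    outlier_flags: np.ndarray
    inlier_pairs: list[tuple]
    removed_cells: list
    n_sd: float = 2.0

    @property
    def upper_threshold(self) -> float:
        return self.mean_distance + self.n_sd * self.sd_distance

    @property
    def lower_threshold(self) -> float:
        return self.mean_distance - self.n_sd * self.sd_distance


@dataclass
class ClusterAssignment:
    """k-means labels with per-cell silhouettes and the cohort score S."""

    labels: np.ndarray
    K: int
    s_per_cell: np.ndarray
    S: float
    a_i: np.ndarray
    b_i: np.ndarray
    cell_ids: np.ndarray
    scores_by_k: dict[int, float] = field(default_factory=dict)

    def is_clustered(self, threshold: float = 0.25) -> bool:
        """Whether the silhouette supports splitting the cohort at all."""
        return self.S >= threshold


@dataclass
class DeltaGCLRecord:
    """Relative effect of one cell on the cohort GCL (paired divisions)."""

    cell_id: object
    delta: float
    gcl_with: float
    gcl_without: float


def filter_top_genes(X: ExpressionMatrix, n_top: int) -> ExpressionMatrix:
    """Keep the ``n_top`` genes with the largest mean expression.

    Ties are broken by gene label order; cell order is preserved.
    """
    if n_top > X.n_genes:
        raise ValueError(f"n_top={n_top} exceeds the {X.n_genes} genes available")
    means = X.values.mean(axis=1)
    label_rank = np.argsort(np.argsort(X.gene_ids))
    # sort by (-mean, label): stable deterministic tie-break
    order = np.lexsort((label_rank, -means))[:n_top]
    return X.select_genes(np.sort(order))


def spearman_dissimilarity(X: ExpressionMatrix) -> DissimilarityMatrix:
    """Pairwise cell dissimilarity d_ij = 1 - SpearmanRho(cell i, cell j).

    Ranks use average-rank tie handling. A cell whose profile is constant
    has no defined rank correlation and raises an error naming the cell.
    """
    vals = X.values
    if X.n_cells < 2:
        raise ValueError("need at least 2 cells")
    spans = vals.max(axis=0) - vals.min(axis=0)
    if np.any(spans == 0):
        j = int(np.argmax(spans == 0))
        raise ValueError(
            f"cell {X.cell_ids[j]!r} has a constant expression profile; "
            "Spearman correlation is undefined"
        )
    rho = spearmanr(vals).statistic
    rho = np.atleast_2d(rho) if np.ndim(rho) == 0 else rho
    if rho.shape != (X.n_cells, X.n_cells):  # M == 2 returns a scalar
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
    d = 1.0 - rho
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d, X.cell_ids.copy())


def detect_abnormal_cells(D: DissimilarityMatrix, n_sd: float = 2.0) -> AbnormalCellReport:
    """Flag outliers and inlier pairs by the n_sd-standard-deviation rule.

    Thresholds come from the distribution of all M(M-1)/2 pairwise
    dissimilarities. A cell is an *outlier* when its minimal distance to
    any other cell exceeds mean + n_sd*SD; a pair of cells are *inliers*
    when their mutual distance falls below mean - n_sd*SD (two abnormally
    similar cells). ``removed_cells`` lists every outlier plus, per inlier
    pair, greedily the member participating in the most sub-threshold
    pairs (ties by cell label) until all pairs are covered — removing one
    member of a near-duplicate pair suffices to restore homogeneity.
    """
    m = D.n_cells
    if m < 4:
        raise ValueError("need at least 4 cells to calibrate the 2-SD rule")
    pair_d = D.offdiag()
    mean_d = float(pair_d.mean())
    sd_d = float(pair_d.std(ddof=1))
    hi = mean_d + n_sd * sd_d
    lo = mean_d - n_sd * sd_d

    offdiag = D.values + np.diag(np.full(m, np.inf))
    min_dist = offdiag.min(axis=1)
    outlier_flags = min_dist > hi

    iu, ju = np.triu_indices(m, k=1)
    low_mask = D.values[iu, ju] < lo
    inlier_pairs_idx = list(zip(iu[low_mask].tolist(), ju[low_mask].tolist()))

    # greedy cover: remove the cell in the most uncovered pairs
    removed_idx: list[int] = []
    uncovered = list(inlier_pairs_idx)
    while uncovered:
        counts: dict[int, int] = {}
        for i, j in uncovered:
            counts[i] = counts.get(i, 0) + 1
            counts[j] = counts.get(j, 0) + 1
        pick = min(counts, key=lambda c: (-counts[c], str(D.cell_ids[c])))
        removed_idx.append(pick)
        uncovered = [p for p in uncovered if pick not in p]

    removed = set(removed_idx) | set(np.nonzero(outlier_flags)[0].tolist())
    removed_cells = [D.cell_ids[i] for i in sorted(removed)]
    inlier_pairs = [(D.cell_ids[i], D.cell_ids[j]) for i, j in inlier_pairs_idx]
    return AbnormalCellReport(
        min_distance=min_dist,
        mean_distance=mean_d,
        sd_distance=sd_d,
        outlier_flags=outlier_flags,
        inlier_pairs=inlier_pairs,
        removed_cells=removed_cells,
        n_sd=n_sd,
    )


def delta_gcl(X: ExpressionMatrix, cell, m: int = 50, rng=None) -> DeltaGCLRecord:
    """Relative effect of one cell on the cohort GCL.

    delta = (GCL with cell - GCL without cell) / (GCL with cell).
    Both evaluations reuse the *same* gene divisions so that the
    difference reflects the cell, not division-sampling noise. Abnormal
    cells (outliers and inliers) tend to inflate the GCL, giving a
    positive delta.
    """
    if X.n_cells < 5:
        raise ValueError("need at least 5 cells (both cohorts must have >= 4)")
    parts = make_partitions(X.n_genes, m, rng)
    with_cell = gcl(X, partitions=parts).gcl
    without = gcl(X.drop_cells([cell]), partitions=parts).gcl
    if with_cell == 0:
        raise ZeroDivisionError("relative effect undefined: cohort GCL is 0")
    return DeltaGCLRecord(
        cell_id=cell,
        delta=(with_cell - without) / with_cell,
        gcl_with=with_cell,
        gcl_without=without,
    )


def interpolate_cell(cell_a: np.ndarray, cell_b: np.ndarray, lam: float) -> np.ndarray:
    """Synthetic cell on the segment between two cells: (1-lam)*a + lam*b.

    lam = 0 reproduces ``cell_a`` exactly, lam = 1 reproduces ``cell_b``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    cell_a = np.asarray(cell_a, dtype=float)
    cell_b = np.asarray(cell_b, dtype=float)
    if cell_a.shape != cell_b.shape:
        raise ValueError("cells must have equal length")
    return (1.0 - lam) * cell_a + lam * cell_b


def kmeans_spearman(X: ExpressionMatrix, K: int, n_init: int = 10, rng=None) -> np.ndarray:
    """k-means on per-cell rank profiles (Spearman geometry), 1-based labels.

    Each cell's profile is rank-transformed across genes; squared Euclidean
    distance between rank vectors is an affine function of the Spearman
    dissimilarity, so Lloyd's algorithm in rank space clusters by Spearman
    geometry.  Best of ``n_init`` restarts by within-cluster inertia.
    """
    if not 2 <= K < X.n_cells:
        raise ValueError("need 2 <= K < number of cells")
    ranks = rankdata(X.values, axis=0).T  # cells x genes
    seed = int(np.random.default_rng(rng).integers(2**31 - 1))
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    return km.fit_predict(ranks) + 1


def silhouette(D: DissimilarityMatrix, labels) -> ClusterAssignment:
    """Per-cell silhouette scores and their cohort mean S.

    For cell i in cluster C_k: a_i is its mean distance to the other
    members of C_k, b_i the smallest mean distance to any other cluster;
    s_i = 1 - a_i/b_i when a_i < b_i, b_i/a_i - 1 when a_i > b_i, and 0
    when they coincide (relative tolerance 1e-12). Cells in singleton
    clusters have no defined a_i and get s_i = 0.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs K >= 2 nonempty clusters")
    m = D.n_cells
    a = np.zeros(m)
    b = np.zeros(m)
    s = np.zeros(m)
    for i in range(m):
        own = labels == labels[i]
        n_own = own.sum()
        others = [
            D.values[i, labels == lab].mean() for lab in uniq if lab != labels[i]
        ]
        b[i] = min(others)
        if n_own == 1:
            a[i] = np.nan  # singleton: undefined, s stays 0
            continue
        mask = own.copy()
        mask[i] = False
        a[i] = D.values[i, mask].mean()
        if np.isclose(a[i], b[i], rtol=_SIL_TOL, atol=0.0):
            s[i] = 0.0
        elif a[i] < b[i]:
            s[i] = 1.0 - a[i] / b[i]
        else:
            s[i] = b[i] / a[i] - 1.0
    relabel = {lab: k + 1 for k, lab in enumerate(uniq)}
    labels_norm = np.array([relabel[lab] for lab in labels])
    return ClusterAssignment(
        labels=labels_norm,
        K=len(uniq),
        s_per_cell=s,
        S=float(s.mean()),
        a_i=a,
        b_i=b,
        cell_ids=D.cell_ids.copy(),
    )


def optimal_clusters(
    X: ExpressionMatrix,
    k_range=range(2, 10),
    n_init: int = 10,
    rng=None,
    D: DissimilarityMatrix | None = None,
) -> ClusterAssignment:
    """Pick the cluster count K maximizing the mean silhouette S^K.

    Runs ``kmeans_spearman`` for each K in ``k_range`` (each with
    ``n_init`` restarts), scores with the Spearman-dissimilarity
    silhouette, and returns the best assignment. ``scores_by_k`` carries
    S^K for every K, so callers can declare "no clusters" when even the
    best score is weak (see :meth:`ClusterAssignment.is_clustered`).
    """
    rng = np.random.default_rng(rng)
    if D is None:
        D = spearman_dissimilarity(X)
    best: ClusterAssignment | None = None
    scores: dict[int, float] = {}
    for K in k_range:
        if K >= X.n_cells:
            break
        labels = kmeans_spearman(X, K, n_init=n_init, rng=rng.spawn(1)[0])
        assign = silhouette(D, labels)
        scores[K] = assign.S
        if best is None or assign.S > best.S:
            best = assign
    if best is None:
        raise ValueError("empty k_range")
    best.scores_by_k = scores
    return best
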