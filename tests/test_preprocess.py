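"""Unit tests for gene filtering, dissimilarity geometry, abnormal-cell
screening, per-cell GCL influence, and cluster detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gclpy as g

from conftest import coordinated_cohort, homogeneous_cohort
from oracles import spearman_dissimilarity_reference


class TestFilterTopGenes:
    def test_identity_when_keeping_all(self, rng):
        x = g.ExpressionMatrix(rng.random((5, 4)))
        out = g.filter_top_genes(x, 5)
        assert np.array_equal(out.values, x.values)
        assert np.array_equal(out.gene_ids, x.gene_ids)

    def test_keeps_largest_means(self):
        x = g.ExpressionMatrix(
            np.array([[5.0, 5.0], [1.0, 1.0], [3.0, 3.0]]),
            gene_ids=["g1", "g2", "g3"],
        )
        out = g.filter_top_genes(x, 2)
        assert list(out.gene_ids) == ["g1", "g3"]

    def test_matches_sort_oracle(self, rng):
        x = g.ExpressionMatrix(rng.random((100, 20)))
        out = g.filter_top_genes(x, 30)
        expected = set(
            x.gene_ids[np.argsort(x.values.mean(axis=1))[::-1][:30]]
        )
        assert set(out.gene_ids) == expected

    def test_rejects_too_many(self, rng):
        with pytest.raises(ValueError):
            g.filter_top_genes(g.ExpressionMatrix(rng.random((3, 4))), 4)


class TestSpearmanDissimilarity:
    def test_duplicate_cells_distance_zero(self, rng):
        col = rng.random(20)
        x = g.ExpressionMatrix(np.column_stack([col, col, rng.random(20)]))
        d = g.spearman_dissimilarity(x)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_ranks_distance_two(self):
        a = np.arange(10.0)
        x = g.ExpressionMatrix(np.column_stack([a, a[::-1]]))
        d = g.spearman_dissimilarity(x)
        assert d.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_rank_pearson_oracle(self, rng):
        x = g.ExpressionMatrix(rng.random((50, 10)))
        d = g.spearman_dissimilarity(x)
        ref = np.array(spearman_dissimilarity_reference(x.values))
        assert np.allclose(d.values, ref, atol=1e-12)

    def test_constant_profile_rejected(self, rng):
        vals = rng.random((10, 3))
        vals[:, 1] = 2.0
        with pytest.raises(ValueError, match="cell_0001"):
            g.spearman_dissimilarity(g.ExpressionMatrix(vals))


class TestDetectAbnormalCells:
    def test_duplicate_cell_flagged_as_inlier_pair(self):
        x = homogeneous_cohort(3, n_cells=40)
        vals = np.column_stack([x.values, x.values[:, 0]])
        dup = g.ExpressionMatrix(vals)
        report = g.detect_abnormal_cells(g.spearman_dissimilarity(dup))
        pair_ids = {frozenset(p) for p in report.inlier_pairs}
        assert frozenset({dup.cell_ids[0], dup.cell_ids[40]}) in pair_ids
        # exactly one member of the duplicate pair removed
        assert len({dup.cell_ids[0], dup.cell_ids[40]} & set(report.removed_cells)) == 1

    def test_rank_permuted_cell_flagged_as_outlier(self, rng):
        x = coordinated_cohort(4, n_genes=200, n_cells=40)
        vals = x.values.copy()
        vals[:, 5] = rng.permutation(vals[:, 5])
        report = g.detect_abnormal_cells(
            g.spearman_dissimilarity(g.ExpressionMatrix(vals))
        )
        assert report.outlier_flags[5]
        assert x.cell_ids[5] in report.removed_cells

    def test_null_cohorts_rarely_flag_outliers(self):
        # MC-calibrated on right-skewed homogeneous cohorts: the
        # min-distance outlier rule stays quiet; the inlier rule flags at
        # most a few percent of cells (it thresholds a quantile).
        n_out, n_removed = [], []
        for seed in range(10):
            x = homogeneous_cohort(2000 + seed)
            rep = g.detect_abnormal_cells(g.spearman_dissimilarity(x))
            n_out.append(int(rep.outlier_flags.sum()))
            n_removed.append(len(rep.removed_cells))
        assert sum(n_out) == 0
        assert max(n_removed) <= 10  # <= ~15% of 60 cells, typical 5-10%

    def test_scale_free(self):
        x = homogeneous_cohort(17)
        r1 = g.detect_abnormal_cells(g.spearman_dissimilarity(x))
        scaled = g.ExpressionMatrix(x.values * 37.5)
        r2 = g.detect_abnormal_cells(g.spearman_dissimilarity(scaled))
        assert np.array_equal(r1.outlier_flags, r2.outlier_flags)
        assert list(r1.removed_cells) == list(r2.removed_cells)

    def test_thresholds_from_all_pairs(self):
        x = homogeneous_cohort(5)
        d = g.spearman_dissimilarity(x)
        rep = g.detect_abnormal_cells(d)
        pairs = d.offdiag()
        assert rep.mean_distance == pytest.approx(pairs.mean())
        assert rep.sd_distance == pytest.approx(pairs.std(ddof=1))


class TestDeltaGCL:
    def test_injected_outlier_increases_gcl(self, rng):
        x = coordinated_cohort(8, n_genes=80, n_cells=25, noise=1.0)
        vals = x.values.copy()
        # distant incoherent cell: permuted profile, inflated magnitude
        vals[:, 0] = rng.permutation(vals[:, 0]) * 5
        cohort = g.ExpressionMatrix(vals)
        rec = g.delta_gcl(cohort, cohort.cell_ids[0], m=20, rng=31)
        assert rec.delta > 0
        assert rec.delta == pytest.approx(
            (rec.gcl_with - rec.gcl_without) / rec.gcl_with
        )

    def test_duplicate_cell_in_shuffled_data_small_effect(self, rng):
        x = homogeneous_cohort(9, n_genes=100, n_cells=80)
        shuffled = g.shuffle_expression(x, rng)
        rec = g.delta_gcl(shuffled, shuffled.cell_ids[3], m=20, rng=32)
        # paired divisions: the single-cell effect is tiny at large M
        assert abs(rec.gcl_with - rec.gcl_without) < 0.02

    def test_removing_flagged_cells_does_not_inflate_gcl(self):
        """Over replicate cohorts with injected abnormal cells, filtering
        the flagged cells lowers (or leaves) the cohort GCL on average."""
        diffs = []
        for seed in range(20):
            r = np.random.default_rng(3000 + seed)
            x = coordinated_cohort(seed, n_genes=60, n_cells=25, noise=1.0)
            vals = x.values.copy()
            vals[:, 1] = vals[:, 0]  # inlier pair
            vals[:, 2] = r.permutation(vals[:, 2]) * 3  # distant incoherent pairmate
            vals[:, 3] = vals[:, 2] * r.lognormal(0, 0.05, size=vals.shape[0])
            cohort = g.ExpressionMatrix(vals)
            screen = g.detect_abnormal_cells(g.spearman_dissimilarity(cohort))
            if not screen.removed_cells:
                continue
            parts = g.make_partitions(cohort.n_genes, 10, 4000 + seed)
            before = g.gcl(cohort, partitions=parts).gcl
            after = g.gcl(cohort.drop_cells(screen.removed_cells), partitions=parts).gcl
            diffs.append(before - after)
        assert len(diffs) >= 15
        assert np.mean(diffs) > 0

    def test_needs_five_cells(self, rng):
        x = g.ExpressionMatrix(rng.random((10, 4)))
        with pytest.raises(ValueError):
            g.delta_gcl(x, x.cell_ids[0], m=2, rng=0)


class TestInterpolateCell:
    def test_endpoints_and_midpoint(self):
        a = np.array([0.0, 2.0])
        b = np.array([2.0, 0.0])
        assert np.array_equal(g.interpolate_cell(a, b, 0.0), a)
        assert np.array_equal(g.interpolate_cell(a, b, 1.0), b)
        assert np.array_equal(g.interpolate_cell(a, b, 0.5), np.array([1.0, 1.0]))

    @given(lam=st.floats(min_value=0, max_value=1))
    @settings(deadline=None, max_examples=25)
    def test_convex_combination(self, lam):
        a = np.array([1.0, 4.0, 0.0])
        b = np.array([3.0, 0.0, 2.0])
        out = g.interpolate_cell(a, b, lam)
        assert np.all(out >= np.minimum(a, b) - 1e-12)
        assert np.all(out <= np.maximum(a, b) + 1e-12)

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_rejects_lambda_outside_unit_interval(self, lam):
        with pytest.raises(ValueError):
            g.interpolate_cell(np.zeros(2), np.ones(2), lam)


def _blob_matrix(rng, n_blobs, per_blob, n_genes=50, jitter=0.0):
    profiles = rng.random((n_genes, n_blobs))
    cols = []
    for b in range(n_blobs):
        for _ in range(per_blob):
            cols.append(profiles[:, b] + jitter * rng.normal(size=n_genes))
    return g.ExpressionMatrix(np.column_stack(cols))


class TestClustering:
    def test_kmeans_separates_duplicated_groups(self, rng):
        x = _blob_matrix(rng, 2, 8)
        labels = g.kmeans_spearman(x, 2, rng=1)
        assert len(np.unique(labels[:8])) == 1
        assert len(np.unique(labels[8:])) == 1
        assert labels[0] != labels[8]

    def test_k_near_m_pigeonhole(self, rng):
        x = g.ExpressionMatrix(rng.random((30, 10)))
        labels = g.kmeans_spearman(x, 9, rng=2)
        sizes = np.bincount(labels)[1:]
        assert (sizes > 1).sum() <= 1

    def test_separates_divergent_grn_cohorts(self, small_grn, small_cohort, rng):
        other = g.perturb_grn(small_grn, 0.3, rng=777)
        cohort_b = g.generate_cohort(other, n_cells=30, n_inoperative=3, rng=888)
        x = g.ExpressionMatrix(
            np.hstack([small_cohort.expression.values, cohort_b.expression.values])
        )
        labels = g.kmeans_spearman(x, 2, rng=3)
        truth = np.repeat([1, 2], 30)
        agree = max(np.mean(labels == truth), np.mean(labels == 3 - truth))
        assert agree >= 0.9


class TestSilhouette:
    def test_equal_a_b_gives_zero(self):
        # 4 cells at the corners of a square in dissimilarity space
        d = np.array(
            [
                [0, 1, 1, np.sqrt(2)],
                [1, 0, np.sqrt(2), 1],
                [1, np.sqrt(2), 0, 1],
                [np.sqrt(2), 1, 1, 0],
            ]
        )
        dm = g.DissimilarityMatrix(d, np.array(["a", "b", "c", "d"], dtype=object))
        out = g.silhouette(dm, [1, 1, 2, 2])
        # a_i = 1 and b_i = (1 + sqrt(2))/2 != 1 here; build a true tie instead
        d2 = np.ones((4, 4)) - np.eye(4)
        dm2 = g.DissimilarityMatrix(d2, dm.cell_ids)
        out2 = g.silhouette(dm2, [1, 1, 2, 2])
        assert np.allclose(out2.s_per_cell, 0.0)
        assert out.S == pytest.approx(out.s_per_cell.mean())

    def test_two_far_blobs_near_one(self, rng):
        x = _blob_matrix(rng, 2, 6, jitter=0.0)
        d = g.spearman_dissimilarity(x)
        out = g.silhouette(d, np.repeat([1, 2], 6))
        assert np.allclose(out.s_per_cell, 1.0, atol=1e-12)
        assert out.S == pytest.approx(1.0)

    def test_random_labels_on_structureless_data(self, rng):
        scores = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = g.ExpressionMatrix(r.random((40, 30)))
            d = g.spearman_dissimilarity(x)
            scores.append(g.silhouette(d, r.integers(1, 3, size=30)).S)
        assert abs(np.mean(scores)) < 0.05

    def test_bounds_and_mean_identity(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            m = 15
            raw = r.random((m, m))
            d = (raw + raw.T) / 2
            np.fill_diagonal(d, 0)
            dm = g.DissimilarityMatrix(d, np.array([f"c{i}" for i in range(m)], dtype=object))
            labels = r.integers(1, 4, size=m)
            if len(np.unique(labels)) < 2:
                continue
            out = g.silhouette(dm, labels)
            assert np.all(out.s_per_cell >= -1 - 1e-12)
            assert np.all(out.s_per_cell <= 1 + 1e-12)
            assert out.S == pytest.approx(out.s_per_cell.mean())

    def test_singleton_cluster_scored_zero(self, rng):
        x = _blob_matrix(rng, 2, 4)
        d = g.spearman_dissimilarity(x)
        labels = np.array([1, 1, 1, 1, 2, 2, 2, 3])
        out = g.silhouette(d, labels)
        assert out.s_per_cell[7] == 0.0

    def test_requires_two_clusters(self, rng):
        x = _blob_matrix(rng, 2, 3)
        d = g.spearman_dissimilarity(x)
        with pytest.raises(ValueError):
            g.silhouette(d, np.ones(6, dtype=int))


class TestOptimalClusters:
    def test_three_duplicate_blobs(self, rng):
        x = _blob_matrix(rng, 3, 5)
        out = g.optimal_clusters(x, k_range=range(2, 6), rng=4)
        assert out.K == 3
        assert out.S == pytest.approx(1.0, abs=1e-12)
        assert out.is_clustered()

    def test_homogeneous_cohort_reports_no_split(self, default_scale_cohort):
        out = g.optimal_clusters(
            default_scale_cohort.expression, k_range=range(2, 6), rng=5
        )
        assert not out.is_clustered(0.25)
        assert set(out.scores_by_k) == {2, 3, 4, 5}

    def test_divergent_grn_cohorts_select_two(self, small_grn, small_cohort):
        other = g.perturb_grn(small_grn, 0.3, rng=777)
        cohort_b = g.generate_cohort(other, n_cells=30, n_inoperative=3, rng=888)
        x = g.ExpressionMatrix(
            np.hstack([small_cohort.expression.values, cohort_b.expression.values])
        )
        out = g.optimal_clusters(x, k_range=range(2, 6), rng=6)
        assert out.K == 2
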