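"""Window construction, SOM training contracts and overlay enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from azadem.compartment_som import (
    EnrichmentResult,
    SomGrid,
    make_windows,
    node_label_density,
    overlay_enrichment,
    train_som,
    u_matrix,
    window_features,
    zscore,
)
from azadem.core_io import GenomicInterval


class TestMakeWindows:
    def test_sliding_lattice_enumeration(self):
        ws = make_windows({"chr1": 250_000})
        assert [(w.start, w.end) for w in ws] == [
            (0, 100_000), (50_000, 150_000), (100_000, 200_000), (150_000, 250_000)]

    def test_chromosome_shorter_than_window_yields_nothing(self):
        assert make_windows({"chr1": 99_999}) == []

    def test_exact_window_size_yields_one(self):
        assert len(make_windows({"chr1": 100_000})) == 1

    def test_invariant_to_chromosome_ordering(self):
        a = make_windows({"chr2": 150_000, "chr1": 200_000})
        b = make_windows({"chr1": 200_000, "chr2": 150_000})
        assert a == b


def _gene(gene_id, chrom, start, end, strand="+"):
    from azadem.core_io import GeneModel
    iv = GenomicInterval(chrom, start, end, strand)
    return GeneModel(gene_id, "coding", iv, (iv,))


class TestWindowFeatures:
    def test_window_means_are_plain_averages(self):
        windows = [GenomicInterval("chr1", 0, 100_000)]
        track = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 20],
                              "score": [80.0, 60.0]})
        genes = [_gene("g1", "chr1", 500, 1500)]
        expr = pd.Series({"g1": 10.0})
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [10]})
        f = window_features(windows, track, track, expr, genes, sites)
        assert f.loc[0, "meth_control"] == pytest.approx(70.0)
        assert f.loc[0, "expr_mean"] == pytest.approx(10.0)
        assert f.loc[0, "hpaii_sites"] == 1

    def test_geneless_window_excluded_and_counted(self):
        windows = [GenomicInterval("chr1", 0, 100_000),
                   GenomicInterval("chr2", 0, 100_000)]
        track = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [10, 10],
                              "score": [50.0, 50.0]})
        genes = [_gene("g1", "chr1", 500, 1500)]
        expr = pd.Series({"g1": 1.0})
        sites = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [10, 10]})
        f = window_features(windows, track, track, expr, genes, sites)
        assert f.attrs["n_excluded"] == 1
        assert bool(f.loc[1, "excluded"])

    def test_zero_effect_fixture_centers_response_at_zero(self, null_bundle):
        tracks = null_bundle.angle_tracks()
        ws = make_windows(null_bundle.chrom_sizes)
        f = window_features(ws, tracks["control"], tracks["acute_1.0"],
                            null_bundle.expression.condition_mean("control"),
                            null_bundle.gene_models, null_bundle.site_positions())
        resp = f.loc[~f["excluded"], "response"]
        assert abs(resp.mean()) < 1.0


class TestTrainSom:
    def test_degenerate_single_vector_collapses_all_nodes(self):
        X = np.tile([1.0, 2.0, 3.0], (50, 1))
        grid = train_som(X, grid_shape=(3, 3), epochs=10, seed=0)
        np.testing.assert_allclose(grid.weights, np.tile([1.0, 2.0, 3.0], (9, 1)),
                                   atol=1e-9)
        assert grid.qe_history[-1] == pytest.approx(0.0, abs=1e-9)

    def test_bmu_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 4))
        grid = train_som(X, grid_shape=(4, 4), epochs=20, seed=1)
        bmu = grid.bmu(X)
        for i, x in enumerate(X):
            dists = [np.linalg.norm(x - w) for w in grid.weights]
            assert bmu[i] == int(np.argmin(dists))

    def test_training_is_seed_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 3))
        g1 = train_som(X, grid_shape=(5, 5), epochs=30, seed=7)
        g2 = train_som(X, grid_shape=(5, 5), epochs=30, seed=7)
        np.testing.assert_array_equal(g1.weights, g2.weights)

    def test_non_finite_features_rejected_with_indices(self):
        X = np.ones((30, 2))
        X[4, 1] = np.nan
        with pytest.raises(ValueError, match=r"\[4\]"):
            train_som(X, grid_shape=(2, 2), epochs=5)

    def test_quantization_error_non_increasing(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(6, 1, (100, 3))])
        grid = train_som(zscore(X), grid_shape=(6, 6), epochs=40, seed=2)
        diffs = np.diff(grid.qe_history)
        assert (diffs <= 1e-9).all()


class TestUMatrix:
    def test_identical_weights_give_all_zeros(self):
        grid = SomGrid((3, 3), np.ones((9, 2)), qe_history=[0.0], epochs=1)
        np.testing.assert_allclose(u_matrix(grid), 0.0)

    def test_one_by_two_grid_euclidean_distance(self):
        grid = SomGrid((1, 2), np.array([[0.0, 0.0], [3.0, 4.0]]),
                       qe_history=[0.0], epochs=1)
        np.testing.assert_allclose(u_matrix(grid), [[5.0, 5.0]])

    def test_untrained_grid_rejected(self):
        grid = SomGrid((2, 2), np.zeros((4, 2)))
        with pytest.raises(ValueError, match="untrained"):
            u_matrix(grid)

    def test_two_cluster_data_produces_separating_ridge(self):
        rng = np.random.default_rng(21)
        X = np.vstack([rng.normal(-4, 0.3, (200, 2)), rng.normal(4, 0.3, (200, 2))])
        grid = train_som(X, grid_shape=(8, 8), epochs=40, seed=3)
        um = u_matrix(grid)
        assert um.max() > np.median(um)


class TestOverlayEnrichment:
    def _features(self, a_tags, b_tags):
        return pd.DataFrame({
            "q_meth": a_tags, "q_expr": b_tags,
            "q_response": a_tags, "excluded": [False] * len(a_tags),
        })

    def test_perfect_association_hypergeometric_p(self):
        # table [[10,0],[0,10]]: two extreme tables out of C(20,10)
        tags_a = [5] * 10 + [1] * 10
        tags_b = [5] * 10 + [1] * 10
        f = self._features(tags_a, tags_b)
        res = overlay_enrichment(f, "methylation", "expression")
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert math.isinf(res.odds_ratio)

    def test_same_label_twice_is_maximal_association(self):
        tags = [5] * 8 + [1] * 12
        f = self._features(tags, tags)
        res = overlay_enrichment(f, "methylation", "methylation")
        assert math.isinf(res.odds_ratio)

    def test_degenerate_margin_reports_undefined_odds_ratio(self):
        f = self._features([5] * 10, [5] * 5 + [1] * 5)
        res = overlay_enrichment(f, "methylation", "expression")
        assert math.isnan(res.odds_ratio)
        assert "degenerate" in res.note

    def test_node_density_counts_mapped_windows(self):
        grid = SomGrid((1, 2), np.array([[0.0], [10.0]]), qe_history=[0.0], epochs=1)
        X = np.array([[0.1], [9.9], [10.2]])
        dens = node_label_density(grid, X, np.array([True, True, False]))
        np.testing.assert_array_equal(dens, [[1.0, 1.0]])
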