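"""Trajectory k-means, semantic labeling and proportion reporting."""

import numpy as np
import pandas as pd
import pytest

from azadem import synthetic_data as sd
from azadem.pipeline import expression_trajectories, promoter_trajectories
from azadem.response_clustering import (
    GAIN_LABELS,
    LOSS_LABELS,
    differential_expression,
    kmeans,
    label_clusters,
    linked_expression_response,
    proportion_report,
)


class TestKmeans:
    def test_single_cluster_centroid_is_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        res = kmeans(X, 1, seed=0)
        np.testing.assert_allclose(res.centroids[0], X.mean(axis=0), atol=1e-9)

    def test_k_equals_n_gives_zero_wcss(self):
        X = np.arange(10, dtype=float).reshape(5, 2)
        res = kmeans(X, 5, seed=0, restarts=5)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_fewer_points_than_clusters_rejected(self):
        with pytest.raises(ValueError, match="at least k"):
            kmeans(np.zeros((3, 2)), 5)

    def test_seven_planted_groups_recovered(self):
        centroids = [(0, 0), (30, 30), (30, 0), (0, 30), (-30, -30), (-30, 0), (0, -30)]
        df, truth = sd.make_trajectory_groups(centroids, 100, sd=1.0, seed=5)
        res = kmeans(df.to_numpy(), 7, seed=1, restarts=10)
        # label-matched agreement via majority vote per planted group
        agree = 0
        for g in range(7):
            members = res.assignments[truth == g]
            agree += (members == np.bincount(members).argmax()).sum()
        assert agree / len(truth) >= 0.99


class TestLabelClusters:
    BASE = [(0.5, 0.5), (20, 19), (18, 1), (1, 18), (-20, -18), (-20, -1), (-1, -19)]

    def test_origin_centroid_is_no_change(self):
        labels = label_clusters(np.array(self.BASE, float))
        assert labels[0] == "no-change"

    def test_persistent_loss_is_loss_early(self):
        labels = label_clusters(np.array(self.BASE, float))
        assert labels[4] == "loss-early"

    def test_acute_only_loss_is_loss_transient(self):
        labels = label_clusters(np.array(self.BASE, float))
        assert labels[5] == "loss-transient"

    def test_every_label_used_exactly_once(self):
        labels = label_clusters(np.array(self.BASE, float))
        assert sorted(labels) == sorted(
            ("no-change",) + LOSS_LABELS + GAIN_LABELS)

    def test_duplicate_centroids_warn_but_resolve(self):
        C = np.array(self.BASE, float)
        C[6] = C[5]
        with pytest.warns(UserWarning, match="duplicate"):
            labels = label_clusters(C)
        assert len(set(labels)) == 7


class TestProportionReport:
    def _report(self, counts, labels):
        assignments = pd.Series(np.repeat(np.arange(len(counts)), counts))
        centroids = np.zeros((len(counts), 2))
        return proportion_report(assignments, centroids, labels=labels)

    def test_loss_aggregate_from_published_percentages(self):
        """Three loss clusters at 23.0%, 3.7% and 5.4% aggregate to 32.1%."""
        counts = [230, 37, 54, 300, 200, 100, 79]
        labels = ["loss-early", "loss-late", "loss-transient", "no-change",
                  "gain-early", "gain-late", "gain-transient"]
        rep = self._report(counts, labels)
        assert rep.proportions["loss-early"] == pytest.approx(23.0)
        assert rep.proportions["loss-late"] == pytest.approx(3.7)
        assert rep.proportions["loss-transient"] == pytest.approx(5.4)
        assert rep.loss_total_pct == pytest.approx(32.1)

    def test_all_units_in_no_change(self):
        rep = self._report([50], ["no-change"])
        assert rep.proportions["no-change"] == pytest.approx(100.0)
        assert rep.loss_total_pct == 0.0

    def test_small_cluster_percentage_of_1338(self):
        rep = self._report([6, 1332], ["gain-early", "no-change"])
        assert round(rep.proportions["gain-early"], 2) == 0.45

    def test_proportions_sum_to_hundred(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 100, size=7).tolist()
        labels = ["no-change"] + list(LOSS_LABELS) + list(GAIN_LABELS)
        rep = self._report(counts, labels)
        assert sum(rep.proportions.values()) == pytest.approx(100.0, abs=0.1)


def _cluster_fixture(bundle):
    tracks = bundle.angle_tracks()
    traj = promoter_trajectories(bundle, tracks, flank=1500)
    res = kmeans(traj[["delta_acute", "delta_recovery"]].to_numpy(), 7,
                 seed=3, restarts=25)
    report = proportion_report(pd.Series(res.assignments, index=traj.index),
                               res.centroids)
    return traj, report


class TestLinkedExpression:
    def test_uncoupled_fixture_has_negligible_induction(self):
        """Promoter demethylation without planted expression change."""
        cfg = sd.SimulationConfig(seed=13, de_fraction_coding=0.0,
                                  de_fraction_lnc=0.0, activated_fraction=0.0)
        bundle = sd.generate(cfg, include_sequence=False)
        traj, report = _cluster_fixture(bundle)
        linked = linked_expression_response(
            report, dict(zip(traj.index, traj["gene_id"])),
            expression_trajectories(bundle), bundle.expression,
            "control", "acute_1.0", seed=3)
        assert report.loss_total_pct > 20.0
        assert linked.induced_fraction_pct < 1.0

    def test_coupled_fixture_induction_tracks_loss(self):
        """Demethylated (euchromatic) promoters planted 4-fold up."""
        cfg = sd.SimulationConfig(seed=17, de_fraction_coding=0.0,
                                  de_fraction_lnc=0.0, activated_fraction=0.0,
                                  couple_expression_to_demethylation=True)
        bundle = sd.generate(cfg, include_sequence=False)
        traj, report = _cluster_fixture(bundle)
        linked = linked_expression_response(
            report, dict(zip(traj.index, traj["gene_id"])),
            expression_trajectories(bundle), bundle.expression,
            "control", "acute_1.0", seed=3)
        eu_frac = (bundle.truth.genes["compartment"] == "eu").mean()
        # all eu-promoter genes are induced; the loss clusters are the eu blob
        assert linked.induced_fraction_pct == pytest.approx(100 * eu_frac, abs=12)
        assert linked.induced_fraction_pct == pytest.approx(report.loss_total_pct,
                                                            abs=15)

    def test_induced_fraction_bounded_by_loss_fraction(self, light_bundle):
        traj, report = _cluster_fixture(light_bundle)
        linked = linked_expression_response(
            report, dict(zip(traj.index, traj["gene_id"])),
            expression_trajectories(light_bundle), light_bundle.expression,
            "control", "acute_1.0", seed=3)
        assert linked.induced_fraction_pct <= report.loss_total_pct

    def test_empty_selection_warns_and_reports_zero(self, light_bundle):
        traj, report = _cluster_fixture(light_bundle)
        with pytest.warns(UserWarning, match="no units"):
            linked = linked_expression_response(
                report, {}, expression_trajectories(light_bundle),
                light_bundle.expression, "control", "acute_1.0",
                select_labels=("not-a-label",))
        assert linked.induced_fraction_pct == 0.0


class TestDifferentialExpression:
    def test_planted_de_genes_recovered(self, light_bundle):
        de = differential_expression(light_bundle.expression, "control", "acute_1.0")
        truth = light_bundle.truth.genes.set_index("gene_id")
        planted_up = truth.index[(truth["de_direction"] == "up")]
        called_up = de.index[de["direction"] == "up"]
        # planted 4-fold changes across 4 replicates are essentially always found
        assert len(set(planted_up) & set(called_up)) >= 0.9 * len(planted_up)
        # false positives are rare
        extra = set(called_up) - set(planted_up) - set(
            truth.index[truth["activated"]])
        assert len(extra) <= 0.01 * len(de)
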