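import itertools
import math

import numpy as np
import pytest

from sexqc.errors import ClusteringError, DegenerateClusteringError, LabelingError, ScoreError
from sexqc.inference import (
    ClusterResult,
    assign_sex,
    call_sample_sex,
    cluster_samples,
    label_clusters,
    median_sex_score,
)
from sexqc.io import ExpressionMatrix
from sexqc.simulate import SimConfig, generate_dataset, panel_for_config

from conftest import make_matrix_for_panel


def brute_force_two_partition(x):
    """Oracle: exhaustive search over all 2-partitions minimizing within-cluster SS."""
    n = x.shape[0]
    best, best_ss = None, np.inf
    for mask in itertools.product([0, 1], repeat=n):
        if len(set(mask)) < 2:
            continue
        mask = np.asarray(mask, dtype=bool)
        ss = 0.0
        for group in (x[mask], x[~mask]):
            ss += ((group - group.mean(axis=0)) ** 2).sum()
        if ss < best_ss - 1e-12:
            best_ss, best = ss, mask
    return best


class TestClusterSamples:
    def test_recovers_planted_partition_vs_bruteforce(self, clean_panel):
        sexes = ["female"] * 3 + ["male"] * 3
        m = make_matrix_for_panel(clean_panel, sexes, noise_sd=0.1, seed=7)
        cr = cluster_samples(m, restarts=25, seed=0)
        labels = np.array([cr.assignment[s] for s in m.sample_ids])
        oracle = brute_force_two_partition(m.values.T)
        # same partition up to cluster index swap
        assert (labels == oracle).all() or (labels == ~oracle).all()
        # and it equals the planted grouping
        planted = np.array([s == "female" for s in sexes])
        assert (labels == planted).all() or (labels == ~planted).all()

    def test_deterministic_given_seed(self, clean_panel):
        m = make_matrix_for_panel(clean_panel, ["female"] * 4 + ["male"] * 4, seed=3)
        a = cluster_samples(m, restarts=10, seed=42)
        b = cluster_samples(m, restarts=10, seed=42)
        assert a.assignment == b.assignment
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_identical_samples_degenerate(self):
        m = ExpressionMatrix(["p1", "p2"], ["s1", "s2", "s3"], np.ones((2, 3)))
        with pytest.raises(DegenerateClusteringError):
            cluster_samples(m)

    def test_too_few_complete_samples(self):
        values = np.array([[1.0, np.nan, np.nan], [2.0, 3.0, np.nan]])
        m = ExpressionMatrix(["p1", "p2"], ["s1", "s2", "s3"], values)
        with pytest.raises(ClusteringError, match="complete"):
            cluster_samples(m)

    def test_incomplete_samples_excluded(self, clean_panel):
        m = make_matrix_for_panel(clean_panel, ["female"] * 3 + ["male"] * 3)
        values = m.values.copy()
        values[0, 0] = np.nan
        cr = cluster_samples(ExpressionMatrix(m.probe_ids, m.sample_ids, values))
        assert "s1" not in cr.assignment
        assert set(cr.assignment) == set(m.sample_ids[1:])


def cluster_result(centroids, probe_ids):
    return ClusterResult(
        sample_ids=["a", "b"],
        assignment={"a": 0, "b": 1},
        centroids=np.asarray(centroids, dtype=float),
        probe_ids=probe_ids,
        inertia=0.0,
        n_restarts=1,
        seed=0,
    )


class TestLabelClusters:
    def test_unanimous_vote(self, clean_panel):
        cr = cluster_result(
            [[10.1, 9.8, 4.2, 4.5], [5.0, 5.2, 9.1, 9.7]],
            ["XIST_1", "XIST_2", "KDM5D_1", "RPS4Y1_1"],
        )
        assert label_clusters(cr, clean_panel) == {0: "female", 1: "male"}

    def test_majority_prevails(self, clean_panel):
        # XIST_2 votes against the three concordant probes
        cr = cluster_result(
            [[10.1, 5.0, 4.2, 4.5], [5.0, 9.8, 9.1, 9.7]],
            ["XIST_1", "XIST_2", "KDM5D_1", "RPS4Y1_1"],
        )
        assert label_clusters(cr, clean_panel) == {0: "female", 1: "male"}

    def test_tied_vote_fails(self, clean_panel):
        cr = cluster_result(
            [[10.0, 5.0, 4.0, 9.0], [5.0, 10.0, 9.0, 4.0]],
            ["XIST_1", "XIST_2", "KDM5D_1", "RPS4Y1_1"],
        )
        with pytest.raises(LabelingError, match="tied"):
            label_clusters(cr, clean_panel)

    def test_equal_centroid_probe_abstains(self, clean_panel):
        cr = cluster_result(
            [[10.0, 7.0, 4.0, 4.0], [5.0, 7.0, 9.0, 9.0]],
            ["XIST_1", "XIST_2", "KDM5D_1", "RPS4Y1_1"],
        )
        assert label_clusters(cr, clean_panel) == {0: "female", 1: "male"}


class TestMedianSexScore:
    def test_pooled_medians(self, clean_panel):
        # female medians {9,10,11} -> 10; male {4,6} -> 5
        panel = clean_panel
        from sexqc.markers import MarkerPanel, MarkerProbe

        panel3 = MarkerPanel(
            [
                MarkerProbe("XIST_1", "XIST", "female_high"),
                MarkerProbe("XIST_2", "XIST", "female_high"),
                MarkerProbe("XIST_3", "XIST", "female_high"),
                MarkerProbe("KDM5D_1", "KDM5D", "male_high"),
                MarkerProbe("RPS4Y1_1", "RPS4Y1", "male_high"),
            ]
        )
        expr = {"XIST_1": 9.0, "XIST_2": 10.0, "XIST_3": 11.0, "KDM5D_1": 4.0, "RPS4Y1_1": 6.0}
        assert median_sex_score(expr, panel3) == pytest.approx(5.0)

    def test_negative_score(self, clean_panel):
        expr = {"XIST_1": 5.0, "KDM5D_1": 9.0, "RPS4Y1_1": 10.0}
        assert median_sex_score(expr, clean_panel) == pytest.approx(-4.5)

    def test_zero_score(self, clean_panel):
        expr = {"XIST_1": 7.0, "KDM5D_1": 7.0}
        assert median_sex_score(expr, clean_panel) == 0.0

    def test_missing_direction_raises(self, clean_panel):
        with pytest.raises(ScoreError):
            median_sex_score({"XIST_1": 9.0, "KDM5D_1": math.nan, "RPS4Y1_1": math.nan}, clean_panel)


class TestCallSampleSex:
    @pytest.mark.parametrize(
        "cluster_sex,D,expected",
        [
            ("female", 5.0, "female"),
            ("female", -2.0, "ambiguous"),
            ("male", -3.0, "male"),
            ("male", 2.0, "ambiguous"),
            ("male", 0.0, "ambiguous"),
            ("female", 0.0, "ambiguous"),
        ],
    )
    def test_rule_table(self, cluster_sex, D, expected):
        assert call_sample_sex(cluster_sex, D) == expected

    def test_invalid_cluster_sex(self):
        with pytest.raises(ValueError):
            call_sample_sex("ambiguous", 1.0)


class TestAssignSex:
    def test_calls_match_planted_sexes(self, clean_panel):
        sexes = ["female"] * 5 + ["male"] * 5
        m = make_matrix_for_panel(clean_panel, sexes, noise_sd=0.2, seed=1)
        calls = assign_sex(m, clean_panel)
        assert [c.final_call for c in calls] == sexes
        assert all(
            (c.D > 0) if c.final_call == "female" else (c.D < 0) for c in calls
        )

    def test_sample_permutation_symmetry(self, clean_panel):
        sexes = ["female", "male"] * 5
        m = make_matrix_for_panel(clean_panel, sexes, noise_sd=0.2, seed=9)
        calls = {c.sample_id: c.final_call for c in assign_sex(m, clean_panel)}
        perm = list(reversed(m.sample_ids))
        permuted = m.subset_samples(perm)
        calls_perm = {c.sample_id: c.final_call for c in assign_sex(permuted, clean_panel)}
        assert calls == calls_perm

    def test_missing_marker_forces_ambiguous(self, clean_panel):
        m = make_matrix_for_panel(clean_panel, ["female"] * 3 + ["male"] * 3)
        values = m.values.copy()
        values[0, 0] = np.nan
        calls = assign_sex(ExpressionMatrix(m.probe_ids, m.sample_ids, values), clean_panel)
        first = calls[0]
        assert first.final_call == "ambiguous" and first.cluster_sex is None
        assert [c.final_call for c in calls[1:]] == ["female", "female", "male", "male", "male"]

    def test_ambiguous_fraction_monotone_in_planted_fraction(self):
        counts = []
        for n_ambiguous in (0, 5, 10):
            cfg = SimConfig(n_samples=40, n_ambiguous=n_ambiguous, seed=2)
            matrix, _, _ = generate_dataset(cfg)
            calls = assign_sex(matrix.subset_probes(panel_for_config(cfg).probe_ids), panel_for_config(cfg))
            counts.append(sum(c.final_call == "ambiguous" for c in calls))
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]
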