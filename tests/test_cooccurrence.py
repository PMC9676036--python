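"""Pearson/Jaccard statistics, co-occurrence networks, profile clustering."""

import numpy as np
import pandas as pd
import pytest

from seapha.cooccurrence import (
    build_network,
    cluster_profiles,
    correlation_matrix,
    density_vectors,
    jaccard_distance,
    pearson_with_p,
)
from seapha.density import DensityMatrix, build_density, log2_normalize

from conftest import annotate


def matrix_from(data: dict[str, list[int]]) -> DensityMatrix:
    return DensityMatrix(counts=pd.DataFrame(data), level="genome")


class TestDensityVectors:
    def test_vectors_are_matrix_columns(self):
        m = matrix_from({"GH2": [1, 0, 3], "PL7": [0, 2, 0]})
        v = density_vectors(m, ["GH2", "PL7"])
        assert list(v["GH2"]) == [1, 0, 3]
        assert list(v["PL7"]) == [0, 2, 0]

    def test_projection_keeps_order(self):
        m = matrix_from({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert list(density_vectors(m, ["c", "a"]).columns) == ["c", "a"]

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            density_vectors(matrix_from({"a": [1, 2]}), ["zzz"])


class TestPearson:
    def test_identity_r_one(self):
        r, p = pearson_with_p([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_antilinear_r_minus_one(self):
        r, _ = pearson_with_p([1, 2, 3, 4], [9, 8, 7, 6])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        # deviations give cov 1, variances 5/3 each -> r = 0.6
        r, p = pearson_with_p([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        assert 0 < p < 1

    def test_constant_vector_flagged_undefined(self):
        r, p = pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(r) and np.isnan(p)

    def test_p_matches_t_distribution(self):
        from scipy import stats

        x = np.array([1, 2, 3, 4, 5, 7], dtype=float)
        y = np.array([2, 1, 4, 3, 6, 5], dtype=float)
        r, p = pearson_with_p(x, y)
        n = len(x)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=n - 2), rel=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(3, 30).astype(float)
        y = rng.poisson(3, 30).astype(float)
        r0, _ = pearson_with_p(x, y)
        r1, _ = pearson_with_p(2.5 * x + 7, y)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 2], [3, 4])


class TestJaccard:
    def test_identical_presence_zero(self):
        assert jaccard_distance([1, 2, 0], [3, 1, 0]) == 0.0

    def test_disjoint_presence_one(self):
        assert jaccard_distance([1, 0, 2, 0], [0, 3, 0, 0]) == 1.0

    def test_partial_overlap(self):
        # A={0,1,2}, B={1,2,3}: jd = 1 - 2/4 = 0.5
        assert jaccard_distance([1, 1, 1, 0], [0, 1, 1, 1]) == pytest.approx(0.5)

    def test_both_empty_flagged_nan(self):
        assert np.isnan(jaccard_distance([0, 0], [0, 0]))

    def test_scale_invariance(self):
        x, y = [5, 0, 1], [2, 2, 0]
        assert jaccard_distance(x, y) == jaccard_distance(
            [40, 0, 8], [6, 6, 0]
        )


class TestCorrelationMatrix:
    def test_pair_count_and_symmetric_content(self):
        m = matrix_from({"a": [1, 2, 3, 1], "b": [2, 1, 4, 2], "c": [0, 1, 0, 3]})
        df = correlation_matrix(m)
        assert len(df) == 3  # C(3,2) unordered pairs
        assert set(zip(df.label_a, df.label_b)) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_genome_order_invariance(self):
        data = {"a": [1, 2, 3, 5], "b": [2, 1, 4, 0], "c": [0, 1, 0, 2]}
        m1 = matrix_from(data)
        perm = [3, 1, 0, 2]
        m2 = DensityMatrix(counts=m1.counts.iloc[perm].reset_index(drop=True), level="genome")
        df1 = correlation_matrix(m1).set_index(["label_a", "label_b"])
        df2 = correlation_matrix(m2).set_index(["label_a", "label_b"])
        pd.testing.assert_frame_equal(df1, df2)

    def test_agrees_with_textbook_formula(self):
        """Independent oracle: cov/sd formula written from scratch."""
        rng = np.random.default_rng(123)
        counts = pd.DataFrame(
            rng.poisson(2.0, size=(30, 8)), columns=[f"L{i}" for i in range(8)]
        )
        df = correlation_matrix(DensityMatrix(counts=counts, level="genome"))
        for row in df.itertuples():
            x = counts[row.label_a].to_numpy(dtype=float)
            y = counts[row.label_b].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                assert np.isnan(row.r)
                continue
            xc, yc = x - x.mean(), y - y.mean()
            r_oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert row.r == pytest.approx(r_oracle, abs=1e-12)
            a, b = set(np.nonzero(x)[0]), set(np.nonzero(y)[0])
            assert row.jd == pytest.approx(1 - len(a & b) / len(a | b))

    def test_q_values_bh_monotone(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.poisson(2.0, (25, 6)), columns=list("abcdef"))
        df = correlation_matrix(DensityMatrix(counts=counts, level="genome")).dropna()
        assert (df["q"] >= df["p"] - 1e-12).all()


class TestBuildNetwork:
    def test_never_copresent_no_edge(self):
        m = matrix_from({"a": [1, 0, 0], "b": [0, 1, 1]})
        net = build_network(m)
        assert not net.graph.has_edge("a", "b")

    def test_full_copresence_weight(self):
        k = 5
        m = matrix_from({"a": [1] * k, "b": [2] * k})
        net = build_network(m)
        assert net.graph.edges["a", "b"]["copresence"] == k
        assert net.graph.edges["a", "b"]["weight"] == pytest.approx(np.log2(k + 1))

    def test_min_copresence_above_max_empty(self):
        m = matrix_from({"a": [1, 1, 0], "b": [1, 0, 1]})
        assert build_network(m, min_copresence=2).graph.number_of_edges() == 0

    def test_edge_weight_bounded_by_presence(self):
        rng = np.random.default_rng(3)
        m = matrix_from({f"L{i}": rng.poisson(1, 20).tolist() for i in range(5)})
        net = build_network(m)
        for a, b, d in net.graph.edges(data=True):
            assert d["copresence"] <= min(
                net.graph.nodes[a]["presence"], net.graph.nodes[b]["presence"]
            )

    def test_clusters_partition_nodes(self):
        rng = np.random.default_rng(4)
        m = matrix_from({f"L{i}": rng.poisson(2, 15).tolist() for i in range(6)})
        net = build_network(m, n_clusters=3)
        assert set(net.clusters) == set(m.labels)
        assert set(net.clusters.values()) <= {1, 2, 3}


class TestClusterProfiles:
    def test_identical_profiles_merge_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], index=["a", "b", "c"])
        link, _, _ = cluster_profiles(df, n_clusters=2)
        assert link[0, 2] == pytest.approx(0.0)  # first merge at height 0

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(11)
        block1 = rng.normal(0, 0.1, size=(4, 6))
        block2 = rng.normal(10, 0.1, size=(4, 6))
        df = pd.DataFrame(np.vstack([block1, block2]),
                          index=[f"x{i}" for i in range(8)])
        _, _, flat = cluster_profiles(df, n_clusters=2)
        assert len(set(flat[:4])) == 1 and len(set(flat[4:])) == 1
        assert flat[0] != flat[-1]

    def test_k1_single_cluster(self):
        df = pd.DataFrame(np.arange(12.0).reshape(4, 3))
        _, _, flat = cluster_profiles(df, n_clusters=1)
        assert set(flat) == {1}

    def test_k_exceeding_items_rejected(self):
        df = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            cluster_profiles(df, n_clusters=4)

    def test_column_axis_clusters_labels(self):
        m = build_density(annotate({
            "g1": {"GH2": 4, "GH43": 4}, "g2": {"GH2": 5, "GH43": 5},
            "g3": {"PhaC": 3}, "g4": {"PhaC": 2},
        }))
        _, order, flat = cluster_profiles(log2_normalize(m), axis="columns", n_clusters=2)
        by_cluster = dict(zip(["GH2", "GH43", "PhaC"], flat))
        assert by_cluster["GH2"] == by_cluster["GH43"] != by_cluster["PhaC"]

    def test_deterministic_leaf_order(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(7, 4)), index=[f"i{j}" for j in range(7)])
        o1 = cluster_profiles(df, n_clusters=3)[1]
        o2 = cluster_profiles(df, n_clusters=3)[1]
        assert o1 == o2
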