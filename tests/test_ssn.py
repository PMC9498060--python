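import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom, norm

from dmne import (
    BoxSpec,
    ExpressionMatrix,
    aggregate_reference_network,
    box_members,
    build_sample_network,
    edge_decision,
    extract_local_networks,
    pair_statistic,
    perturbed_degree_matrix,
    reference_degree_matrix,
    stage_degree_matrices,
    topk_local_networks,
)
from dmne.ssn import SampleNetwork, adjacency_for_target, k_box_for


# --- independent brute-force oracle ---------------------------------------

def oracle_box(values, target, k):
    """Explicit nearest-neighbour scan with (distance, index) sorting."""
    ranked = sorted(
        (i for i in range(len(values)) if i != target),
        key=lambda i: (abs(values[i] - values[target]), i),
    )
    return {target} | set(ranked[: k - 1])


def oracle_pair(Ei, Ej, target, spec):
    n = len(Ei)
    k = max(1, int(math.floor(spec.box_fraction * n + 0.5)))
    bi, bj = oracle_box(Ei, target, k), oracle_box(Ej, target, k)
    n_xy = len(bi & bj)
    r = n_xy / n - (k / n) * (k / n)
    var = k * k * (n - k) * (n - k) / (n * n * (n - 1))
    z = 0.0 if var == 0 else (n_xy - k * k / n) / math.sqrt(var)
    return r, z, n_xy


class TestBoxMembers:
    def test_equidistant_tie_goes_to_smaller_index(self):
        values = np.arange(20) * 0.1  # 0.0 .. 1.9
        # target value 0.5 at index 5: 0.4 and 0.6 are equidistant
        assert box_members(values, 5, 2) == {4, 5}

    def test_whole_cloud_and_single(self):
        values = np.array([3.0, 1.0, 2.0])
        assert box_members(values, 1, 3) == {0, 1, 2}
        assert box_members(values, 2, 1) == {2}

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            box_members([1.0, 2.0], 0, 3)

    @given(st.integers(0, 999))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 25))
        values = rng.normal(size=n).round(2)  # rounding provokes ties
        t = int(rng.integers(n))
        k = int(rng.integers(1, n + 1))
        assert box_members(values, t, k) == oracle_box(values, t, k)


class TestPairStatistic:
    def test_identical_genes_known_z(self):
        # fully dependent pair: boxes coincide, n_xy = k_box
        vals = np.random.default_rng(1).permutation(100).astype(float)
        stat = pair_statistic(vals, vals, 0, BoxSpec())
        assert stat.n_xy == 10
        expected_z = (10 - 1.0) / math.sqrt(10 * 10 * 90 * 90 / (100**2 * 99))
        assert stat.z == pytest.approx(expected_z)
        assert stat.z == pytest.approx(9.95, abs=0.01)

    def test_degenerate_whole_cloud_box(self):
        vals = np.arange(5, dtype=float)
        stat = pair_statistic(vals, vals[::-1], 2, BoxSpec(box_fraction=1.0))
        assert stat.n_xy == 5
        assert stat.r == pytest.approx(0.0)
        assert stat.z == 0.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pair_statistic([1.0, 2.0], [2.0, 1.0], 0, BoxSpec())

    @given(st.integers(0, 999))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 31))
        Ei = rng.permutation(n).astype(float)
        Ej = rng.permutation(n).astype(float)
        t = int(rng.integers(n))
        spec = BoxSpec()
        stat = pair_statistic(Ei, Ej, t, spec)
        r, z, n_xy = oracle_pair(Ei, Ej, t, spec)
        assert stat.n_xy == n_xy
        assert stat.r == pytest.approx(r, abs=1e-12)
        assert stat.z == pytest.approx(z, abs=1e-12)


class TestEdgeDecision:
    def test_strong_dependence_is_edge(self):
        vals = np.random.default_rng(1).permutation(100).astype(float)
        stat = pair_statistic(vals, vals, 0, BoxSpec())
        assert edge_decision(stat, BoxSpec()) is True
        assert edge_decision(stat, BoxSpec(edge_rule="zscore")) is True

    def test_zero_r_not_positive_edge(self):
        vals = np.arange(5, dtype=float)
        stat = pair_statistic(vals, vals[::-1], 2, BoxSpec(box_fraction=1.0))
        assert edge_decision(stat, BoxSpec(box_fraction=1.0, edge_rule="positive")) is False

    def test_degenerate_box_never_significant(self):
        vals = np.arange(5, dtype=float)
        spec = BoxSpec(box_fraction=1.0)
        stat = pair_statistic(vals, vals[::-1], 2, spec)
        assert stat.z == 0.0
        assert edge_decision(stat, spec) is False


class TestNetworkConstruction:
    @pytest.mark.parametrize("rule", ["significance", "zscore", "positive"])
    def test_vectorised_equals_pairwise_path(self, rule):
        """Dual route: the matrix construction must equal per-pair decisions."""
        rng = np.random.default_rng(3)
        m, n = 7, 15
        values = rng.normal(size=(m, n))
        spec = BoxSpec(edge_rule=rule)
        A = adjacency_for_target(values, 4, spec)
        for i in range(m):
            for j in range(i + 1, m):
                stat = pair_statistic(values[i], values[j], 4, spec)
                assert A[i, j] == edge_decision(stat, spec), (i, j, rule)
        assert np.array_equal(A, A.T)
        assert not A.diagonal().any()

    def test_identical_genes_connected(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=100)
        x = ExpressionMatrix(["G1", "G2"], [f"S{i}" for i in range(100)],
                             np.vstack([row, row]))
        net = build_sample_network(x, "S0", BoxSpec())
        assert net.adjacency[0, 1]

    def test_reference_degree_matrix_shape_and_bounds(self):
        rng = np.random.default_rng(5)
        m, n = 12, 10
        x = ExpressionMatrix(
            [f"G{i}" for i in range(m)], [f"S{i}" for i in range(n)],
            rng.normal(size=(m, n)),
        )
        dm, nets = reference_degree_matrix(x, BoxSpec())
        assert dm.degrees.shape == (m, n)
        assert len(nets) == n
        assert (dm.degrees >= 0).all() and (dm.degrees <= m - 1).all()
        for net, col in zip(nets, dm.degrees.T):
            np.testing.assert_array_equal(net.degrees, col)

    def test_construction_is_deterministic(self):
        rng = np.random.default_rng(8)
        x = ExpressionMatrix(
            [f"G{i}" for i in range(6)], [f"S{i}" for i in range(12)],
            rng.normal(size=(6, 12)),
        )
        a = build_sample_network(x, "S3", BoxSpec()).adjacency
        b = build_sample_network(x, "S3", BoxSpec()).adjacency
        np.testing.assert_array_equal(a, b)

    def test_null_edge_rate_conservative(self):
        """The exact significance rule never exceeds its nominal level."""
        rng = np.random.default_rng(11)
        m, n = 60, 400
        values = rng.random((m, n))
        A = adjacency_for_target(values, 0, BoxSpec(alpha=0.01))
        rate = A[np.triu_indices(m, 1)].mean()
        npairs = m * (m - 1) / 2
        assert rate <= 0.01 + 3 * math.sqrt(0.01 * 0.99 / npairs)


class TestPerturbedDegrees:
    def _ref(self, rng, m=8, n=12):
        return ExpressionMatrix(
            [f"G{i}" for i in range(m)], [f"R{i}" for i in range(n)],
            rng.normal(size=(m, n)),
        )

    def test_one_column_per_case_sample(self):
        rng = np.random.default_rng(2)
        x_ref = self._ref(rng)
        x_case = ExpressionMatrix(
            x_ref.gene_ids, [f"C{i}" for i in range(5)], rng.normal(size=(8, 5))
        )
        dm = perturbed_degree_matrix(x_ref, x_case, BoxSpec())
        assert dm.degrees.shape == (8, 5)
        assert dm.column_ids == x_case.sample_ids

    def test_duplicated_reference_profile_matches_reference_column(self):
        rng = np.random.default_rng(4)
        x_ref = self._ref(rng)
        x_case = ExpressionMatrix(x_ref.gene_ids, ["copy"], x_ref.values[:, [3]])
        dm_ref, dm_case = stage_degree_matrices(x_ref, x_case, BoxSpec())
        # same cloud, identical profiles -> identical degree columns
        np.testing.assert_array_equal(dm_case.degrees[:, 0], dm_ref.degrees[:, 3])

    def test_gene_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        x_ref = self._ref(rng)
        x_case = ExpressionMatrix(["X1"] + x_ref.gene_ids[1:], ["C0"],
                                  rng.normal(size=(8, 1)))
        with pytest.raises(ValueError, match="gene"):
            perturbed_degree_matrix(x_ref, x_case, BoxSpec())

    def test_box_size_follows_cloud_size(self):
        assert k_box_for(0.1, 25) == 3   # 2.5 rounds half-up
        assert k_box_for(0.1, 26) == 3
        assert k_box_for(0.1, 30) == 3
        assert k_box_for(0.1, 35) == 4
        assert k_box_for(0.1, 4) == 1    # floored at 1


def _net(gene_ids, edges):
    m = len(gene_ids)
    A = np.zeros((m, m), dtype=bool)
    for i, j in edges:
        A[i, j] = A[j, i] = True
    return SampleNetwork("t", gene_ids, A, n_points=m)


class TestAggregation:
    genes = ["A", "B", "C"]

    def test_unanimous_edge_survives_any_vote(self):
        nets = [_net(self.genes, [(0, 1)]) for _ in range(5)]
        for vf in (0.2, 0.5, 1.0):
            agg = aggregate_reference_network(nets, vote_fraction=vf)
            assert agg.adjacency[0, 1]

    def test_minority_edge_dropped_at_majority(self):
        nets = [_net(self.genes, [(0, 1)])] * 2 + [_net(self.genes, [])] * 3
        agg = aggregate_reference_network(nets, vote_fraction=0.5)  # need >= 3
        assert not agg.adjacency[0, 1]

    def test_small_vote_fraction_is_union(self):
        nets = [_net(self.genes, [(0, 1)]), _net(self.genes, [(1, 2)])]
        agg = aggregate_reference_network(nets, vote_fraction=1e-9)
        assert agg.adjacency[0, 1] and agg.adjacency[1, 2]


class TestLocalNetworks:
    def test_star_graph(self):
        genes = ["hub", "l1", "l2", "l3"]
        topo = _net(genes, [(0, 1), (0, 2), (0, 3)])
        locals_ = extract_local_networks(topo)
        by_center = {l.center: l for l in locals_}
        assert by_center["hub"].size == 4
        assert all(by_center[f"l{i}"].size == 2 for i in (1, 2, 3))

    def test_triangle(self):
        topo = _net(["A", "B", "C"], [(0, 1), (1, 2), (0, 2)])
        locals_ = extract_local_networks(topo)
        assert len(locals_) == 3
        assert all(l.size == 3 for l in locals_)

    def test_isolated_gene_excluded(self):
        topo = _net(["A", "B", "C"], [(0, 1)])
        centers = {l.center for l in extract_local_networks(topo)}
        assert centers == {"A", "B"}

    def test_topk_locals_fixed_size_and_center_first(self):
        rng = np.random.default_rng(7)
        x = ExpressionMatrix(
            [f"G{i}" for i in range(9)], [f"S{i}" for i in range(10)],
            rng.normal(size=(9, 10)),
        )
        _, nets = reference_degree_matrix(x, BoxSpec())
        locals_ = topk_local_networks(nets, k_neighbors=4)
        assert len(locals_) == 9
        for l in locals_:
            assert l.size == 5
            assert l.members[0] == l.center
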