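"""Sample-specific network construction via the neighbourhood-box statistic.

For a target sample and a gene pair (g_i, g_j), draw a one-dimensional box
around the target's value on each axis holding exactly ``k_box`` samples
(the target plus its nearest neighbours by absolute difference, ties broken
by smaller sample index). The dependence statistic compares the overlap of
the two boxes with its expectation under independence:

    r = n_xy / n - (n_x / n)(n_y / n)
    z = (n_xy - n_x n_y / n) / sqrt(n_x n_y (n - n_x)(n - n_y) / (n^2 (n-1)))

with n_x = n_y = k_box. Because the target sample sits in both boxes, the
overlap of the remaining members follows Hypergeom(n-1, k_box-1, k_box-1)
under independence; the default ``significance`` edge rule is the exact
one-sided tail test of that conditional null at level alpha. The
``zscore`` rule thresholds z against the standard-normal quantile (the
classical cell-specific-network criterion; anticonservative at small n),
and ``positive`` is the literal r > 0 rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom, norm

from .io_gem import ExpressionMatrix

__all__ = [
    "BoxSpec",
    "PairStatistic",
    "SampleNetwork",
    "DegreeMatrix",
    "LocalNetwork",
    "k_box_for",
    "box_members",
    "pair_statistic",
    "edge_decision",
    "adjacency_for_target",
    "build_sample_network",
    "reference_degree_matrix",
    "perturbed_degree_matrix",
    "stage_degree_matrices",
    "aggregate_reference_network",
    "knn_reference_topology",
    "extract_local_networks",
]

EDGE_RULES = ("significance", "zscore", "positive")


def k_box_for(box_fraction: float, n_points: int) -> int:
    """Box size: round-half-up of box_fraction * n_points, floored at 1."""
    return max(1, int(math.floor(box_fraction * n_points + 0.5)))


@dataclass(frozen=True)
class BoxSpec:
    """Parameters of the box statistic.

    box_fraction : fraction of the point cloud captured per box (default 0.1)
    alpha        : significance level for the edge test (default 0.01)
    edge_rule    : 'significance' (exact conditional test, default),
                   'zscore' (normal threshold on z), or 'positive' (r > 0)
    """

    box_fraction: float = 0.1
    alpha: float = 0.01
    edge_rule: str = "significance"

    def __post_init__(self):
        if not 0.0 < self.box_fraction <= 1.0:
            raise ValueError("box_fraction must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.edge_rule not in EDGE_RULES:
            raise ValueError(f"edge_rule must be one of {EDGE_RULES}")

    def k_box(self, n_points: int) -> int:
        return k_box_for(self.box_fraction, n_points)


@dataclass(frozen=True)
class PairStatistic:
    """Box-overlap statistic for one gene pair at one target sample."""

    r: float
    z: float
    n_xy: int
    n: int
    k_box: int

    @property
    def p_value(self) -> float:
        """Exact one-sided tail of the overlap beyond the shared target.

        P(H >= n_xy - 1) with H ~ Hypergeom(n-1, k_box-1, k_box-1).
        """
        return float(
            hypergeom.sf(self.n_xy - 2, self.n - 1, self.k_box - 1, self.k_box - 1)
        )


def box_members(values, target_index: int, k_box: int) -> set:
    """Indices of the box: target plus the k_box-1 nearest values.

    Nearness is absolute difference to the target's value; ties are broken
    by smaller sample index, so the result is deterministic.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if not 0 <= target_index < n:
        raise IndexError(f"target_index {target_index} out of range for n={n}")
    if not 1 <= k_box <= n:
        raise ValueError(f"k_box must be in [1, {n}], got {k_box}")
    diffs = np.abs(values - values[target_index])
    diffs[target_index] = -1.0  # target always first
    order = np.argsort(diffs, kind="stable")  # stable => ties by smaller index
    return set(int(i) for i in order[:k_box])


def _overlap_stats(n_xy: int, n: int, k: int):
    r = n_xy / n - (k * k) / (n * n)
    var = k * k * (n - k) * (n - k) / (n * n * (n - 1))
    z = 0.0 if var == 0 else (n_xy - k * k / n) / math.sqrt(var)
    return r, z


def pair_statistic(Ei, Ej, target_index: int, spec: BoxSpec) -> PairStatistic:
    """Box statistic for one gene pair; n must be at least 3."""
    Ei = np.asarray(Ei, dtype=float)
    Ej = np.asarray(Ej, dtype=float)
    if Ei.shape != Ej.shape:
        raise ValueError("Ei and Ej must have equal length")
    n = Ei.size
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    k = spec.k_box(n)
    bi = box_members(Ei, target_index, k)
    bj = box_members(Ej, target_index, k)
    n_xy = len(bi & bj)
    r, z = _overlap_stats(n_xy, n, k)
    return PairStatistic(r=r, z=z, n_xy=n_xy, n=n, k_box=k)


def edge_decision(stat: PairStatistic, spec: BoxSpec) -> bool:
    """Apply the edge rule named in ``spec.edge_rule`` to a pair statistic."""
    if spec.edge_rule == "positive":
        return bool(stat.r > 0)
    if spec.edge_rule == "zscore":
        return bool(stat.z > norm.ppf(1.0 - spec.alpha))
    return bool(stat.p_value <= spec.alpha and stat.n_xy > 1)


@dataclass
class SampleNetwork:
    """Undirected gene-gene adjacency attributed to one target sample."""

    target_sample_id: str
    gene_ids: list
    adjacency: np.ndarray = field(repr=False)
    n_points: int = 0

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=bool)
        if A.shape[0] != A.shape[1] or A.shape[0] != len(self.gene_ids):
            raise ValueError("adjacency must be square over gene_ids")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency must have an empty diagonal")
        self.adjacency = A

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_list(self):
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        return [(self.gene_ids[i], self.gene_ids[j]) for i, j in zip(ii, jj)]


@dataclass
class DegreeMatrix:
    """Genes x target-samples matrix of node degrees (the NDM)."""

    gene_ids: list
    column_ids: list
    degrees: np.ndarray = field(repr=False)

    def __post_init__(self):
        D = np.asarray(self.degrees)
        if D.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError("degrees shape must be (genes, columns)")
        if (D < 0).any() or (D > len(self.gene_ids) - 1).any():
            raise ValueError("degrees must lie in [0, m-1]")
        self.degrees = D.astype(int)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.degrees, index=self.gene_ids, columns=self.column_ids)


@dataclass(frozen=True)
class LocalNetwork:
    """A centre gene plus its neighbour genes (centre first).

    The same membership is used on the reference and the perturbed side.
    """

    center: str
    members: tuple

    def __post_init__(self):
        if not self.members or self.members[0] != self.center:
            raise ValueError("members must start with the centre gene")
        if len(set(self.members)) != len(self.members):
            raise ValueError("members must be unique")

    @property
    def size(self) -> int:
        return len(self.members)


def _box_matrix(values: np.ndarray, target: int, k: int) -> np.ndarray:
    """Boolean m x n box membership for every gene at one target sample."""
    d = np.abs(values - values[:, [target]])
    d[:, target] = -1.0
    order = np.argsort(d, axis=1, kind="stable")
    B = np.zeros(values.shape, dtype=bool)
    np.put_along_axis(B, order[:, :k], True, axis=1)
    return B


def _critical_overlap(n: int, k: int, alpha: float) -> int:
    """Smallest n_xy with exact conditional tail probability <= alpha."""
    hs = np.arange(0, k + 1)
    sf = hypergeom.sf(hs - 1, n - 1, k - 1, k - 1)
    ok = np.flatnonzero(sf <= alpha)
    if ok.size == 0:
        return k + 2  # unattainable: no edge can be called
    h = int(hs[ok[0]])
    return max(h, 1) + 1  # +1 for the shared target; never call on overlap 1


def adjacency_for_target(values: np.ndarray, target: int, spec: BoxSpec) -> np.ndarray:
    """Vectorised all-pairs edge decisions for one target sample.

    Equivalent to applying :func:`pair_statistic` + :func:`edge_decision`
    to every unordered gene pair (property-tested against that path).
    """
    m, n = values.shape
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    k = spec.k_box(n)
    B = _box_matrix(values, target, k)
    n_xy = (B.astype(np.float32) @ B.T.astype(np.float32)).round().astype(int)
    if spec.edge_rule == "positive":
        A = n_xy / n - (k * k) / (n * n) > 0
    elif spec.edge_rule == "zscore":
        var = k * k * (n - k) * (n - k) / (n * n * (n - 1))
        if var == 0:
            A = np.zeros((m, m), dtype=bool)
        else:
            A = (n_xy - k * k / n) / math.sqrt(var) > norm.ppf(1.0 - spec.alpha)
    else:
        A = n_xy >= _critical_overlap(n, k, spec.alpha)
    np.fill_diagonal(A, False)
    return A


def build_sample_network(x: ExpressionMatrix, target_sample: str, spec: BoxSpec) -> SampleNetwork:
    """Construct the SSN of one target sample over the matrix's point cloud."""
    if x.n_genes < 2:
        raise ValueError("need at least 2 genes")
    t = x.sample_ids.index(target_sample)
    A = adjacency_for_target(x.values, t, spec)
    return SampleNetwork(target_sample, x.gene_ids, A, n_points=x.n_samples)


def reference_degree_matrix(x_ref: ExpressionMatrix, spec: BoxSpec):
    """One network per reference sample over the reference cloud.

    Returns the degree matrix (one column per reference sample) and the
    list of sample networks.
    """
    if x_ref.n_samples < 3:
        raise ValueError("need at least 3 reference samples")
    nets = [build_sample_network(x_ref, s, spec) for s in x_ref.sample_ids]
    D = np.column_stack([net.degrees for net in nets])
    return DegreeMatrix(x_ref.gene_ids, list(x_ref.sample_ids), D), nets


def _check_same_genes(a: ExpressionMatrix, b: ExpressionMatrix):
    if a.gene_ids != b.gene_ids:
        raise ValueError("gene sets of reference and case matrices differ")


def perturbed_degree_matrix(
    x_ref: ExpressionMatrix,
    x_case_stage: ExpressionMatrix,
    spec: BoxSpec,
    pooled: bool = True,
) -> DegreeMatrix:
    """Degree matrix of case-centred networks at one stage.

    With ``pooled=True`` (default) the point cloud is the n reference
    samples plus all of the stage's case samples, so that co-varying case
    samples can support each other's boxes; with ``pooled=False`` each case
    sample is added to the references alone (cloud of n+1).
    """
    _check_same_genes(x_ref, x_case_stage)
    if x_case_stage.n_samples < 1:
        raise ValueError("need at least one case sample")
    n = x_ref.n_samples
    cols = []
    if pooled:
        cloud = np.column_stack([x_ref.values, x_case_stage.values])
        for j in range(x_case_stage.n_samples):
            cols.append(adjacency_for_target(cloud, n + j, spec).sum(axis=1))
    else:
        for j in range(x_case_stage.n_samples):
            cloud = np.column_stack([x_ref.values, x_case_stage.values[:, [j]]])
            cols.append(adjacency_for_target(cloud, n, spec).sum(axis=1))
    return DegreeMatrix(
        x_ref.gene_ids, list(x_case_stage.sample_ids), np.column_stack(cols)
    )


def stage_degree_matrices(
    x_ref: ExpressionMatrix,
    x_case_stage: ExpressionMatrix,
    spec: BoxSpec,
    pooled: bool = True,
):
    """Reference- and case-centred degree matrices on the same stage cloud.

    Recomputing the reference degrees on the pooled cloud makes the two
    cohorts directly comparable (same point count, same box size), removing
    the systematic entropy offset a 25- vs 30-point cloud would inject.
    Returns ``(dm_ref_stage, dm_case_stage)``.
    """
    _check_same_genes(x_ref, x_case_stage)
    n = x_ref.n_samples
    dm_case = perturbed_degree_matrix(x_ref, x_case_stage, spec, pooled=pooled)
    if pooled:
        cloud = np.column_stack([x_ref.values, x_case_stage.values])
    else:
        cloud = x_ref.values
    ref_cols = [adjacency_for_target(cloud, t, spec).sum(axis=1) for t in range(n)]
    dm_ref = DegreeMatrix(
        x_ref.gene_ids, list(x_ref.sample_ids), np.column_stack(ref_cols)
    )
    return dm_ref, dm_case


def aggregate_reference_network(networks, vote_fraction: float = 0.5) -> SampleNetwork:
    """Vote-threshold aggregate: edge kept when present in enough networks.

    An edge survives when it appears in at least
    ``ceil(vote_fraction * n_networks)`` of the input networks.
    """
    if not networks:
        raise ValueError("need at least one network")
    if not 0.0 < vote_fraction <= 1.0:
        raise ValueError("vote_fraction must be in (0, 1]")
    votes = np.zeros_like(networks[0].adjacency, dtype=int)
    for net in networks:
        if net.gene_ids != networks[0].gene_ids:
            raise ValueError("networks must share gene_ids")
        votes += net.adjacency
    need = math.ceil(vote_fraction * len(networks))
    A = votes >= max(1, need)
    np.fill_diagonal(A, False)
    return SampleNetwork("aggregate", networks[0].gene_ids, A, networks[0].n_points)


def _topk_neighbour_order(networks, k_neighbors: int):
    gene_ids = networks[0].gene_ids
    m = len(gene_ids)
    k_neighbors = min(k_neighbors, m - 1)
    votes = np.zeros((m, m), dtype=float)
    for net in networks:
        if net.gene_ids != gene_ids:
            raise ValueError("networks must share gene_ids")
        votes += net.adjacency
    np.fill_diagonal(votes, -1.0)
    order = np.argsort(-votes, axis=1, kind="stable")
    return gene_ids, order[:, :k_neighbors]


def knn_reference_topology(networks, k_neighbors: int = 10) -> SampleNetwork:
    """Top-K co-edge-vote neighbourhood graph over the reference networks.

    For each gene, keep links to the ``k_neighbors`` genes that co-occur
    with it as an edge in the most reference networks (ties broken by gene
    order), symmetrised by union. Unlike a global vote threshold this
    guarantees every gene a neighbourhood.
    """
    if not networks:
        raise ValueError("need at least one network")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    gene_ids, top = _topk_neighbour_order(networks, k_neighbors)
    m = len(gene_ids)
    A = np.zeros((m, m), dtype=bool)
    rows = np.repeat(np.arange(m), top.shape[1])
    A[rows, top.ravel()] = True
    A = A | A.T
    np.fill_diagonal(A, False)
    return SampleNetwork("knn_topology", gene_ids, A, networks[0].n_points)


def topk_local_networks(networks, k_neighbors: int = 10) -> list:
    """Per-gene local networks from directed top-K co-edge votes.

    Each gene becomes the centre of a local network holding exactly
    ``k_neighbors`` neighbours: the genes it co-edges with in the most
    reference networks (ties broken by gene order). The fixed membership
    count keeps every centre's own degree at the same 1/(K+1) weight in
    the entropy.
    """
    if not networks:
        raise ValueError("need at least one network")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    gene_ids, top = _topk_neighbour_order(networks, k_neighbors)
    return [
        LocalNetwork(
            center=gene_ids[g],
            members=(gene_ids[g],) + tuple(gene_ids[j] for j in top[g]),
        )
        for g in range(len(gene_ids))
    ]


def extract_local_networks(topology: SampleNetwork) -> list:
    """One local network per gene with at least one neighbour.

    Members are the centre gene followed by its neighbours in gene order;
    isolated genes yield no local network.
    """
    out = []
    A = topology.adjacency
    for g in range(len(topology.gene_ids)):
        nb = np.flatnonzero(A[g])
        if nb.size == 0:
            continue
        members = (topology.gene_ids[g],) + tuple(topology.gene_ids[i] for i in nb)
        out.append(LocalNetwork(center=topology.gene_ids[g], members=members))
    return out
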