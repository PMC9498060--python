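"""Degree-matrix network entropy.

Node degrees are turned into probabilities through Gaussian CDFs fitted
per gene across a cohort's degree-matrix columns,

    p_i = Phi(x_i; mu_i, sigma_i) / sum_j Phi(x_j; mu_j, sigma_j),

normalised within each local network, and the entropy of a local network
with member degrees x and probabilities p is

    H = -(1/M) * sum_i x_i p_i ln(x_i p_i),

with 0 * ln(0) := 0. Because x_i p_i may exceed 1, H can be negative. The
global entropy is the arithmetic mean over the l local networks, and the
differential score of a stage is Delta H_T = H_perturbed - H_reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .ssn import DegreeMatrix, LocalNetwork

__all__ = [
    "GaussianParams",
    "fit_gaussian",
    "gaussian_cdf",
    "node_probabilities",
    "local_entropy",
    "global_entropy",
    "cohort_entropy",
    "entropy_at",
    "dmne_score",
    "gene_dmne_scores",
]

SIGMA_FLOOR = 1e-8


@dataclass
class GaussianParams:
    """Per-gene degree mean and standard deviation for one cohort."""

    gene_ids: list
    mu: np.ndarray = field(repr=False)
    sigma: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.size != len(self.gene_ids):
            raise ValueError("mu/sigma must align with gene_ids")
        if (self.sigma < 0).any():
            raise ValueError("sigma must be non-negative")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def take(self, genes):
        try:
            idx = [self._index[g] for g in genes]
        except KeyError as e:
            raise KeyError(f"no Gaussian parameters for gene {e.args[0]!r}") from None
        return self.mu[idx], self.sigma[idx]


def fit_gaussian(dm: DegreeMatrix) -> GaussianParams:
    """Per-gene mean and sample SD (ddof=1) across the cohort's columns.

    A single column gives sigma = 0 for every gene; the CDF then follows
    the step convention of :func:`gaussian_cdf`.
    """
    D = dm.degrees
    if D.shape[1] < 1:
        raise ValueError("degree matrix needs at least one column")
    mu = D.mean(axis=1)
    sigma = D.std(axis=1, ddof=1) if D.shape[1] >= 2 else np.zeros(D.shape[0])
    return GaussianParams(list(dm.gene_ids), mu, sigma)


def gaussian_cdf(x, mu, sigma):
    """Phi(x; mu, sigma) with a step convention at sigma = 0.

    Degenerate genes (sigma = 0) get 0 below the mean, 0.5 at it and 1
    above it; otherwise sigma is floored at 1e-8 to keep the CDF finite.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.maximum(np.asarray(sigma, dtype=float), SIGMA_FLOOR)
    out = norm.cdf(x, loc=mu, scale=sigma)
    # exact ties at a degenerate mean: force the midpoint value
    tie = (np.asarray(sigma) <= SIGMA_FLOOR) & np.isclose(x, mu)
    if np.any(tie):
        out = np.where(tie, 0.5, out)
    return out


def node_probabilities(local: LocalNetwork, x, params: GaussianParams) -> np.ndarray:
    """Normalised Gaussian-CDF node probabilities for one local network.

    ``x`` holds the member degrees (centre first, matching
    ``local.members``). If every CDF value is zero the distribution falls
    back to uniform.
    """
    x = np.asarray(x, dtype=float)
    if x.size != local.size:
        raise ValueError("x must hold one degree per member")
    mu, sigma = params.take(local.members)
    phi = gaussian_cdf(x, mu, sigma)
    total = phi.sum()
    if total <= 0:
        return np.full(local.size, 1.0 / local.size)
    return phi / total


def local_entropy(x, p) -> float:
    """H = -(1/M) sum x_i p_i ln(x_i p_i), with 0 ln 0 := 0."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if x.shape != p.shape:
        raise ValueError("x and p must align")
    xp = x * p
    terms = np.where(xp > 0, xp * np.log(np.where(xp > 0, xp, 1.0)), 0.0)
    return float(-terms.sum() / x.size)


def global_entropy(local_values) -> float:
    """Arithmetic mean of the per-local-network entropies."""
    vals = np.asarray(list(local_values), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one local network")
    return float(vals.mean())


def _local_index_arrays(locals_, gene_index):
    member_idx = np.concatenate(
        [[gene_index[g] for g in ln.members] for ln in locals_]
    ).astype(int)
    sizes = np.array([ln.size for ln in locals_])
    local_id = np.repeat(np.arange(len(locals_)), sizes)
    return member_idx, local_id, sizes


def entropy_at(x_vector, locals_, params: GaussianParams, gene_ids) -> np.ndarray:
    """Per-local-network entropy for one degree vector over all genes.

    Vectorised evaluation of :func:`node_probabilities` +
    :func:`local_entropy` for every local network at once.
    """
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    member_idx, local_id, sizes = _local_index_arrays(locals_, gene_index)
    x_vector = np.asarray(x_vector, dtype=float)
    mu, sigma = params.take(gene_ids)
    phi = gaussian_cdf(x_vector, mu, sigma)
    ph = phi[member_idx]
    denom = np.bincount(local_id, weights=ph, minlength=sizes.size)
    d = denom[local_id]
    p = np.where(d > 0, ph / np.where(d > 0, d, 1.0), 1.0 / sizes[local_id])
    xp = x_vector[member_idx] * p
    terms = np.where(xp > 0, xp * np.log(np.where(xp > 0, xp, 1.0)), 0.0)
    return -np.bincount(local_id, weights=terms, minlength=sizes.size) / sizes


def cohort_entropy(dm: DegreeMatrix, locals_, params: GaussianParams):
    """Entropies of every local network for every column of a cohort.

    Returns ``(H_per_column, H_mean, H_local)`` where ``H_local`` has shape
    (n_locals, n_columns), ``H_per_column`` is the global entropy of each
    column and ``H_mean`` their arithmetic mean.
    """
    if not locals_:
        raise ValueError("need at least one local network")
    cols = [
        entropy_at(dm.degrees[:, j], locals_, params, dm.gene_ids)
        for j in range(dm.degrees.shape[1])
    ]
    H_local = np.column_stack(cols)
    H_per_column = H_local.mean(axis=0)
    return H_per_column, float(H_per_column.mean()), H_local


def dmne_score(H_pert: float, H_ref: float) -> float:
    """Differential network entropy Delta H_T = H_perturbed - H_reference."""
    return float(H_pert) - float(H_ref)


def gene_dmne_scores(ref_locals, pert_locals, centers) -> dict:
    """Per-centre-gene differential entropy.

    ``ref_locals`` and ``pert_locals`` are per-local-network entropy values
    (column-averaged if the cohort had several columns) over the same local
    networks; ``centers`` names each local network's centre gene.
    """
    ref_locals = np.asarray(ref_locals, dtype=float)
    pert_locals = np.asarray(pert_locals, dtype=float)
    if ref_locals.shape != pert_locals.shape or len(centers) != ref_locals.size:
        raise ValueError("reference and perturbed local entropies must align")
    return {c: float(p - r) for c, r, p in zip(centers, ref_locals, pert_locals)}
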