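"""Stage scoring, critical-transition flagging, DNB and dark-gene selection."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_gem import ExpressionMatrix
from .ssn import (
    BoxSpec,
    aggregate_reference_network,
    extract_local_networks,
    reference_degree_matrix,
    stage_degree_matrices,
    topk_local_networks,
)
from .entropy import cohort_entropy, entropy_at, fit_gaussian, gene_dmne_scores

__all__ = [
    "StageScores",
    "score_stages",
    "detect_critical",
    "select_dnbs",
    "flag_dark_genes",
]


@dataclass
class StageScores:
    """Output of :func:`score_stages`.

    curve          : Delta H_T per stage (pd.Series, stage-indexed)
    gene_scores    : per-gene per-stage differential entropy (genes x stages)
    h_ref          : reference global entropy per stage (stage-matched cloud)
    h_pert         : perturbed global entropy per stage
    ref_spread     : SD of per-reference-column global entropies per stage
    locals_        : the shared local networks
    reference_dm   : degree matrix of the plain reference cloud
    """

    curve: pd.Series
    gene_scores: pd.DataFrame
    h_ref: pd.Series
    h_pert: pd.Series
    ref_spread: pd.Series
    locals_: list = field(repr=False)
    reference_dm: object = field(repr=False)


def score_stages(
    x_ref: ExpressionMatrix,
    cases_by_stage: dict,
    spec: BoxSpec | None = None,
    *,
    topology: str = "knn",
    k_neighbors: int = 10,
    vote_fraction: float = 0.5,
    pooled: bool = True,
    pert_x: str = "stage_mean",
    pert_params: str = "reference",
) -> StageScores:
    """Run the network-entropy pipeline over all stages.

    The reference side is computed once: one sample-specific network per
    reference sample, aggregated into a fixed topology from which the local
    networks are extracted (``topology='knn'`` keeps each gene's top-K
    co-edge-vote neighbours so every gene is scored; ``'vote'`` uses the
    vote-threshold aggregate). Per stage, reference- and case-centred
    degrees are recomputed on the shared stage cloud, Gaussian parameters
    are fitted on the reference columns, and the perturbed entropy is
    evaluated at the stage-mean case degrees (``pert_x='stage_mean'``) or
    per case column (``'per_column'``); ``pert_params='perturbed'`` instead
    fits the CDF parameters on the case columns.
    """
    spec = spec or BoxSpec()
    if len(cases_by_stage) < 1:
        raise ValueError("need at least one stage")
    if pert_x not in ("stage_mean", "per_column"):
        raise ValueError("pert_x must be 'stage_mean' or 'per_column'")
    if pert_params not in ("reference", "perturbed"):
        raise ValueError("pert_params must be 'reference' or 'perturbed'")

    dm_ref0, ref_nets = reference_degree_matrix(x_ref, spec)
    if topology == "knn":
        locals_ = topk_local_networks(ref_nets, k_neighbors=k_neighbors)
    elif topology == "vote":
        topo = aggregate_reference_network(ref_nets, vote_fraction=vote_fraction)
        locals_ = extract_local_networks(topo)
    else:
        raise ValueError("topology must be 'knn' or 'vote'")
    if not locals_:
        raise ValueError(
            "reference topology has no connected gene; "
            "lower vote_fraction or use topology='knn'"
        )
    centers = [ln.center for ln in locals_]

    stages = list(cases_by_stage)
    curve, h_ref_s, h_pert_s, spread_s = {}, {}, {}, {}
    gene_scores = pd.DataFrame(np.nan, index=x_ref.gene_ids, columns=stages)
    for stage in stages:
        x_case = cases_by_stage[stage]
        dm_ref_T, dm_case_T = stage_degree_matrices(x_ref, x_case, spec, pooled=pooled)
        params_ref = fit_gaussian(dm_ref_T)

        # reference baseline at the cohort-mean degrees: Phi = 0.5 exactly,
        # so probabilities are uniform and H depends only on mean degrees
        mu_ref = dm_ref_T.degrees.mean(axis=1)
        Hl_ref = entropy_at(mu_ref, locals_, params_ref, x_ref.gene_ids)

        if pert_params == "perturbed":
            params_pert = fit_gaussian(dm_case_T)
        else:
            params_pert = params_ref
        if pert_x == "stage_mean":
            x_pert = dm_case_T.degrees.mean(axis=1)
            Hl_pert = entropy_at(x_pert, locals_, params_pert, x_ref.gene_ids)
        else:
            _, _, H_local = cohort_entropy(dm_case_T, locals_, params_pert)
            Hl_pert = H_local.mean(axis=1)

        h_ref_s[stage] = float(Hl_ref.mean())
        h_pert_s[stage] = float(Hl_pert.mean())
        curve[stage] = h_pert_s[stage] - h_ref_s[stage]
        per_gene = gene_dmne_scores(Hl_ref, Hl_pert, centers)
        gene_scores.loc[list(per_gene), stage] = list(per_gene.values())

        ref_cols, _, _ = cohort_entropy(dm_ref_T, locals_, params_ref)
        spread_s[stage] = float(np.std(ref_cols, ddof=1)) if len(ref_cols) > 1 else 0.0

    return StageScores(
        curve=pd.Series(curve, name="dmne_score"),
        gene_scores=gene_scores,
        h_ref=pd.Series(h_ref_s, name="H_ref"),
        h_pert=pd.Series(h_pert_s, name="H_pert"),
        ref_spread=pd.Series(spread_s, name="ref_entropy_spread"),
        locals_=locals_,
        reference_dm=dm_ref0,
    )


def detect_critical(curve, min_ratio: float = 2.0) -> list:
    """Flag stages whose score is a sudden, outstanding local maximum.

    A stage is flagged when its score is a strict local maximum (endpoints
    compared to their single neighbour) and exceeds the curve median by at
    least ``min_ratio`` robust standard deviations (1.4826 x MAD). The rule
    is invariant to scaling the curve by a positive constant and to adding
    a constant. A constant curve has no strict local maximum, hence no
    flags; several stages may be flagged.
    """
    if min_ratio <= 0:
        raise ValueError("min_ratio must be positive")
    if isinstance(curve, pd.Series):
        labels = list(curve.index)
        c = curve.to_numpy(dtype=float)
    else:
        c = np.asarray(curve, dtype=float)
        labels = list(range(len(c)))
    T = c.size
    if T < 3:
        raise ValueError("need at least 3 stages for detection")
    med = np.median(c)
    spread = 1.4826 * np.median(np.abs(c - med))
    out = []
    for t in range(T):
        left_ok = c[t] > c[t - 1] if t > 0 else True
        right_ok = c[t] > c[t + 1] if t < T - 1 else True
        if left_ok and right_ok and c[t] >= med + min_ratio * spread:
            out.append(labels[t])
    return out


def select_dnbs(scores, k: int | None = None, fraction: float | None = None) -> list:
    """Rank genes by score (descending, ties by gene id) and keep the top.

    With neither ``k`` nor ``fraction`` given, the default is 200 genes, or
    ceil(1.5% of scored genes) when fewer than 200/0.015 genes are scored
    (so small matrices keep the published 1.5% proportion). Unscored (NaN)
    genes are excluded.
    """
    s = pd.Series(scores).dropna()
    m = s.size
    if m == 0:
        return []
    if k is not None and fraction is not None:
        raise ValueError("give either k or fraction, not both")
    if fraction is not None:
        if not 0.0 < fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        k = math.ceil(fraction * m)
    elif k is None:
        k = 200 if m >= 200 / 0.015 else math.ceil(0.015 * m)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m:
        warnings.warn(f"requested {k} DNBs but only {m} genes scored; returning all")
        k = m
    ranked = s.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:k])


def flag_dark_genes(
    scores,
    x_ref: ExpressionMatrix,
    x_case_stage: ExpressionMatrix,
    lfc_threshold: float = 0.585,
    score_quantile: float = 0.95,
) -> pd.DataFrame:
    """Non-differential genes whose network-entropy score is extreme.

    A gene is dark when |mean case - mean reference| (on the log-normalised
    values) is below ``lfc_threshold`` (default 0.585, i.e. 1.5-fold) while
    its score reaches the ``score_quantile`` quantile of the stage's gene
    scores. Returns a frame with the score and the mean shift per flagged
    gene, sorted by descending score.
    """
    if x_ref.gene_ids != x_case_stage.gene_ids:
        raise ValueError("gene sets differ between reference and case matrices")
    if not 0.0 < score_quantile < 1.0:
        raise ValueError("score_quantile must be in (0, 1)")
    s = pd.Series(scores).dropna()
    if s.empty:
        return pd.DataFrame(columns=["score", "mean_shift"])
    cut = s.quantile(score_quantile)
    shift = pd.Series(
        x_case_stage.values.mean(axis=1) - x_ref.values.mean(axis=1),
        index=x_ref.gene_ids,
    )
    dark = s[(s >= cut) & (shift.reindex(s.index).abs() < lfc_threshold)]
    out = pd.DataFrame(
        {"score": dark, "mean_shift": shift.reindex(dark.index)}
    ).sort_values("score", ascending=False, kind="stable")
    out.index.name = "gene"
    return out
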