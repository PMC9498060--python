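"""Model / results interface for degree-matrix network entropy analysis.

``DMNE`` is built from an expression matrix plus sample metadata (cohort
and stage per sample), mirroring the model/results split of statsmodels:
``DMNE(...).fit()`` returns a :class:`DMNEResults` carrying the stage
score curve, the per-gene score landscape, flagged critical stages, DNB
rankings, dark genes and run diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .io_gem import (
    ExpressionMatrix,
    SampleMetadata,
    collapse_duplicate_genes,
    filter_unexpressed,
    normalize_log1p,
    read_gem,
    read_metadata,
)
from .ssn import BoxSpec
from .detection import detect_critical, flag_dark_genes, score_stages, select_dnbs

__all__ = ["DMNE", "DMNEResults"]


class DMNE:
    """Degree-matrix network entropy model for stage-course expression data.

    Parameters
    ----------
    expression : ExpressionMatrix
        Raw (or already log-normalised) genes x samples matrix.
    metadata : SampleMetadata
        Cohort ('reference' / 'case') and stage per sample.
    box_spec : BoxSpec, optional
        Box fraction, significance level and edge rule of the network
        construction.
    min_nonzero_fraction : float
        Expression filter threshold (fraction of samples with value > 0).
    topology : {'knn', 'vote'}
        How the reference networks are condensed into the fixed local-
        network topology.
    k_neighbors, vote_fraction :
        Parameters of the two topology modes.
    pooled : bool
        Whether the stage's case samples share one point cloud.
    pert_x : {'stage_mean', 'per_column'}
        Degree value entering the perturbed entropy.
    pert_params : {'reference', 'perturbed'}
        Cohort whose degree distribution parameterises the perturbed CDFs.
    exclude_genes : iterable of str, optional
        Genes dropped before analysis (e.g. a housekeeping list).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        metadata: SampleMetadata,
        box_spec: BoxSpec | None = None,
        *,
        min_nonzero_fraction: float = 0.1,
        topology: str = "knn",
        k_neighbors: int = 10,
        vote_fraction: float = 0.5,
        pooled: bool = True,
        pert_x: str = "stage_mean",
        pert_params: str = "reference",
        exclude_genes=None,
    ):
        metadata.validate_against(expression)
        self.box_spec = box_spec or BoxSpec()
        self.metadata = metadata
        self.options = dict(
            min_nonzero_fraction=min_nonzero_fraction,
            topology=topology,
            k_neighbors=k_neighbors,
            vote_fraction=vote_fraction,
            pooled=pooled,
            pert_x=pert_x,
            pert_params=pert_params,
        )

        x = collapse_duplicate_genes(expression)
        if exclude_genes:
            drop = set(exclude_genes)
            keep = [i for i, g in enumerate(x.gene_ids) if g not in drop]
            x = ExpressionMatrix(
                [x.gene_ids[i] for i in keep], x.sample_ids, x.values[keep], x.normalized
            )
        if not x.normalized:
            x = normalize_log1p(x)
        x = filter_unexpressed(x, min_nonzero_fraction)
        if x.n_genes < 2:
            raise ValueError("fewer than 2 genes survive preprocessing")
        self.expression = x
        self.x_ref = x.subset_samples(metadata.reference_ids)
        self.cases_by_stage = {
            stage: x.subset_samples(metadata.case_ids(stage))
            for stage in metadata.stages
        }

    @classmethod
    def from_files(cls, expression_path, metadata_path, delimiter="\t", **kwargs) -> "DMNE":
        return cls(
            read_gem(expression_path, delimiter=delimiter),
            read_metadata(metadata_path),
            **kwargs,
        )

    @classmethod
    def from_dataframes(cls, expression: pd.DataFrame, metadata: pd.DataFrame, normalized=False, **kwargs) -> "DMNE":
        return cls(
            ExpressionMatrix.from_frame(expression, normalized=normalized),
            SampleMetadata(metadata),
            **kwargs,
        )

    def fit(
        self,
        min_ratio: float = 2.0,
        dnb_k: int | None = None,
        dnb_fraction: float | None = None,
        lfc_threshold: float = 0.585,
        score_quantile: float = 0.95,
    ) -> "DMNEResults":
        """Score every stage, flag critical transitions and rank genes."""
        ss = score_stages(
            self.x_ref,
            self.cases_by_stage,
            self.box_spec,
            **{
                k: self.options[k]
                for k in ("topology", "k_neighbors", "vote_fraction", "pooled", "pert_x", "pert_params")
            },
        )
        critical = detect_critical(ss.curve, min_ratio=min_ratio)
        dnbs, dark = {}, {}
        for stage in critical:
            scores = ss.gene_scores[stage]
            dnbs[stage] = select_dnbs(scores, k=dnb_k, fraction=dnb_fraction)
            dark[stage] = flag_dark_genes(
                scores,
                self.x_ref,
                self.cases_by_stage[stage],
                lfc_threshold=lfc_threshold,
                score_quantile=score_quantile,
            )
        params = dict(
            box_fraction=self.box_spec.box_fraction,
            alpha=self.box_spec.alpha,
            edge_rule=self.box_spec.edge_rule,
            min_ratio=min_ratio,
            dnb_k=dnb_k,
            dnb_fraction=dnb_fraction,
            lfc_threshold=lfc_threshold,
            score_quantile=score_quantile,
            **self.options,
        )
        return DMNEResults(
            model=self,
            stage_scores=ss,
            critical_stages=critical,
            dnbs=dnbs,
            dark_genes=dark,
            params=params,
        )


@dataclass
class DMNEResults:
    """Fitted DMNE analysis: score curve, flags, DNB and dark-gene tables."""

    model: DMNE = field(repr=False)
    stage_scores: object = field(repr=False)
    critical_stages: list
    dnbs: dict
    dark_genes: dict = field(repr=False)
    params: dict = field(repr=False)

    @property
    def curve(self) -> pd.Series:
        return self.stage_scores.curve

    @property
    def gene_scores(self) -> pd.DataFrame:
        return self.stage_scores.gene_scores

    def summary(self) -> str:
        ss = self.stage_scores
        lines = [
            "Degree-matrix network entropy (DMNE) results",
            "=" * 52,
            f"genes: {self.model.expression.n_genes}   "
            f"reference samples: {self.model.x_ref.n_samples}   "
            f"stages: {len(self.curve)}",
            f"edge rule: {self.params['edge_rule']} (alpha={self.params['alpha']}, "
            f"box fraction={self.params['box_fraction']})",
            "",
            "stage    H_ref      H_pert     dmne_score  flagged",
        ]
        for stage in self.curve.index:
            flag = "  *" if stage in self.critical_stages else ""
            lines.append(
                f"{stage!s:>5}  {ss.h_ref[stage]:9.5f}  {ss.h_pert[stage]:9.5f}  "
                f"{self.curve[stage]:10.5f}{flag}"
            )
        if self.critical_stages:
            lines.append("")
            lines.append(f"critical stages: {', '.join(map(str, self.critical_stages))}")
            for stage in self.critical_stages:
                top = self.dnbs.get(stage, [])[:5]
                lines.append(
                    f"  stage {stage}: {len(self.dnbs.get(stage, []))} DNBs "
                    f"(top: {', '.join(map(str, top))}), "
                    f"{len(self.dark_genes.get(stage, []))} dark genes"
                )
        else:
            lines.append("")
            lines.append("no critical stage flagged")
        return "\n".join(lines)

    def report(self) -> dict:
        """JSON-serialisable run report with resolved parameters."""
        return {
            "version": _version,
            "params": {k: v for k, v in self.params.items()},
            "stages": [str(s) for s in self.curve.index],
            "curve": [float(v) for v in self.curve],
            "h_ref": [float(v) for v in self.stage_scores.h_ref],
            "h_pert": [float(v) for v in self.stage_scores.h_pert],
            "ref_entropy_spread": [float(v) for v in self.stage_scores.ref_spread],
            "critical_stages": [str(s) for s in self.critical_stages],
            "n_genes": self.model.expression.n_genes,
            "n_reference": self.model.x_ref.n_samples,
        }

    def save(self, out_dir) -> Path:
        """Write scores, landscape, DNB / dark-gene tables and the report."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tab = pd.DataFrame(
            {
                "H_ref": self.stage_scores.h_ref,
                "H_pert": self.stage_scores.h_pert,
                "dmne_score": self.curve,
            }
        )
        tab.index.name = "stage"
        tab.to_csv(out / "scores.tsv", sep="\t", float_format="%.10g")
        land = self.gene_scores.stack().rename("score").reset_index()
        land.columns = ["gene", "stage", "score"]
        land.to_csv(out / "gene_scores.tsv", sep="\t", index=False, float_format="%.10g")
        for stage in self.critical_stages:
            s = pd.Series(
                self.gene_scores[stage].reindex(self.dnbs[stage]), name="score"
            )
            s.index.name = "gene"
            s.to_csv(out / f"dnbs_stage_{stage}.tsv", sep="\t", float_format="%.10g")
            self.dark_genes[stage].to_csv(
                out / f"dark_genes_stage_{stage}.tsv", sep="\t", float_format="%.10g"
            )
        (out / "report.json").write_text(json.dumps(self.report(), indent=2))
        return out

    def plot_curve(self, ax=None):
        """Stage score curve with flagged stages highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        xs = np.arange(len(self.curve))
        ax.plot(xs, self.curve.to_numpy(), marker="o", color="tab:blue")
        for i, stage in enumerate(self.curve.index):
            if stage in self.critical_stages:
                ax.axvline(i, color="tab:red", ls="--", lw=1)
        ax.set_xticks(xs, [str(s) for s in self.curve.index])
        ax.set_xlabel("stage")
        ax.set_ylabel(r"$\Delta H_T$ (nats)")
        ax.set_title("DMNE score curve")
        return ax

    def plot_landscape(self, ax=None, top: int = 50):
        """Heatmap of the per-gene score landscape (top-scoring genes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        g = self.gene_scores.dropna(how="all")
        order = g.max(axis=1).sort_values(ascending=False).index[:top]
        im = ax.imshow(g.loc[order].to_numpy(), aspect="auto", cmap="magma")
        ax.set_xticks(range(g.shape[1]), [str(s) for s in g.columns])
        ax.set_xlabel("stage")
        ax.set_ylabel(f"top {len(order)} genes")
        plt.colorbar(im, ax=ax, label="score")
        return ax
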