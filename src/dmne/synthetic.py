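"""Seeded multi-stage expression generator with a planted DNB module.

The generator realises the three statistical signatures of a dynamic
network biomarker group approaching a tipping point: at the critical stage
the module's intra-group correlation jumps (rho_base -> rho_crit), its
per-gene standard deviation inflates (x sd_crit_factor), and its
correlation to background genes stays at ``cross_rho_crit``. Reference
samples and off-critical case samples are distributionally identical
(the stable normal state); correlations are induced through a shared
per-sample latent factor, x_i = sqrt(rho) f + sqrt(1 - rho) eps_i, so the
target pairwise correlation is exact in expectation. Values are clipped at
zero to stay in the domain of the log(1 + x) preprocessing step.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_gem import ExpressionMatrix, SampleMetadata, write_gem

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "empirical_dnb_conditions", "write_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and effect-size parameters of the generator."""

    m: int = 300                 # genes
    n_ref: int = 25              # reference samples
    n_case_per_stage: int = 5    # case samples per stage
    stages: int = 5              # number of case stages
    critical_stage: int = 2      # 1-based index of the planted transition
    module_size: int = 20        # planted DNB module size
    rho_base: float = 0.1        # intra-module correlation off-critical
    rho_crit: float = 0.8        # intra-module correlation at the transition
    sd_base: float = 1.0         # per-gene SD (expression units)
    sd_crit_factor: float = 3.0  # module SD inflation at the transition
    cross_rho_crit: float = 0.0  # module-to-background correlation at k*
    baseline_mean: float = 5.0   # expression baseline
    seed: int = 0

    def __post_init__(self):
        if self.m < 2 or self.n_ref < 3 or self.n_case_per_stage < 1:
            raise ValueError("need m >= 2, n_ref >= 3, n_case_per_stage >= 1")
        if self.stages < 1:
            raise ValueError("need at least one stage")
        if not 1 <= self.critical_stage <= self.stages:
            raise ValueError("critical_stage must lie in 1..stages")
        if not 0 <= self.module_size < self.m:
            raise ValueError("module_size must be in [0, m)")
        if not 0.0 <= self.rho_base <= self.rho_crit <= 1.0:
            raise ValueError("need 0 <= rho_base <= rho_crit <= 1")
        if self.sd_crit_factor < 1.0:
            raise ValueError("sd_crit_factor must be >= 1")
        if self.sd_base <= 0:
            raise ValueError("sd_base must be positive")
        if not 0.0 <= self.cross_rho_crit <= 1.0:
            raise ValueError("cross_rho_crit must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    critical_stage: int
    module_gene_ids: tuple


def _block(rng, cfg: SyntheticConfig, module_idx, n_samples: int, critical: bool):
    """One cohort block of shape (m, n_samples)."""
    eps = rng.standard_normal((cfg.m, n_samples))
    f = rng.standard_normal(n_samples)          # shared module factor, per sample
    g = rng.standard_normal(n_samples)          # factor shared with background at k*
    rho = cfg.rho_crit if critical else cfg.rho_base
    sd_mod = cfg.sd_base * (cfg.sd_crit_factor if critical else 1.0)

    z = eps.copy()
    z[module_idx] = math.sqrt(rho) * f + math.sqrt(1.0 - rho) * eps[module_idx]
    values = cfg.baseline_mean + cfg.sd_base * z
    values[module_idx] = cfg.baseline_mean + sd_mod * z[module_idx]
    if critical and cfg.cross_rho_crit > 0:
        # couple module and background through one extra factor
        c = math.sqrt(cfg.cross_rho_crit)
        mix = lambda rows, sd: sd * (c * g + math.sqrt(1 - c * c) * z[rows])
        values[module_idx] = cfg.baseline_mean + mix(module_idx, sd_mod)
        bg = np.setdiff1d(np.arange(cfg.m), module_idx)
        values[bg] = cfg.baseline_mean + mix(bg, cfg.sd_base)
    return np.clip(values, 0.0, None)


def generate(config: SyntheticConfig):
    """Generate (ExpressionMatrix, SampleMetadata, SyntheticTruth).

    Bit-identical for a fixed config (including the seed).
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.m))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(config.m)]
    module_idx = np.sort(rng.choice(config.m, size=config.module_size, replace=False))

    blocks, sample_ids, rows = [], [], []
    blocks.append(_block(rng, config, module_idx, config.n_ref, critical=False))
    for i in range(config.n_ref):
        sid = f"R{i + 1:02d}"
        sample_ids.append(sid)
        rows.append({"sample_id": sid, "cohort": "reference", "stage": 0})
    for stage in range(1, config.stages + 1):
        blocks.append(
            _block(
                rng,
                config,
                module_idx,
                config.n_case_per_stage,
                critical=(stage == config.critical_stage),
            )
        )
        for i in range(config.n_case_per_stage):
            sid = f"S{stage}C{i + 1:02d}"
            sample_ids.append(sid)
            rows.append({"sample_id": sid, "cohort": "case", "stage": stage})

    x = ExpressionMatrix(gene_ids, sample_ids, np.column_stack(blocks), normalized=False)
    meta = SampleMetadata(pd.DataFrame(rows))
    truth = SyntheticTruth(
        critical_stage=config.critical_stage,
        module_gene_ids=tuple(gene_ids[i] for i in module_idx),
    )
    return x, meta, truth


def empirical_dnb_conditions(x: ExpressionMatrix, metadata: SampleMetadata, truth: SyntheticTruth) -> pd.DataFrame:
    """Per-stage Pearson statistics of the planted module over case samples.

    Columns: mean intra-module correlation, mean module-to-background
    correlation, mean module gene SD, and a reliability flag (False when a
    stage has fewer than 3 case samples).
    """
    mod = [x.gene_ids.index(g) for g in truth.module_gene_ids]
    bg = np.setdiff1d(np.arange(x.n_genes), mod)
    recs = {}
    for stage in metadata.stages:
        ids = metadata.case_ids(stage)
        sub = x.subset_samples(ids).values
        reliable = len(ids) >= 3
        if not reliable or len(mod) < 2:
            recs[stage] = dict(intra_r=np.nan, cross_r=np.nan, module_sd=np.nan, reliable=False)
            continue
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(sub)
        intra = C[np.ix_(mod, mod)][np.triu_indices(len(mod), 1)]
        cross = C[np.ix_(mod, bg)]
        recs[stage] = dict(
            intra_r=float(np.nanmean(intra)),
            cross_r=float(np.nanmean(cross)),
            module_sd=float(sub[mod].std(axis=1, ddof=1).mean()),
            reliable=True,
        )
    out = pd.DataFrame(recs).T
    out.index.name = "stage"
    return out


def write_dataset(x, metadata, truth, out_dir, config: SyntheticConfig | None = None):
    """Write expression.tsv, metadata.tsv and truth.json to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gem(x, out / "expression.tsv")
    metadata.table.to_csv(out / "metadata.tsv", sep="\t", index=False)
    payload = {
        "critical_stage": truth.critical_stage,
        "module_gene_ids": list(truth.module_gene_ids),
    }
    if config is not None:
        payload["config"] = asdict(config)
    (out / "truth.json").write_text(json.dumps(payload, indent=2))
    return out / "expression.tsv", out / "metadata.tsv", out / "truth.json"
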