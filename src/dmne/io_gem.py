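"""Reading, validation, preprocessing and writing of gene expression matrices.

An expression matrix is genes x samples: first column gene identifiers,
header row sample identifiers, numeric body. Sample metadata assigns each
sample to a cohort (``reference`` or ``case``) and an ordered stage label
(e.g. age in weeks). Preprocessing follows the usual microarray recipe:
collapse duplicate gene rows by averaging, then log(1 + x) with the natural
logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "read_gem",
    "write_gem",
    "read_metadata",
    "apply_id_mapping",
    "collapse_duplicate_genes",
    "normalize_log1p",
    "filter_unexpressed",
]

COHORTS = ("reference", "case")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers, unique after preprocessing.
    sample_ids : list of str
        Column identifiers, always unique.
    values : ndarray of shape (n_genes, n_samples)
        Expression values; non-negative before normalization.
    normalized : bool
        True once log(1 + x) has been applied.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValueError(f"duplicate sample id {dup!r}")
        if np.isnan(self.values).any():
            g, s = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, normalized: bool = False) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), normalized)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            self.gene_ids, list(sample_ids), self.values[:, idx], self.normalized
        )


@dataclass
class SampleMetadata:
    """Cohort and stage assignment for every sample.

    ``stages`` are kept in order of ascending numeric stage value.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        required = {"sample_id", "cohort", "stage"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        tab = self.table.copy()
        tab["sample_id"] = tab["sample_id"].astype(str)
        if tab["sample_id"].duplicated().any():
            dup = tab.loc[tab["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r} in metadata")
        bad = ~tab["cohort"].isin(COHORTS)
        if bad.any():
            raise ValueError(
                f"unknown cohort {tab.loc[bad, 'cohort'].iloc[0]!r}; "
                f"expected one of {COHORTS}"
            )
        self.table = tab.reset_index(drop=True)

    @property
    def reference_ids(self) -> list:
        return list(self.table.loc[self.table["cohort"] == "reference", "sample_id"])

    @property
    def stages(self) -> list:
        """Case stages in ascending numeric order (labels kept as given)."""
        case = self.table[self.table["cohort"] == "case"]
        uniq = case["stage"].drop_duplicates().tolist()
        return sorted(uniq, key=_stage_key)

    def case_ids(self, stage) -> list:
        case = self.table[self.table["cohort"] == "case"]
        return list(case.loc[case["stage"] == stage, "sample_id"])

    def validate_against(self, x: ExpressionMatrix, min_reference: int = 3) -> None:
        meta_ids = set(self.table["sample_id"])
        mat_ids = set(x.sample_ids)
        if meta_ids != mat_ids:
            extra = sorted(meta_ids ^ mat_ids)[:5]
            raise ValueError(f"metadata / matrix sample mismatch, e.g. {extra}")
        if len(self.reference_ids) < min_reference:
            raise ValueError(
                f"need at least {min_reference} reference samples, "
                f"got {len(self.reference_ids)}"
            )
        for st in self.stages:
            if not self.case_ids(st):
                raise ValueError(f"stage {st!r} has no case samples")


def _stage_key(v):
    try:
        return (0, float(v))
    except (TypeError, ValueError):
        return (1, str(v))


def _first_duplicate(items):
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def read_gem(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples expression table.

    First column holds gene identifiers, the header row sample identifiers.
    Malformed headers, duplicate sample ids, empty cells and non-numeric
    cells raise ``ValueError`` naming the offending row/column.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n")
    raw_ids = header.split(delimiter)[1:]  # pandas mangles duplicate columns
    dup = _first_duplicate(raw_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate sample id {dup!r} in header")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a gene-id column plus >=1 sample column")
    sample_ids = [str(c) for c in df.columns[1:]]
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:]
    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        converted = pd.to_numeric(body[col].replace("", np.nan), errors="coerce")
        if converted.isna().any():
            i = int(converted.isna().idxmax())
            raw = body[col].iloc[i]
            what = "empty cell" if raw == "" else f"non-numeric value {raw!r}"
            raise ValueError(
                f"{path}: {what} at gene {gene_ids[i]!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(gene_ids, sample_ids, values, normalized=False)


def write_gem(x: ExpressionMatrix, path, delimiter: str = "\t", float_format: str = "%.10g") -> None:
    df = x.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep=delimiter, float_format=float_format)


def read_metadata(path, delimiter: str = "\t") -> SampleMetadata:
    tab = pd.read_csv(path, sep=delimiter)
    return SampleMetadata(tab)


def apply_id_mapping(x: ExpressionMatrix, mapping: pd.DataFrame) -> ExpressionMatrix:
    """Rename probe ids to gene ids via a two-column (probe_id, gene_id) table.

    Probes without a mapping entry are dropped. Several probes may map to the
    same gene; collapse afterwards with :func:`collapse_duplicate_genes`.
    """
    if mapping.shape[1] < 2:
        raise ValueError("mapping table needs two columns: probe_id, gene_id")
    lut = dict(zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)))
    keep = [i for i, g in enumerate(x.gene_ids) if g in lut]
    new_ids = [lut[x.gene_ids[i]] for i in keep]
    return ExpressionMatrix(new_ids, x.sample_ids, x.values[keep], x.normalized)


def collapse_duplicate_genes(x: ExpressionMatrix) -> ExpressionMatrix:
    """Average rows that share a gene id; output order is first occurrence."""
    if len(set(x.gene_ids)) == len(x.gene_ids):
        return replace(x)
    order = list(dict.fromkeys(x.gene_ids))
    pos = {g: i for i, g in enumerate(order)}
    sums = np.zeros((len(order), x.n_samples))
    counts = np.zeros(len(order))
    for i, g in enumerate(x.gene_ids):
        sums[pos[g]] += x.values[i]
        counts[pos[g]] += 1
    return ExpressionMatrix(order, x.sample_ids, sums / counts[:, None], x.normalized)


def normalize_log1p(x: ExpressionMatrix) -> ExpressionMatrix:
    """Apply natural log(1 + v) to every cell; requires non-negative input."""
    if x.normalized:
        raise ValueError("matrix is already normalized")
    if (x.values < 0).any():
        g, s = np.argwhere(x.values < 0)[0]
        raise ValueError(
            f"negative value {x.values[g, s]} at gene {x.gene_ids[g]!r}, "
            f"sample {x.sample_ids[s]!r}; log(1+x) needs x >= 0"
        )
    return ExpressionMatrix(x.gene_ids, x.sample_ids, np.log1p(x.values), normalized=True)


def filter_unexpressed(x: ExpressionMatrix, min_nonzero_fraction: float = 0.1) -> ExpressionMatrix:
    """Drop genes detected in too few samples.

    A gene is kept when the fraction of samples with value > 0 is at least
    ``min_nonzero_fraction``. All-zero genes are always dropped.
    """
    if not 0.0 <= min_nonzero_fraction <= 1.0:
        raise ValueError("min_nonzero_fraction must be in [0, 1]")
    frac = (x.values > 0).mean(axis=1)
    keep = (frac >= min_nonzero_fraction) & (frac > 0)
    idx = np.flatnonzero(keep)
    return ExpressionMatrix(
        [x.gene_ids[i] for i in idx], x.sample_ids, x.values[idx], x.normalized
    )
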