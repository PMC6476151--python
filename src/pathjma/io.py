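"""Readers, writers and preprocessing for expression/phenotype tables.

Expression files are delimited text with samples in rows and genes in
columns: a header row of gene identifiers and a first column of sample
identifiers.  Phenotype files carry two columns (sample_id, value).  TSV is
the default dialect, CSV is selected by file extension, and gzip is handled
transparently by pandas.

Preprocessing follows the standard RNA-seq prediction pipeline: genes with
more than a threshold fraction of zero expression values are removed, the
remaining genes are standardized, and a continuous phenotype such as onset
age can be quantile-normalized to a standard normal distribution with a
rank-based inverse-normal transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionTable",
    "RunConfig",
    "load_expression",
    "write_expression",
    "load_phenotype",
    "write_phenotype",
    "join_samples",
    "filter_genes",
    "quantile_normalize_phenotype",
]


@dataclass
class ExpressionTable:
    """A rectangular sample-by-gene expression matrix with identifiers."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.gene_ids) != p:
            raise ValueError("identifier lists do not match the value matrix shape")
        for kind, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dup:
                raise ValueError(f"duplicate {kind} identifiers: {dup[:10]}")
        if np.isnan(self.values).any():
            raise ValueError("missing values in expression matrix")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


def _sep_for(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def load_expression(path: str | Path) -> ExpressionTable:
    """Read a delimited expression file (samples x genes, both labelled)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no gene columns found")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression values: {exc}") from exc
    table = ExpressionTable(
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        values=values,
    )
    logger.info("loaded %d samples x %d genes from %s",
                table.n_samples, table.n_genes, path)
    return table


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep=_sep_for(path), index_label="sample_id",
                            float_format="%.10g")


def load_phenotype(path: str | Path, sample_ids: list[str] | None = None) -> pd.Series:
    """Read a two-column (sample_id, value) phenotype file.

    If ``sample_ids`` is given, the result is inner-joined on sample id and
    returned in ``sample_ids`` (expression-table) order.  Non-numeric
    entries raise a parse error naming the offending line.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (sample_id, value)")
    ids = df.iloc[:, 0].astype(str)
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample identifiers: {dup[:10]}")
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if vals.isna().any():
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in vals.index[vals.isna()]]
        raise ValueError(f"{path}: non-numeric phenotype value at line(s) {lines[:10]}")
    y = pd.Series(vals.to_numpy(), index=ids, name="phenotype")
    if sample_ids is not None:
        keep = [s for s in sample_ids if s in y.index]
        if not keep:
            raise ValueError(f"{path}: no sample id in common with the expression table")
        logger.info("joined %d of %d expression samples with phenotypes",
                    len(keep), len(sample_ids))
        y = y.loc[keep]
    return y


def write_phenotype(y: pd.Series | np.ndarray, path: str | Path,
                    sample_ids: list[str] | None = None) -> None:
    if isinstance(y, pd.Series):
        ser = y
    else:
        if sample_ids is None:
            sample_ids = [f"s{i + 1}" for i in range(len(y))]
        ser = pd.Series(np.asarray(y, dtype=float), index=sample_ids, name="phenotype")
    ser.rename_axis("sample_id").to_csv(path, sep=_sep_for(path),
                                        float_format="%.10g")


def join_samples(table: ExpressionTable, y: pd.Series) -> tuple[ExpressionTable, np.ndarray]:
    """Inner-join expression and phenotype on sample id, expression order."""
    keep = [i for i, s in enumerate(table.sample_ids) if s in y.index]
    if not keep:
        raise ValueError("no sample id in common between expression and phenotype")
    kept_ids = [table.sample_ids[i] for i in keep]
    sub = ExpressionTable(kept_ids, table.gene_ids, table.values[keep])
    return sub, y.loc[kept_ids].to_numpy()


def filter_genes(
    table: ExpressionTable,
    zero_fraction_threshold: float = 0.5,
    standardize: bool = True,
) -> ExpressionTable:
    """Drop genes whose fraction of zero values *strictly exceeds* the threshold.

    Surviving genes are standardized to mean 0, sample SD 1 unless
    ``standardize=False`` (used by the model-fitting pipeline, where the
    estimator owns the training statistics so they can be stored for
    prediction on new data).
    """
    if not 0 <= zero_fraction_threshold <= 1:
        raise ValueError("zero_fraction_threshold must be in [0, 1]")
    zero_frac = (table.values == 0).mean(axis=0)
    keep = zero_frac <= zero_fraction_threshold
    if not keep.any():
        raise ValueError("all genes removed by the zero-fraction filter")
    removed = int((~keep).sum())
    if removed:
        logger.info("removed %d gene(s) with zero-fraction > %.2f",
                    removed, zero_fraction_threshold)
    vals = table.values[:, keep]
    if standardize:
        vals = vals - vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        vals = vals / sd
    return ExpressionTable(
        table.sample_ids,
        [g for g, k in zip(table.gene_ids, keep) if k],
        vals,
    )


def quantile_normalize_phenotype(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform to a standard normal.

    ``value_i = Phi^{-1}((rank_i - 0.5) / n)`` with average ranks for ties.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(y).size == 1:
        raise ValueError("phenotype is constant; quantile normalization undefined")
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.5) / y.size)


@dataclass
class RunConfig:
    """Settings for a CLI run; round-trips losslessly through YAML."""

    expression: str | None = None
    phenotype: str | None = None
    gmt: str | None = None
    output_dir: str | None = None
    delta: float = 1.0
    lower: float = 0.0
    upper: float = 1.0
    n_splits: int = 100
    train_fraction: float = 0.8
    seed: int = 0
    zero_fraction_threshold: float = 0.5
    quantile_normalize: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 <= self.zero_fraction_threshold <= 1:
            raise ValueError("zero_fraction_threshold must be in [0, 1]")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if not self.lower < self.upper:
            raise ValueError("need lower < upper")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
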