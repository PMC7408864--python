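"""Expression-matrix containers and I/O.

Datasets are normalized, log2-scale genes x samples matrices, one per study.
Reading validates shape and numeric content; probe-level matrices are
collapsed to gene level by keeping, per gene, the probe with the highest
mean expression (the common WGCNA-ecosystem convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_gene_map",
    "collapse_probes",
]


@dataclass
class ExpressionDataset:
    """One normalized genes x samples expression matrix.

    Parameters
    ----------
    dataset_id : str
        Identifier of the study the matrix came from.
    data : pandas.DataFrame
        Rows indexed by gene (or probe) id, columns by sample id, float
        values on log2 scale. NaN is allowed (handled pairwise downstream);
        infinities are not.
    """

    dataset_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(
                f"dataset {self.dataset_id!r}: duplicate sample ids {dupes}"
            )
        values = self.data.to_numpy(dtype=float, copy=False)
        if np.isinf(values).any():
            raise ValueError(f"dataset {self.dataset_id!r}: infinite values present")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def _validate_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Coerce to float, pointing at the first offending cell on failure."""
    try:
        return df.astype(float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"{path}: non-numeric value {df[col].iloc[i]!r} at "
                    f"row {df.index[i]!r} (data row {i + 1}), column {col!r} "
                    f"(data column {j + 1})"
                ) from None
        raise


def read_expression_matrix(
    path: str | Path, dialect: str = "tsv", dataset_id: str | None = None
) -> ExpressionDataset:
    """Read a genes x samples matrix from TSV, CSV or GCT.

    TSV/CSV: first column holds gene ids, header row holds sample ids.
    GCT (1.2): two header lines ("#1.2" and "<n_genes>\\t<n_samples>"),
    then Name/Description columns before the samples; Description is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if dialect not in {"tsv", "csv", "gct"}:
        raise ValueError(f"unknown dialect {dialect!r}; expected tsv, csv or gct")

    sep = "," if dialect == "csv" else "\t"
    # pandas mangles duplicate header labels, so check the raw header first
    with open(path) as fh:
        header_line = 2 if dialect == "gct" else 0
        for _ in range(header_line):
            fh.readline()
        header = fh.readline().rstrip("\n").split(sep)
    dupes = [n for i, n in enumerate(header[1:]) if n in header[1:][:i]]
    if dupes:
        raise ValueError(f"{path}: duplicate sample ids {sorted(set(dupes))}")
    try:
        if dialect == "gct":
            with open(path) as fh:
                version = fh.readline().strip()
            if not version.startswith("#1."):
                raise ValueError(f"{path}: missing GCT '#1.2' version header")
            df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0, dtype=str)
            if df.columns[0].lower() == "description":
                df = df.drop(columns=df.columns[0])
        else:
            df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed rows ({exc})") from exc

    df.index = df.index.astype(str)
    df = _validate_numeric(df, str(path))
    return ExpressionDataset(dataset_id=dataset_id or path.stem, data=df)


def write_expression_matrix(
    dataset: ExpressionDataset, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write a dataset in the dialect `read_expression_matrix` accepts."""
    path = Path(path)
    if dialect == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{dataset.n_genes}\t{dataset.n_samples}\n")
            out = dataset.data.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t")
    elif dialect in {"tsv", "csv"}:
        sep = "," if dialect == "csv" else "\t"
        out = dataset.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_probe_gene_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV of probe id -> gene symbol."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (probe, gene)")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if any(not g or (isinstance(g, float) and np.isnan(g)) for g in mapping.values()):
        raise ValueError(f"{path}: empty gene symbol in map")
    return mapping


def collapse_probes(
    dataset: ExpressionDataset, probe_map: Mapping[str, str]
) -> ExpressionDataset:
    """Collapse probe-level rows to one row per gene symbol.

    Per gene, the probe with the highest mean expression is retained (ties
    broken by probe id). Probes absent from the map are dropped with a
    warning. Rows whose id already appears as a gene symbol in the map are
    treated as mapped to themselves, which makes the operation idempotent.
    """
    if any(not g for g in probe_map.values()):
        raise ValueError("probe map contains empty gene symbols")
    effective = dict(probe_map)
    for symbol in set(probe_map.values()):
        effective.setdefault(symbol, symbol)

    present = [p for p in dataset.gene_ids if p in effective]
    if not present:
        raise ValueError(
            f"dataset {dataset.dataset_id!r}: no probes overlap the probe map"
        )
    missing = [p for p in dataset.gene_ids if p not in effective]
    if missing:
        warnings.warn(
            f"dataset {dataset.dataset_id!r}: dropping {len(missing)} probes "
            f"absent from the probe map (e.g. {missing[:3]})",
            stacklevel=2,
        )

    sub = dataset.data.loc[present]
    means = sub.mean(axis=1, skipna=True)
    keep: dict[str, str] = {}
    for probe in sorted(present):
        gene = effective[probe]
        if gene not in keep or means[probe] > means[keep[gene]]:
            keep[gene] = probe
    genes = sorted(keep)
    collapsed = sub.loc[[keep[g] for g in genes]]
    collapsed.index = pd.Index(genes, name="gene_id")
    return ExpressionDataset(dataset_id=dataset.dataset_id, data=collapsed)
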