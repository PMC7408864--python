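"""Biweight midcorrelation and multi-dataset consensus gene selection.

The screen identifies genes co-expressed with a panel of B-cell-receptor
signaling kinases. Per dataset, a robust correlation (biweight
midcorrelation, "bicor") between every gene and every panel kinase is
computed; a gene "supports" a kinase if |r| >= threshold (default 0.5) in
a dataset. Consensus counts the supporting datasets per (gene, kinase);
two selection stages follow:

stage 1: support >= min_datasets (default 5) for the anchor kinase
         (default ZAP70) and for at least one other panel kinase;
stage 2: support >= min_datasets for the anchor and for at least
         min_other_kinases (default 2) non-anchor kinases.

bicor definition (standard WGCNA form): with m = median(x) and
MAD = median(|x - m|) (unscaled), u_i = (x_i - m) / (9 MAD),
weight a_i = (1 - u_i^2)^2 * 1[|u_i| < 1], x~_i = (x_i - m) a_i, and
r = sum(x~ y~) / (||x~|| ||y~||). A vector with MAD = 0 falls back to
Pearson for that pair and the record is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionDataset

__all__ = [
    "KINASE_PANEL",
    "ConsensusCounts",
    "SelectionResult",
    "biweight_midcorrelation",
    "bicor_matrix",
    "correlate_collection",
    "build_consensus",
    "select_stage1",
    "select_stage2",
    "rank_by_support",
    "kinase_overlap_matrix",
    "normalize_kinase_name",
]

#: Default BcR-signaling kinase panel (HGNC symbols).
KINASE_PANEL = ("ZAP70", "AKT1", "AKT2", "BTK", "MAPK1", "MAPK3", "PIK3CD")

#: Common alternate spellings mapped to HGNC.
_KINASE_ALIASES = {"PI3KCD": "PIK3CD"}

DEFAULT_MIN_OVERLAP = 8


def normalize_kinase_name(name: str) -> str:
    return _KINASE_ALIASES.get(name, name)


def _biweight_transform(x: np.ndarray) -> np.ndarray | None:
    """Median/MAD weighted deviations; None signals MAD == 0."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        return None
    u = (x - med) / (9.0 * mad)
    a = np.square(1.0 - np.square(u)) * (np.abs(u) < 1.0)
    return (x - med) * a


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0.0:
        raise ValueError("constant vector: correlation undefined")
    return float(np.clip(np.dot(xc, yc) / denom, -1.0, 1.0))


def biweight_midcorrelation(
    x: Sequence[float],
    y: Sequence[float],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float:
    """Biweight midcorrelation of two vectors with pairwise NaN deletion.

    Falls back to Pearson when either vector has zero MAD on the complete
    pairs (see `biweight_midcorrelation_flagged` to observe the fallback).
    """
    r, _ = biweight_midcorrelation_flagged(x, y, min_overlap=min_overlap)
    return r


def biweight_midcorrelation_flagged(
    x: Sequence[float],
    y: Sequence[float],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[float, bool]:
    """bicor plus a flag marking the zero-MAD Pearson fallback."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    n_used = int(mask.sum())
    if n_used < min_overlap:
        raise ValueError(
            f"only {n_used} complete pairs; minimum overlap is {min_overlap}"
        )
    xv, yv = x[mask], y[mask]
    xt = _biweight_transform(xv)
    yt = _biweight_transform(yv)
    if xt is None or yt is None:
        return _pearson(xv, yv), True
    denom = np.sqrt(np.sum(xt**2)) * np.sqrt(np.sum(yt**2))
    if denom == 0.0:
        return _pearson(xv, yv), True
    return float(np.clip(np.dot(xt, yt) / denom, -1.0, 1.0)), False


def bicor_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """All-pairs bicor between rows of X (p x n) and rows of Y (q x n).

    Complete-data fast path: rows are transformed once and correlations
    obtained as a single matrix product. Rows with zero MAD fall back to
    Pearson (centred/normalized), matching the scalar routine.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must be 2-D with matching sample dimension")

    def transform_rows(M: np.ndarray) -> np.ndarray:
        med = np.median(M, axis=1, keepdims=True)
        mad = np.median(np.abs(M - med), axis=1, keepdims=True)
        bad = (mad == 0.0).ravel()
        safe_mad = np.where(mad == 0.0, 1.0, mad)
        u = (M - med) / (9.0 * safe_mad)
        a = np.square(1.0 - np.square(u)) * (np.abs(u) < 1.0)
        T = (M - med) * a
        if bad.any():  # Pearson fallback rows
            C = M[bad] - M[bad].mean(axis=1, keepdims=True)
            T[bad] = C
        norms = np.sqrt(np.sum(T**2, axis=1, keepdims=True))
        norms[norms == 0.0] = np.nan
        return T / norms

    return np.clip(transform_rows(X) @ transform_rows(Y).T, -1.0, 1.0)


def correlate_collection(
    datasets: Iterable[ExpressionDataset],
    kinase_panel: Sequence[str] = KINASE_PANEL,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Per-dataset gene-kinase bicor records.

    Returns a tidy frame with columns (dataset_id, gene, kinase, r, n_used,
    pearson_fallback); one row per (dataset, gene, kinase present in that
    dataset). Panel kinases are excluded from the gene side. Genes with
    missing values are handled with pairwise deletion; pairs below the
    minimum overlap are dropped.
    """
    panel = [normalize_kinase_name(k) for k in kinase_panel]
    if len(set(panel)) != len(panel):
        raise ValueError("kinase panel contains duplicates")
    frames: list[pd.DataFrame] = []
    any_kinase = False
    for ds in datasets:
        present = [k for k in panel if k in ds.data.index]
        if not present:
            continue
        any_kinase = True
        genes = [g for g in ds.gene_ids if g not in set(panel)]
        if not genes:
            continue
        G = ds.data.loc[genes].to_numpy(dtype=float)
        K = ds.data.loc[present].to_numpy(dtype=float)
        if ds.n_samples < min_overlap:
            continue
        if np.isnan(G).any() or np.isnan(K).any():
            rows = []
            for gi, g in enumerate(genes):
                for ki, k in enumerate(present):
                    mask = ~(np.isnan(G[gi]) | np.isnan(K[ki]))
                    if mask.sum() < min_overlap:
                        continue
                    r, fb = biweight_midcorrelation_flagged(
                        G[gi], K[ki], min_overlap=min_overlap
                    )
                    rows.append((ds.dataset_id, g, k, r, int(mask.sum()), fb))
            frames.append(
                pd.DataFrame(
                    rows,
                    columns=[
                        "dataset_id", "gene", "kinase", "r", "n_used",
                        "pearson_fallback",
                    ],
                )
            )
        else:
            R = bicor_matrix(G, K)
            mad_g = np.median(
                np.abs(G - np.median(G, axis=1, keepdims=True)), axis=1
            )
            mad_k = np.median(
                np.abs(K - np.median(K, axis=1, keepdims=True)), axis=1
            )
            fb = (mad_g[:, None] == 0.0) | (mad_k[None, :] == 0.0)
            frames.append(
                pd.DataFrame(
                    {
                        "dataset_id": ds.dataset_id,
                        "gene": np.repeat(genes, len(present)),
                        "kinase": np.tile(present, len(genes)),
                        "r": R.ravel(),
                        "n_used": ds.n_samples,
                        "pearson_fallback": fb.ravel(),
                    }
                )
            )
    if not any_kinase:
        raise ValueError("no dataset contains any kinase from the panel")
    if not frames:
        return pd.DataFrame(
            columns=["dataset_id", "gene", "kinase", "r", "n_used", "pearson_fallback"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.dropna(subset=["r"]).reset_index(drop=True)


@dataclass
class ConsensusCounts:
    """Per (gene, kinase) count of datasets passing the |r| threshold.

    `counts` is a genes x kinases integer frame. With `joint_with_anchor`
    the count for (gene, k) is instead the number of datasets where the
    gene passes for BOTH the anchor and k simultaneously (the stricter
    same-datasets reading of the consensus rule).
    """

    counts: pd.DataFrame = field(repr=False)
    threshold: float
    n_datasets: int
    anchor_joint: str | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def kinases(self) -> list[str]:
        return list(self.counts.columns)

    def support(self, min_datasets: int) -> pd.DataFrame:
        """Boolean genes x kinases support indicator."""
        return self.counts >= min_datasets


def build_consensus(
    records: pd.DataFrame,
    threshold: float = 0.5,
    same_datasets_anchor: str | None = None,
) -> ConsensusCounts:
    """Count, per (gene, kinase), the datasets with |r| >= threshold.

    Both correlation signs count (absolute threshold). When
    `same_datasets_anchor` is given, a dataset counts towards (gene, k)
    only if the gene also passes for the anchor in that same dataset.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if records.empty:
        raise ValueError("no correlation records")
    rec = records.copy()
    rec["pass"] = rec["r"].abs() >= threshold
    n_datasets = rec["dataset_id"].nunique()

    if same_datasets_anchor is not None:
        anchor = normalize_kinase_name(same_datasets_anchor)
        if anchor not in set(rec["kinase"]):
            raise ValueError(f"anchor kinase {anchor!r} absent from records")
        apass = (
            rec[rec["kinase"] == anchor]
            .set_index(["dataset_id", "gene"])["pass"]
            .rename("anchor_pass")
        )
        rec = rec.join(apass, on=["dataset_id", "gene"])
        rec["anchor_pass"] = rec["anchor_pass"].fillna(False)
        rec["pass"] &= rec["anchor_pass"].astype(bool)

    counts = (
        rec.pivot_table(
            index="gene", columns="kinase", values="pass",
            aggfunc="sum", fill_value=0,
        )
        .astype(int)
    )
    counts = counts.sort_index()
    return ConsensusCounts(
        counts=counts,
        threshold=threshold,
        n_datasets=n_datasets,
        anchor_joint=same_datasets_anchor,
    )


def select_stage1(
    counts: ConsensusCounts, anchor: str = "ZAP70", min_datasets: int = 5
) -> list[str]:
    """Genes supported for the anchor and >=1 other kinase, each in
    >= min_datasets datasets (support counted per kinase independently)."""
    anchor = normalize_kinase_name(anchor)
    if anchor not in counts.kinases:
        raise ValueError(f"anchor kinase {anchor!r} absent from consensus counts")
    sup = counts.support(min_datasets)
    others = [k for k in counts.kinases if k != anchor]
    mask = sup[anchor] & (sup[others].sum(axis=1) >= 1 if others else False)
    return sorted(sup.index[mask])


@dataclass
class SelectionResult:
    """Outcome of the two-stage consensus selection."""

    stage1_genes: list[str]
    stage2_genes: list[str]  # ordered per rank_by_support
    kinase_support: dict[str, list[str]]  # stage-2 gene -> supported kinases
    overlap_matrix: pd.DataFrame = field(repr=False)
    anchor: str = "ZAP70"
    min_datasets: int = 5
    min_other_kinases: int = 2
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "anchor": self.anchor,
            "threshold": self.threshold,
            "min_datasets": self.min_datasets,
            "min_other_kinases": self.min_other_kinases,
            "n_stage1": len(self.stage1_genes),
            "n_stage2": len(self.stage2_genes),
            "stage1_genes": self.stage1_genes,
            "stage2_genes": self.stage2_genes,
            "kinase_support": self.kinase_support,
            "overlap_matrix": self.overlap_matrix.to_dict(),
        }


def select_stage2(
    counts: ConsensusCounts,
    stage1_genes: Sequence[str] | None = None,
    anchor: str = "ZAP70",
    min_other_kinases: int = 2,
    min_datasets: int = 5,
) -> SelectionResult:
    """Stage-2 selection: anchor support plus >= min_other_kinases other
    kinases supported, each in >= min_datasets datasets."""
    anchor = normalize_kinase_name(anchor)
    if anchor not in counts.kinases:
        raise ValueError(f"anchor kinase {anchor!r} absent from consensus counts")
    others = [k for k in counts.kinases if k != anchor]
    if min_other_kinases > len(others):
        raise ValueError(
            f"min_other_kinases={min_other_kinases} exceeds panel size - 1 "
            f"({len(others)})"
        )
    if stage1_genes is None:
        stage1_genes = select_stage1(counts, anchor=anchor, min_datasets=min_datasets)
    sup = counts.support(min_datasets)
    mask = sup[anchor] & (sup[others].sum(axis=1) >= min_other_kinases)
    stage2 = [g for g in sup.index[mask] if g in set(stage1_genes)] if min_other_kinases >= 1 else sorted(sup.index[sup[anchor]])
    support_sets = {
        g: sorted(k for k in counts.kinases if sup.loc[g, k]) for g in stage2
    }
    result = SelectionResult(
        stage1_genes=sorted(stage1_genes),
        stage2_genes=sorted(stage2),
        kinase_support=support_sets,
        overlap_matrix=pd.DataFrame(),
        anchor=anchor,
        min_datasets=min_datasets,
        min_other_kinases=min_other_kinases,
        threshold=counts.threshold,
    )
    result.stage2_genes = rank_by_support(result, counts)
    result.overlap_matrix = kinase_overlap_matrix(result)
    return result


def rank_by_support(selection: SelectionResult, counts: ConsensusCounts) -> list[str]:
    """Order stage-2 genes by total supporting-dataset count (summed over
    kinases), descending; ties broken lexicographically by gene name."""
    genes = selection.stage2_genes
    if not genes:
        return []
    totals = counts.counts.loc[genes].sum(axis=1)
    return sorted(genes, key=lambda g: (-int(totals[g]), g))


def kinase_overlap_matrix(selection: SelectionResult) -> pd.DataFrame:
    """Kinase x kinase matrix: entry (i, j) counts selected genes supported
    for both kinases; the diagonal holds per-kinase totals."""
    kinases = sorted({k for ks in selection.kinase_support.values() for k in ks})
    mat = pd.DataFrame(0, index=kinases, columns=kinases, dtype=int)
    for ks in selection.kinase_support.values():
        for i in ks:
            for j in ks:
                mat.loc[i, j] += 1
    return mat
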