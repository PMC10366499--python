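"""Ambient-gene identification, per-cell ambient percentages, standard QC.

Ambient transcripts contaminate *all* droplets, so a truly ambient gene
should be detected in nearly every retained barcode, cells and empties
alike.  Allowing for droplet-level sampling dropout, genes with a
dropout rate below 2% (configurable) across the retained (4x-truncated)
barcode set are called ambient.  The share of each putative cell's UMIs
falling in ambient genes, and the number of ambient genes, complete the
contamination metric set; conventional QC summaries (UMIs/cell,
genes/cell, % mitochondrial) are computed on the same rank-based cell
proxy (the top ``n_cells_est`` barcodes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import QCWarning
from .io import CountMatrix

__all__ = [
    "AmbientGeneSet",
    "MetricSet",
    "gene_dropout",
    "ambient_gene_set",
    "percent_counts_ambient",
    "standard_qc",
    "DEFAULT_DROPOUT_THRESHOLD",
    "DEFAULT_MITO_PREFIXES",
]

DEFAULT_DROPOUT_THRESHOLD = 0.02
DEFAULT_MITO_PREFIXES = ("mt-", "MT-")


@dataclass
class AmbientGeneSet:
    """Genes with dropout strictly below the threshold."""

    dropout: np.ndarray
    mask: np.ndarray
    ambient_ids: np.ndarray
    threshold: float

    @property
    def n_ambient(self) -> int:
        return int(self.mask.sum())


@dataclass
class MetricSet:
    """All quality metrics for one dataset.

    Contamination metrics (higher = more contaminated):
    ``empty_droplet_slope_sum``, ``inverted_max_secant``,
    ``inverted_secant_sd``, ``inverted_auc_pct``, ``n_ambient_genes``,
    ``avg_pct_counts_ambient`` (plus its companion
    ``avg_ambient_umi_per_cell``); standard metrics: ``n_cells``,
    ``avg_pct_counts_mito``, ``avg_genes_per_cell``, ``avg_umi_per_cell``;
    ``overall_score`` in [0, 1] (0 = perfect signal-to-noise, 1 = all
    noise), filled in by the scoring module.
    """

    empty_droplet_slope_sum: float
    inverted_max_secant: float
    inverted_secant_sd: float
    inverted_auc_pct: float
    n_ambient_genes: int
    avg_pct_counts_ambient: float
    avg_ambient_umi_per_cell: float
    n_cells: int
    avg_pct_counts_mito: float
    avg_genes_per_cell: float
    avg_umi_per_cell: float
    overall_score: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        for name in (
            "empty_droplet_slope_sum",
            "inverted_max_secant",
            "inverted_auc_pct",
        ):
            value = getattr(self, name)
            if not -1e-9 <= value <= 1 + 1e-9:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if not -1e-9 <= self.inverted_secant_sd <= 0.5 + 1e-9:
            raise ValueError(f"inverted_secant_sd={self.inverted_secant_sd} outside [0, 0.5]")
        for name in ("avg_pct_counts_ambient", "avg_pct_counts_mito"):
            value = getattr(self, name)
            if not -1e-9 <= value <= 100 + 1e-9:
                raise ValueError(f"{name}={value} outside [0, 100]")

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "empty_droplet_slope_sum": self.empty_droplet_slope_sum,
            "inverted_max_secant": self.inverted_max_secant,
            "inverted_secant_sd": self.inverted_secant_sd,
            "inverted_auc_pct": self.inverted_auc_pct,
            "n_ambient_genes": self.n_ambient_genes,
            "avg_pct_counts_ambient": self.avg_pct_counts_ambient,
            "avg_ambient_umi_per_cell": self.avg_ambient_umi_per_cell,
            "n_cells": self.n_cells,
            "avg_pct_counts_mito": self.avg_pct_counts_mito,
            "avg_genes_per_cell": self.avg_genes_per_cell,
            "avg_umi_per_cell": self.avg_umi_per_cell,
            "overall_score": self.overall_score,
        }

    @classmethod
    def from_dict(cls, record: dict) -> "MetricSet":
        return cls(**{k: v for k, v in record.items() if k in cls.__dataclass_fields__})


def gene_dropout(counts_truncated: CountMatrix) -> np.ndarray:
    """Per-gene fraction of retained barcodes with zero count."""
    n = counts_truncated.n_barcodes
    detected = np.asarray((counts_truncated.values > 0).sum(axis=0)).ravel()
    return 1.0 - detected / n


def ambient_gene_set(
    dropout: np.ndarray,
    gene_ids: np.ndarray,
    threshold: float = DEFAULT_DROPOUT_THRESHOLD,
) -> AmbientGeneSet:
    """Genes with dropout *strictly* below ``threshold`` are ambient."""
    dropout = np.asarray(dropout, dtype=float)
    mask = dropout < threshold
    return AmbientGeneSet(
        dropout=dropout,
        mask=mask,
        ambient_ids=np.asarray(gene_ids, dtype=object)[mask],
        threshold=float(threshold),
    )


def percent_counts_ambient(
    counts_truncated: CountMatrix,
    ambient: AmbientGeneSet,
    n_cells_est: int,
) -> tuple[np.ndarray, float, float]:
    """Share of each cell's UMIs that fall in ambient genes.

    The top ``n_cells_est`` barcodes of the (rank-ordered) truncated
    matrix stand in for the cells.  Returns the per-cell percentage
    vector, its mean, and the mean ambient UMI count per cell.  A cell
    with zero total counts gets 0% with a warning.
    """
    cells = counts_truncated.values[: int(n_cells_est)]
    totals = np.asarray(cells.sum(axis=1)).ravel().astype(float)
    ambient_counts = np.asarray(cells[:, ambient.mask].sum(axis=1)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell barcode(s) with zero total counts; "
            "percent counts ambient set to 0 for them",
            QCWarning,
            stacklevel=2,
        )
        totals[zero] = 1.0
        ambient_counts[zero] = 0.0
    pct = 100.0 * ambient_counts / totals
    return pct, float(pct.mean()), float(ambient_counts.mean())


def standard_qc(
    counts_truncated: CountMatrix,
    n_cells_est: int,
    mito_prefixes=DEFAULT_MITO_PREFIXES,
) -> tuple[int, float, float, float]:
    """Conventional QC summaries over the top ``n_cells_est`` barcodes.

    Returns ``(n_cells, avg % mito counts, avg genes per cell,
    avg UMIs per cell)``.  Mitochondrial genes are matched by symbol
    prefix (case-sensitive per prefix; default ``mt-``/``MT-``); if no
    gene matches, the mitochondrial percentage is 0 with a warning.
    """
    symbols = counts_truncated.symbols()
    mito_mask = np.array(
        [any(str(s).startswith(p) for p in mito_prefixes) for s in symbols], dtype=bool
    )
    cells = counts_truncated.values[: int(n_cells_est)]
    totals = np.asarray(cells.sum(axis=1)).ravel().astype(float)
    genes_per_cell = np.asarray((cells > 0).sum(axis=1)).ravel().astype(float)
    safe_totals = np.where(totals == 0, 1.0, totals)
    if mito_mask.any():
        mito_counts = np.asarray(cells[:, mito_mask].sum(axis=1)).ravel().astype(float)
        pct_mito = float((100.0 * mito_counts / safe_totals).mean())
    else:
        warnings.warn(
            "no gene symbol matched the mitochondrial prefixes "
            f"{tuple(mito_prefixes)}; percent mito set to 0",
            QCWarning,
            stacklevel=2,
        )
        pct_mito = 0.0
    return int(n_cells_est), pct_mito, float(genes_per_cell.mean()), float(totals.mean())
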