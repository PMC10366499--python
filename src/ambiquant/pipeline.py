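"""End-to-end scoring: single samples, cohorts, and calibration sweeps.

``compute_metrics`` chains the full pipeline on an in-memory
CountMatrix: rank barcodes, estimate (or accept) the real-cell number,
truncate to ``multiple x`` that number, compute the curve-geometry and
slope-distribution metrics, the ambient-gene metrics, the standard QC
summaries, and the overall score.  ``run_sample``/``run_cohort`` wrap it
with file I/O and a sample manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import curve_metrics as cm
from . import slope_metrics as sm
from .ambient import (
    DEFAULT_DROPOUT_THRESHOLD,
    DEFAULT_MITO_PREFIXES,
    MetricSet,
    ambient_gene_set,
    gene_dropout,
    percent_counts_ambient,
    standard_qc,
)
from .io import CountMatrix, read_h5_counts, read_mtx, report_frame
from .rankcurve import estimate_cell_number, rank_barcodes, truncate_and_normalize
from .scoring import ScoreModel, default_model, overall_score

__all__ = [
    "RunConfig",
    "CohortResult",
    "compute_metrics",
    "load_counts",
    "run_sample",
    "run_cohort",
    "collect_sweep_metrics",
]

logger = logging.getLogger("ambiquant")

#: metric columns used for the per-row min-max normalized cohort view
_NORMALIZED_COLUMNS = [
    "empty_droplet_slope_sum",
    "inverted_max_secant",
    "inverted_secant_sd",
    "inverted_auc_pct",
    "n_ambient_genes",
    "avg_pct_counts_ambient",
    "avg_ambient_umi_per_cell",
    "avg_pct_counts_mito",
    "avg_genes_per_cell",
    "avg_umi_per_cell",
    "overall_score",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults match the method)."""

    input: str | Path
    expected_cells: int | None = None
    multiple: int = 4
    n_bins: int = 100
    dropout_threshold: float = DEFAULT_DROPOUT_THRESHOLD
    mito_prefixes: tuple = DEFAULT_MITO_PREFIXES
    model: str | Path | ScoreModel | None = "builtin"
    sample_id: str | None = None


def _resolve_model(model) -> ScoreModel | None:
    if model is None:
        return None
    if isinstance(model, ScoreModel):
        return model
    if model == "builtin":
        return default_model()
    return ScoreModel.load(model)


def load_counts(path: str | Path) -> CountMatrix:
    """Load counts from an MTX directory or an HDF5/h5ad file."""
    path = Path(path)
    if path.is_dir():
        return read_mtx(path)
    if path.suffix in {".h5", ".hdf5", ".h5ad"}:
        return read_h5_counts(path)
    raise ValueError(f"cannot infer input format of {path}")


def compute_metrics(
    counts: CountMatrix,
    *,
    expected_cells: int | None = None,
    multiple: int = 4,
    n_bins: int = 100,
    dropout_threshold: float = DEFAULT_DROPOUT_THRESHOLD,
    mito_prefixes=DEFAULT_MITO_PREFIXES,
    model: str | Path | ScoreModel | None = "builtin",
    sample_id: str | None = None,
) -> MetricSet:
    """Run the full contamination-metric pipeline on a count matrix.

    ``expected_cells`` bypasses knee estimation when the real cell
    number is known.  ``model`` selects the overall-score weights
    (``"builtin"`` default, a path, a :class:`ScoreModel`, or ``None``
    to skip the overall score).
    """
    totals_sorted, _ = rank_barcodes(counts)
    if expected_cells is not None:
        n_cells_est = int(expected_cells)
        logger.info("using user-supplied expected cell number: %d", n_cells_est)
    else:
        n_cells_est = estimate_cell_number(totals_sorted, fallback_multiple=multiple)
        logger.info("estimated cell number from knee: %d", n_cells_est)

    curve, truncated = truncate_and_normalize(counts, n_cells_est, multiple=multiple)
    logger.info("retained N=%d barcodes (multiple=%d)", curve.N, multiple)

    profile = cm.secant_profile(curve)
    slopes = sm.slope_series(curve)
    dist = sm.scaled_slope_distribution(slopes, n_bins=n_bins)
    logger.info("slope threshold (median+sd): %g", dist.threshold)

    dropout = gene_dropout(truncated)
    ambient = ambient_gene_set(dropout, truncated.gene_ids, threshold=dropout_threshold)
    logger.info("ambient genes (dropout < %g): %d", dropout_threshold, ambient.n_ambient)
    _, avg_pct_ambient, avg_ambient_umi = percent_counts_ambient(
        truncated, ambient, n_cells_est
    )
    n_cells, pct_mito, genes_per_cell, umi_per_cell = standard_qc(
        truncated, n_cells_est, mito_prefixes=mito_prefixes
    )

    metrics = MetricSet(
        empty_droplet_slope_sum=sm.empty_droplet_slope_sum(dist),
        inverted_max_secant=cm.inverted_max_secant(profile),
        inverted_secant_sd=cm.inverted_secant_sd(profile),
        inverted_auc_pct=cm.inverted_auc_percentage(curve),
        n_ambient_genes=ambient.n_ambient,
        avg_pct_counts_ambient=avg_pct_ambient,
        avg_ambient_umi_per_cell=avg_ambient_umi,
        n_cells=n_cells,
        avg_pct_counts_mito=pct_mito,
        avg_genes_per_cell=genes_per_cell,
        avg_umi_per_cell=umi_per_cell,
        sample_id=sample_id,
    )
    resolved = _resolve_model(model)
    if resolved is not None:
        metrics.overall_score = overall_score(metrics, resolved)
    return metrics


def run_sample(config: RunConfig) -> MetricSet:
    """Load one sample and compute its MetricSet."""
    try:
        counts = load_counts(config.input)
        return compute_metrics(
            counts,
            expected_cells=config.expected_cells,
            multiple=config.multiple,
            n_bins=config.n_bins,
            dropout_threshold=config.dropout_threshold,
            mito_prefixes=config.mito_prefixes,
            model=config.model,
            sample_id=config.sample_id or str(config.input),
        )
    except Exception as exc:
        raise type(exc)(f"[sample {config.sample_id or config.input}] {exc}") from exc


@dataclass
class CohortResult:
    """Per-sample metrics plus the cohort table and error records."""

    metric_sets: list
    table: pd.DataFrame
    errors: list = field(default_factory=list)

    @property
    def n_failed(self) -> int:
        return len(self.errors)

    def normalized_table(self) -> pd.DataFrame:
        """Min-max normalize each metric across samples (for heatmaps)."""
        table = self.table.copy()
        for col in _NORMALIZED_COLUMNS:
            if col in table:
                vals = table[col].astype(float)
                span = vals.max() - vals.min()
                table[col] = 0.0 if span == 0 else (vals - vals.min()) / span
        return table


def run_cohort(
    manifest: str | Path | pd.DataFrame,
    *,
    model: str | Path | ScoreModel | None = "builtin",
    multiple: int = 4,
    n_bins: int = 100,
    dropout_threshold: float = DEFAULT_DROPOUT_THRESHOLD,
    mito_prefixes=DEFAULT_MITO_PREFIXES,
) -> CohortResult:
    """Score every sample of a manifest; failures are recorded, not fatal.

    The manifest (TSV path or DataFrame) needs ``sample_id`` and
    ``path`` columns; an optional ``expected_cells`` column overrides
    knee estimation per sample, and any further columns are carried into
    the cohort table as metadata.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, sep="\t")
    for required in ("sample_id", "path"):
        if required not in manifest.columns:
            raise ValueError(f"manifest is missing required column {required!r}")

    resolved = _resolve_model(model)
    metric_sets, errors, meta_rows = [], [], []
    meta_cols = [c for c in manifest.columns if c not in {"sample_id", "path", "expected_cells"}]
    for _, row in manifest.iterrows():
        expected = row.get("expected_cells")
        expected = None if pd.isna(expected) else int(expected)
        config = RunConfig(
            input=row["path"],
            expected_cells=expected,
            multiple=multiple,
            n_bins=n_bins,
            dropout_threshold=dropout_threshold,
            mito_prefixes=mito_prefixes,
            model=resolved,
            sample_id=str(row["sample_id"]),
        )
        try:
            metric_sets.append(run_sample(config))
            meta_rows.append({c: row[c] for c in meta_cols})
        except Exception as exc:
            logger.error("sample %s failed: %s", row["sample_id"], exc)
            errors.append({"sample_id": str(row["sample_id"]), "error": str(exc)})

    table = report_frame(metric_sets)
    for col in meta_cols:
        table[col] = [m.get(col) for m in meta_rows]
    return CohortResult(metric_sets=metric_sets, table=table, errors=errors)


def collect_sweep_metrics(
    params_grid,
    levels_per_param=None,
    *,
    model=None,
    expected_cells: int | None = None,
    multiple: int = 4,
) -> pd.DataFrame:
    """Simulate each parameter set, score it, and discard it (streaming).

    Returns a DataFrame of metric values with an ``ambient_level``
    column; used by calibration and the sweep-based validation suites.
    """
    from .simulate import simulate_dataset

    rows = []
    for params in params_grid:
        dataset = simulate_dataset(params)
        ms = compute_metrics(
            dataset.counts,
            expected_cells=expected_cells,
            multiple=multiple,
            model=model,
        )
        record = ms.to_dict()
        record["ambient_level"] = params.ambient_umi_level
        rows.append(record)
    return pd.DataFrame(rows)
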