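"""Reading and writing unfiltered count matrices and metric reports.

The universal in-memory container is :class:`CountMatrix`: a sparse
barcodes x genes matrix of raw UMI counts with barcode and gene
identifiers.  Supported on-disk formats are Matrix Market triplets with
TSV annotations (CellRanger-style, either orientation), 10x-style HDF5
(``raw_feature_bc_matrix``-like layout), and ``.h5ad``.  Barcode and
gene order is always preserved exactly as on disk; ranking happens
downstream, never at I/O time.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import FormatError

__all__ = [
    "CountMatrix",
    "read_mtx",
    "read_h5_counts",
    "write_mtx",
    "write_h5_counts",
    "write_dataset",
    "write_report",
    "REPORT_COLUMNS",
]

#: Canonical report column order: five curve/gene contamination metrics,
#: average percent counts ambient (+ its UMI companion), four standard QC
#: metrics, and the overall score.
REPORT_COLUMNS = [
    "empty_droplet_slope_sum",
    "inverted_max_secant",
    "inverted_secant_sd",
    "inverted_auc_pct",
    "n_ambient_genes",
    "avg_pct_counts_ambient",
    "avg_ambient_umi_per_cell",
    "n_cells",
    "avg_pct_counts_mito",
    "avg_genes_per_cell",
    "avg_umi_per_cell",
    "overall_score",
]


@dataclass
class CountMatrix:
    """Sparse barcodes x genes raw UMI count matrix with identifiers.

    Parameters
    ----------
    values
        Sparse non-negative integer matrix, one row per barcode.
    barcodes
        Unique barcode identifiers, one per row.
    gene_ids
        Gene identifiers, one per column.
    gene_symbols
        Optional gene symbols (used e.g. for mitochondrial matching);
        falls back to ``gene_ids`` when absent.
    """

    values: sp.csr_matrix
    barcodes: np.ndarray
    gene_ids: np.ndarray
    gene_symbols: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.gene_symbols is not None:
            self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        n_bc, n_genes = self.values.shape
        if len(self.barcodes) != n_bc or len(self.gene_ids) != n_genes:
            raise FormatError(
                f"annotation lengths ({len(self.barcodes)} barcodes, "
                f"{len(self.gene_ids)} genes) do not match matrix shape {self.values.shape}"
            )
        self.values.data = _ensure_integer_data(self.values)
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("count matrix contains negative entries")
        uniq, counts = np.unique(self.barcodes.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1][0]
            raise FormatError(f"duplicate barcode identifier: {dup!r}")

    # -- convenience accessors -------------------------------------------
    @property
    def n_barcodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def barcode_totals(self) -> np.ndarray:
        """Total UMI count per barcode."""
        return np.asarray(self.values.sum(axis=1)).ravel()

    def total(self) -> int:
        """Total UMI count of the whole matrix."""
        return int(self.values.sum())

    def symbols(self) -> np.ndarray:
        return self.gene_symbols if self.gene_symbols is not None else self.gene_ids

    def subset_barcodes(self, index: np.ndarray) -> "CountMatrix":
        """Row-subset (and/or reorder) by positional barcode index."""
        return CountMatrix(
            self.values[index],
            self.barcodes[index],
            self.gene_ids,
            self.gene_symbols,
        )


def _ensure_integer_data(matrix: sp.spmatrix) -> np.ndarray:
    """Validate that stored values are integral; return them as int64.

    Float-stored integral counts (e.g. 3.0) are accepted and cast;
    genuine fractions are rejected with the offending coordinate.
    """
    data = matrix.data
    if np.issubdtype(data.dtype, np.integer):
        return data.astype(np.int64)
    rounded = np.rint(data)
    bad = np.nonzero(np.abs(data - rounded) > 1e-6)[0]
    if bad.size:
        coo = matrix.tocoo()
        i = bad[0]
        raise FormatError(
            f"non-integer count {coo.data[i]!r} at (barcode {coo.row[i]}, gene {coo.col[i]})"
        )
    return rounded.astype(np.int64)


# ---------------------------------------------------------------------------
# Matrix Market
# ---------------------------------------------------------------------------


def _find_file(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            candidate = directory / f"{stem}{suffix}"
            if candidate.exists():
                return candidate
    raise FormatError(f"none of {list(stems)} found in {directory}")


def _read_tsv_column(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        return pd.read_csv(handle, sep="\t", header=None, dtype=str)


def read_mtx(
    source: str | Path | tuple,
    orientation: str = "auto",
) -> CountMatrix:
    """Read a Matrix Market triplet + annotation TSVs into a CountMatrix.

    ``source`` is either a directory containing ``matrix.mtx[.gz]``,
    ``barcodes.tsv[.gz]`` and ``features.tsv[.gz]`` (or ``genes.tsv``),
    or an explicit ``(matrix, barcodes, features)`` path triple.  The
    on-disk orientation (barcodes or genes as rows) is detected from the
    annotation lengths; a square matrix with equally long annotations is
    ambiguous and requires ``orientation`` = ``"barcodes-rows"`` or
    ``"genes-rows"``.
    """
    if isinstance(source, (tuple, list)):
        mtx_path, bc_path, feat_path = (Path(p) for p in source)
    else:
        directory = Path(source)
        if not directory.is_dir():
            raise FormatError(f"{directory} is not a directory; pass explicit paths instead")
        mtx_path = _find_file(directory, ["matrix.mtx"])
        bc_path = _find_file(directory, ["barcodes.tsv"])
        feat_path = _find_file(directory, ["features.tsv", "genes.tsv"])

    matrix = sp.coo_matrix(mmread(str(mtx_path)))
    barcodes = _read_tsv_column(bc_path)[0].to_numpy(dtype=object)
    feats = _read_tsv_column(feat_path)
    gene_ids = feats[0].to_numpy(dtype=object)
    gene_symbols = feats[1].to_numpy(dtype=object) if feats.shape[1] > 1 else None

    n_bc, n_genes = len(barcodes), len(gene_ids)
    matrix = _orient(matrix, n_bc, n_genes, orientation, mtx_path)
    return CountMatrix(matrix.tocsr(), barcodes, gene_ids, gene_symbols)


def _orient(
    matrix: sp.spmatrix, n_bc: int, n_genes: int, orientation: str, origin
) -> sp.spmatrix:
    shape = matrix.shape
    if shape == (n_bc, n_genes) and shape == (n_genes, n_bc):
        # square with equal annotation lengths: genuinely ambiguous
        if orientation == "barcodes-rows":
            return matrix
        if orientation == "genes-rows":
            return matrix.T
        raise FormatError(
            f"{origin}: square matrix with {n_bc} barcodes and {n_genes} genes is "
            "ambiguous; pass orientation='barcodes-rows' or 'genes-rows'"
        )
    if shape == (n_bc, n_genes):
        return matrix
    if shape == (n_genes, n_bc):
        return matrix.T
    raise FormatError(
        f"{origin}: matrix shape {shape} matches neither "
        f"(barcodes={n_bc}, genes={n_genes}) nor its transpose"
    )


def write_mtx(
    counts: CountMatrix,
    directory: str | Path,
    genes_as_rows: bool = True,
) -> Path:
    """Write a CountMatrix as matrix.mtx + barcodes.tsv + features.tsv.

    ``genes_as_rows=True`` produces the CellRanger-style genes x barcodes
    layout; the reader re-orients either way.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = counts.values.T.tocoo() if genes_as_rows else counts.values.tocoo()
    mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    pd.Series(counts.barcodes).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    feats = pd.DataFrame({"id": counts.gene_ids, "symbol": counts.symbols()})
    feats.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    return directory


def write_dataset(dataset, directory: str | Path, genes_as_rows: bool = True) -> Path:
    """Write a simulated dataset: MTX triplet + truth-table TSV."""
    directory = write_mtx(dataset.counts, directory, genes_as_rows=genes_as_rows)
    dataset.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    return directory


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

_H5_LAYOUT_HINT = (
    "expected either an .h5ad file or a 10x-style HDF5 group holding datasets "
    "'data', 'indices', 'indptr', 'shape', 'barcodes' and 'features/id' "
    "(or 'genes'/'gene_names')"
)


def read_h5_counts(path: str | Path) -> CountMatrix:
    """Read counts from an HDF5 container (10x-style raw matrix or h5ad)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as handle:
        if "X" in handle and "obs" in handle:
            return _read_h5ad(path)
        group = _locate_matrix_group(handle)
        data = group["data"][:]
        indices = group["indices"][:]
        indptr = group["indptr"][:]
        shape = tuple(int(v) for v in group["shape"][:])
        barcodes = _decode(group["barcodes"][:])
        if "features" in group:
            gene_ids = _decode(group["features"]["id"][:])
            gene_symbols = (
                _decode(group["features"]["name"][:]) if "name" in group["features"] else None
            )
        elif "genes" in group:
            gene_ids = _decode(group["genes"][:])
            gene_symbols = _decode(group["gene_names"][:]) if "gene_names" in group else None
        else:
            raise FormatError(f"{path}: no feature annotations; {_H5_LAYOUT_HINT}")
    # 10x stores genes x barcodes in CSC over barcode columns; reconstruct
    # and let annotation lengths decide the final orientation.
    matrix = sp.csc_matrix((data, indices, indptr), shape=shape)
    matrix = _orient(matrix.tocoo(), len(barcodes), len(gene_ids), "auto", path)
    return CountMatrix(matrix.tocsr(), barcodes, gene_ids, gene_symbols)


def _locate_matrix_group(handle):
    import h5py

    def is_matrix_group(group) -> bool:
        return all(key in group for key in ("data", "indices", "indptr", "shape"))

    if is_matrix_group(handle):
        return handle
    for key in handle:
        node = handle[key]
        if isinstance(node, h5py.Group) and is_matrix_group(node):
            return node
    raise FormatError(f"{handle.filename}: {_H5_LAYOUT_HINT}")


def _read_h5ad(path: Path) -> CountMatrix:
    import anndata as ad

    adata = ad.read_h5ad(path)
    matrix = sp.csr_matrix(adata.X)
    symbols = None
    for key in ("gene_symbols", "symbol", "name"):
        if key in adata.var.columns:
            symbols = adata.var[key].to_numpy(dtype=object)
            break
    return CountMatrix(
        matrix,
        adata.obs_names.to_numpy(dtype=object),
        adata.var_names.to_numpy(dtype=object),
        symbols,
    )


def _decode(values: np.ndarray) -> np.ndarray:
    return np.array(
        [v.decode() if isinstance(v, bytes) else str(v) for v in values], dtype=object
    )


def write_h5_counts(counts: CountMatrix, path: str | Path) -> Path:
    """Write a CountMatrix in the 10x-style HDF5 raw-matrix layout."""
    import h5py

    path = Path(path)
    csc = counts.values.T.tocsc()  # genes x barcodes, CSC over barcodes
    with h5py.File(path, "w") as handle:
        group = handle.create_group("matrix")
        group.create_dataset("data", data=csc.data.astype(np.int64))
        group.create_dataset("indices", data=csc.indices.astype(np.int64))
        group.create_dataset("indptr", data=csc.indptr.astype(np.int64))
        group.create_dataset("shape", data=np.array(csc.shape, dtype=np.int64))
        group.create_dataset(
            "barcodes", data=np.array([str(b).encode() for b in counts.barcodes])
        )
        feats = group.create_group("features")
        feats.create_dataset("id", data=np.array([str(g).encode() for g in counts.gene_ids]))
        feats.create_dataset("name", data=np.array([str(g).encode() for g in counts.symbols()]))
    return path


# ---------------------------------------------------------------------------
# Metric reports
# ---------------------------------------------------------------------------


def report_frame(metric_sets: Iterable) -> pd.DataFrame:
    """Metric sets as a DataFrame in the canonical column order."""
    rows = []
    for ms in metric_sets:
        record = ms.to_dict()
        rows.append({"sample_id": record.get("sample_id")} | {
            col: record.get(col) for col in REPORT_COLUMNS
        })
    return pd.DataFrame(rows, columns=["sample_id"] + REPORT_COLUMNS)


def write_report(metric_sets: Sequence, path: str | Path, format: str = "csv") -> Path:
    """Write one row/record per dataset, full float precision."""
    if not metric_sets:
        raise ValueError("at least one MetricSet is required")
    path = Path(path)
    frame = report_frame(metric_sets)
    if format == "csv":
        frame.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        records = frame.to_dict(orient="records")
        with open(path, "w") as handle:
            json.dump(records, handle, indent=1)
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'csv' or 'json')")
    return path
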