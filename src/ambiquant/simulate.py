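"""Synthetic unfiltered droplet datasets with controllable ambient contamination.

The generator emulates the calibration substrate for the contamination
metrics: a dataset is a set of droplets, each either containing a cell or
empty.  Cell droplets draw a biological UMI total centred on
``biological_umi_center`` and spread it multinomially over their
cluster's expression profile; *every* droplet additionally receives an
ambient UMI total drawn from a lognormal whose arithmetic mean is the
dataset's ambient level, spread over the ambient profile (the
expression-weighted average of all simulated cell profiles).  Dataset
sizes are optionally randomized around their centres (2000 cells, 12000
droplets, 5000 biological UMIs per cell by default).

Ambient levels between 5 and 4900 span noise-to-signal ratios of roughly
0.001 (pristine) to 0.98 (all noise) against the 5000-UMI biological
centre.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ParameterError
from .io import CountMatrix

__all__ = [
    "SimulationParams",
    "SimulatedDataset",
    "simulate_dataset",
    "sweep_ambient_levels",
    "sweep_params",
    "derive_seed",
    "downsample_counts",
]

#: log-scale standard deviation of the per-droplet ambient lognormal
AMBIENT_LOG_SIGMA = 0.5
#: coefficient of variation used when randomizing dataset sizes
SIZE_CV = 0.10
#: fraction of the marker-gene pool assigned to each cluster profile
_MARKERS_PER_CLUSTER_FRAC = 0.05
#: shared housekeeping component: mixture weight and Dirichlet concentration
_HOUSEKEEPING_WEIGHT = 0.5
_HOUSEKEEPING_ALPHA = 0.05


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated droplet dataset.

    ``randomize`` controls whether the dataset sizes (cell number,
    droplet number, biological UMI centre) are themselves drawn around
    their centres (truncated normal, 10% CV) or held fixed; per-cell
    biological totals always vary around the (possibly drawn) centre.
    """

    n_cells_center: int = 2000
    n_droplets_center: int = 12000
    biological_umi_center: int = 5000
    ambient_umi_level: float = 100.0
    n_clusters: int = 5
    n_genes: int = 2000
    randomize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cells_center",
            "n_droplets_center",
            "biological_umi_center",
            "n_clusters",
            "n_genes",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.n_cells_center >= self.n_droplets_center:
            raise ParameterError("n_cells_center must be smaller than n_droplets_center")
        if self.ambient_umi_level < 0:
            raise ParameterError("ambient_umi_level must be non-negative")

    def replace(self, **changes) -> "SimulationParams":
        return dataclasses.replace(self, **changes)


@dataclass
class SimulatedDataset:
    """A simulated dataset: counts plus per-droplet ground truth.

    ``truth`` has one row per droplet (aligned with ``counts.barcodes``)
    with columns ``barcode``, ``is_cell``, ``cluster`` (-1 for empties),
    ``biological_umi`` and ``ambient_umi``.
    """

    counts: CountMatrix
    truth: pd.DataFrame
    params: SimulationParams

    @property
    def realized_ambient_umi(self) -> np.ndarray:
        return self.truth["ambient_umi"].to_numpy()

    def noise_to_signal(self) -> float:
        """Mean ambient/biological UMI ratio over cell droplets."""
        cells = self.truth[self.truth["is_cell"]]
        return float((cells["ambient_umi"] / cells["biological_umi"]).mean())


def _truncated_normal_int(rng: np.random.Generator, center: float, size=None) -> np.ndarray:
    draw = rng.normal(center, SIZE_CV * center, size=size)
    return np.maximum(np.rint(draw), 1).astype(np.int64)


def _sample_gene_counts(
    rng: np.random.Generator, totals: np.ndarray, profile: np.ndarray
) -> np.ndarray:
    """Exact multinomial gene counts for many droplets sharing a profile.

    Dense (n_droplets x n_genes) int64 output.  Two exact samplers with
    identical marginal law: inverse-CDF per UMI when the total pool is
    small, otherwise numpy's multinomial chain run on the profile sorted
    descending (early exit once every UMI is placed).
    """
    n = len(totals)
    n_genes = len(profile)
    pool = int(totals.sum())
    if pool == 0:
        return np.zeros((n, n_genes), dtype=np.int64)
    if pool * 8 < n * n_genes:
        cdf = np.cumsum(profile)
        cdf[-1] = 1.0
        genes = np.searchsorted(cdf, rng.random(pool))
        rows = np.repeat(np.arange(n, dtype=np.int64), totals)
        flat = np.bincount(rows * n_genes + genes, minlength=n * n_genes)
        return flat.reshape(n, n_genes)
    order = np.argsort(profile)[::-1]
    counts_sorted = rng.multinomial(totals, profile[order])
    out = np.empty_like(counts_sorted)
    out[:, order] = counts_sorted
    return out


def _dense_to_csr(dense: np.ndarray) -> sp.csr_matrix:
    n, n_genes = dense.shape
    flat = dense.ravel()
    idx = np.flatnonzero(flat)
    vals = flat[idx].astype(np.int32)
    cols = (idx % n_genes).astype(np.int32)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.count_nonzero(dense, axis=1), out=indptr[1:])
    return sp.csr_matrix((vals, cols, indptr), shape=(n, n_genes))


def simulate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Generate one dataset; deterministic given ``params`` (incl. seed).

    The RNG stream is consumed in a fixed order (sizes, cluster
    profiles, cluster assignment, biological totals, biological gene
    draws, ambient lognormal factors, ambient gene draws, droplet
    shuffle) and the ambient level enters only as a multiplicative scale
    on pre-drawn lognormal factors, so two simulations sharing a seed
    but differing in ``ambient_umi_level`` share identical biology.
    """
    rng = np.random.default_rng(params.seed)

    # dataset sizes ------------------------------------------------------
    if params.randomize:
        n_cells = int(_truncated_normal_int(rng, params.n_cells_center))
        n_droplets = int(_truncated_normal_int(rng, params.n_droplets_center))
        umi_center = float(_truncated_normal_int(rng, params.biological_umi_center))
        n_droplets = max(n_droplets, n_cells + 1)
    else:
        n_cells = params.n_cells_center
        n_droplets = params.n_droplets_center
        umi_center = float(params.biological_umi_center)

    n_genes, n_clusters = params.n_genes, params.n_clusters

    # cluster expression profiles: a shared heavy-tailed housekeeping
    # component (as in real transcriptomes, where a small set of genes is
    # highly expressed in every cell type) mixed with a cluster-specific
    # Dirichlet carrying a distinct sparse high-expression marker block
    housekeeping = rng.dirichlet(np.full(n_genes, _HOUSEKEEPING_ALPHA))
    marker_pool = rng.permutation(n_genes)
    markers_per = max(1, int(n_genes * _MARKERS_PER_CLUSTER_FRAC))
    profiles = np.empty((n_clusters, n_genes))
    for k in range(n_clusters):
        alpha = np.full(n_genes, 0.3)
        block = marker_pool[(k * markers_per + np.arange(markers_per)) % n_genes]
        alpha[block] = 30.0
        profiles[k] = (
            _HOUSEKEEPING_WEIGHT * housekeeping
            + (1.0 - _HOUSEKEEPING_WEIGHT) * rng.dirichlet(alpha)
        )

    # biological counts --------------------------------------------------
    clusters = rng.integers(n_clusters, size=n_cells)
    bio_totals = _truncated_normal_int(rng, umi_center, size=n_cells)
    dense = np.zeros((n_droplets, n_genes), dtype=np.int64)
    for k in range(n_clusters):
        members = np.nonzero(clusters == k)[0]
        if members.size:
            dense[members] += _sample_gene_counts(rng, bio_totals[members], profiles[k])

    # ambient counts -----------------------------------------------------
    # expression-weighted average of the simulated cell profiles
    weights = np.bincount(clusters, weights=bio_totals.astype(float), minlength=n_clusters)
    if weights.sum() == 0:
        weights = np.ones(n_clusters)
    ambient_profile = (weights / weights.sum()) @ profiles

    # the droplet shuffle and the lognormal factors are drawn *before*
    # the ambient gene draws (whose RNG consumption depends on the
    # ambient level), keeping biology and droplet order shared across
    # levels under a common seed
    order = rng.permutation(n_droplets)
    lognorm_factor = np.exp(
        AMBIENT_LOG_SIGMA * rng.standard_normal(n_droplets) - AMBIENT_LOG_SIGMA**2 / 2
    )
    ambient_totals = np.rint(params.ambient_umi_level * lognorm_factor).astype(np.int64)
    dense += _sample_gene_counts(rng, ambient_totals, ambient_profile)

    # assemble -----------------------------------------------------------
    dense = dense[order]
    is_cell = np.zeros(n_droplets, dtype=bool)
    is_cell[:n_cells] = True
    cluster_col = np.full(n_droplets, -1, dtype=np.int64)
    cluster_col[:n_cells] = clusters
    bio_col = np.zeros(n_droplets, dtype=np.int64)
    bio_col[:n_cells] = bio_totals

    barcodes = np.array([f"BC{i:06d}" for i in range(n_droplets)], dtype=object)
    gene_ids = np.array([f"GENE{j:05d}" for j in range(n_genes)], dtype=object)
    counts = CountMatrix(_dense_to_csr(dense), barcodes, gene_ids)
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "is_cell": is_cell[order],
            "cluster": cluster_col[order],
            "biological_umi": bio_col[order],
            "ambient_umi": ambient_totals[order],
        }
    )
    return SimulatedDataset(counts=counts, truth=truth, params=params)


def derive_seed(base_seed: int, level_index: int, replicate_index: int) -> int:
    """Stable per-dataset seed fan-out for sweeps (always < 2**31)."""
    seq = np.random.SeedSequence([int(base_seed), int(level_index), int(replicate_index)])
    return int(seq.generate_state(1)[0] % (2**31))


def sweep_params(
    base_params: SimulationParams, levels, replicates: int
) -> list[SimulationParams]:
    """Parameter grid for a sweep: one entry per (level, replicate)."""
    levels = list(levels)
    if not levels:
        raise ParameterError("levels must be non-empty")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    grid = []
    for li, level in enumerate(levels):
        for rep in range(replicates):
            grid.append(
                base_params.replace(
                    ambient_umi_level=float(level),
                    seed=derive_seed(base_params.seed, li, rep),
                )
            )
    return grid


def sweep_ambient_levels(
    base_params: SimulationParams, levels, replicates: int
) -> list[SimulatedDataset]:
    """Simulate one dataset per (ambient level, replicate).

    Materializes every dataset; for large sweeps prefer iterating over
    :func:`sweep_params` and simulating/discarding one at a time.
    """
    return [simulate_dataset(p) for p in sweep_params(base_params, levels, replicates)]


def downsample_counts(
    counts: CountMatrix,
    fraction: float,
    seed: int,
    replace: bool = False,
) -> CountMatrix:
    """Randomly downsample total UMIs to a fraction of the original.

    Default is sampling without replacement: exactly
    ``round(fraction * total)`` UMIs are retained (so ``fraction=1`` is
    the identity).  ``replace=True`` resamples UMIs with replacement
    (multinomial over the observed counts) instead.
    """
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    data = counts.values.data.astype(np.int64)
    total = int(data.sum())
    target = int(round(fraction * total))
    if not replace and target == total:
        new_data = data
    elif replace:
        new_data = rng.multinomial(target, data / total)
    else:
        new_data = rng.multivariate_hypergeometric(data, target, method="marginals")
    csr = counts.values.copy()
    csr.data = np.asarray(new_data, dtype=np.int64)
    csr.eliminate_zeros()
    return CountMatrix(csr, counts.barcodes, counts.gene_ids, counts.gene_symbols)
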