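"""Simulator contracts: conservation, determinism, sweeps, downsampling."""

import warnings

import numpy as np
import pytest

from ambiquant import (
    ParameterError,
    SimulationParams,
    compute_metrics,
    derive_seed,
    downsample_counts,
    simulate_dataset,
    sweep_ambient_levels,
    sweep_params,
)


class TestParams:
    def test_rejects_non_positive_counts(self):
        with pytest.raises(ParameterError):
            SimulationParams(n_cells_center=0)
        with pytest.raises(ParameterError):
            SimulationParams(n_genes=-5)

    def test_rejects_cells_not_below_droplets(self):
        with pytest.raises(ParameterError):
            SimulationParams(n_cells_center=500, n_droplets_center=500)

    def test_rejects_negative_ambient(self):
        with pytest.raises(ParameterError):
            SimulationParams(ambient_umi_level=-1.0)


class TestSimulateDataset:
    def test_counts_conserve_truth_totals(self, small_dataset):
        row_totals = small_dataset.counts.barcode_totals()
        truth = small_dataset.truth
        expected = (truth["biological_umi"] + truth["ambient_umi"]).to_numpy()
        assert np.array_equal(row_totals, expected)

    def test_cell_flag_count_matches_params(self, small_dataset):
        truth = small_dataset.truth
        assert truth["is_cell"].sum() == small_dataset.params.n_cells_center
        assert len(truth) == small_dataset.params.n_droplets_center
        assert (truth.loc[truth["is_cell"], "cluster"] >= 0).all()
        assert (truth.loc[~truth["is_cell"], "cluster"] == -1).all()

    def test_zero_ambient_empties_have_no_counts(self, zero_ambient_dataset):
        truth = zero_ambient_dataset.truth
        totals = zero_ambient_dataset.counts.barcode_totals()
        assert (totals[~truth["is_cell"].to_numpy()] == 0).all()
        cells = truth["is_cell"].to_numpy()
        assert np.array_equal(totals[cells], truth.loc[cells, "biological_umi"].to_numpy())

    def test_deterministic_given_seed(self, small_params):
        a = simulate_dataset(small_params)
        b = simulate_dataset(small_params)
        assert (a.counts.values != b.counts.values).nnz == 0
        assert a.truth.equals(b.truth)

    def test_noise_to_signal_tracks_ambient_over_biological(self, small_params):
        ds = simulate_dataset(small_params.replace(ambient_umi_level=6.0))
        # ambient mean 6 against ~600 biological UMIs per cell
        assert ds.noise_to_signal() == pytest.approx(0.01, rel=0.25)

    def test_shared_seed_shares_biology_across_ambient_levels(self, small_params):
        low = simulate_dataset(small_params.replace(ambient_umi_level=10.0))
        high = simulate_dataset(small_params.replace(ambient_umi_level=400.0))
        assert np.array_equal(
            low.truth["biological_umi"].to_numpy(), high.truth["biological_umi"].to_numpy()
        )
        assert (low.truth["ambient_umi"] <= high.truth["ambient_umi"]).all()


class TestSweep:
    def test_cardinality_and_distinct_seeds(self, small_params):
        grid = sweep_params(small_params, [10.0, 100.0], 3)
        assert len(grid) == 6
        assert len({p.seed for p in grid}) == 6
        assert all(p.seed < 2**31 for p in grid)

    def test_empty_levels_rejected(self, small_params):
        with pytest.raises(ParameterError):
            sweep_params(small_params, [], 3)
        with pytest.raises(ParameterError):
            sweep_params(small_params, [10.0], 0)

    def test_seed_fanout_is_stable(self):
        assert derive_seed(0, 1, 2) == derive_seed(0, 1, 2)
        assert derive_seed(0, 1, 2) != derive_seed(0, 2, 1)

    def test_identical_base_seed_gives_identical_matrices(self, small_params):
        a = sweep_ambient_levels(small_params, [25.0], 2)
        b = sweep_ambient_levels(small_params, [25.0], 2)
        for da, db in zip(a, b):
            assert (da.counts.values != db.counts.values).nnz == 0

    def test_empty_slope_sum_mean_increases_with_ambient_level(self, small_params):
        means = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for level in (100.0, 400.0):
                sums = [
                    compute_metrics(ds.counts, model=None).empty_droplet_slope_sum
                    for ds in sweep_ambient_levels(small_params, [level], 20)
                ]
                means[level] = np.mean(sums)
        assert means[400.0] > means[100.0]


class TestDownsample:
    def test_fraction_one_is_identity(self, small_dataset):
        out = downsample_counts(small_dataset.counts, 1.0, seed=0)
        assert (out.values != small_dataset.counts.values).nnz == 0

    def test_fraction_half_halves_total_exactly(self, small_dataset):
        total = small_dataset.counts.total()
        out = downsample_counts(small_dataset.counts, 0.5, seed=0)
        assert out.total() == round(0.5 * total)

    def test_entries_bounded_by_input_without_replacement(self, small_dataset):
        out = downsample_counts(small_dataset.counts, 0.3, seed=1)
        diff = small_dataset.counts.values - out.values
        assert diff.min() >= 0

    def test_deterministic_given_seed(self, small_dataset):
        a = downsample_counts(small_dataset.counts, 0.4, seed=5)
        b = downsample_counts(small_dataset.counts, 0.4, seed=5)
        assert (a.values != b.values).nnz == 0

    def test_with_replacement_hits_target_total(self, small_dataset):
        total = small_dataset.counts.total()
        out = downsample_counts(small_dataset.counts, 0.5, seed=2, replace=True)
        assert out.total() == round(0.5 * total)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, small_dataset, fraction):
        with pytest.raises(ParameterError):
            downsample_counts(small_dataset.counts, fraction, seed=0)
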