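"""Slope distribution, median+sd threshold, empty-droplet scaled slope sum."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from ambiquant import (
    RankedCurve,
    empty_droplet_slope_sum,
    gaussian_threshold_coverage,
    scaled_slope_distribution,
    slope_series,
)


def curve_from_totals(totals):
    return RankedCurve.from_totals(np.asarray(sorted(totals, reverse=True)), 1)


class TestSlopeSeries:
    def test_slopes_are_normalized_totals(self):
        slopes = slope_series(curve_from_totals([97, 1, 1, 1]))
        assert np.allclose(slopes, [0.97, 0.01, 0.01, 0.01])

    def test_uniform_totals_give_constant_slopes(self):
        slopes = slope_series(curve_from_totals([4] * 10))
        assert np.allclose(slopes, 0.1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=10**5), min_size=3, max_size=200))
    def test_slopes_telescope_to_one(self, values):
        values = sorted(values, reverse=True)
        if values[0] == 0:
            values[0] = 1
        slopes = slope_series(curve_from_totals(values))
        assert (slopes >= 0).all()
        assert slopes.sum() == pytest.approx(1.0)


class TestScaledSlopeDistribution:
    def test_threshold_is_median_plus_population_sd(self):
        # hand oracle: median(1,1,1,5)=1, population sd = sqrt(3) = 1.7320508
        dist = scaled_slope_distribution(np.array([1.0, 1.0, 1.0, 5.0]))
        assert dist.threshold == pytest.approx(1.0 + np.sqrt(3.0))

    def test_scaled_mass_normalized_to_one(self):
        rng = np.random.default_rng(0)
        dist = scaled_slope_distribution(rng.lognormal(size=500))
        assert dist.y.sum() == pytest.approx(1.0)
        assert dist.n_bins == 100
        assert dist.frequencies.sum() == 500

    def test_bimodal_slopes_threshold_separates_modes(self):
        # emulates a clean dataset: heavy low-slope (empty) mode plus a
        # lighter high-slope (cell) mode
        rng = np.random.default_rng(1)
        empties = rng.normal(1e-5, 1e-6, size=4000)
        cells = rng.normal(4e-4, 2e-5, size=2000)
        slopes = np.concatenate([empties, cells])
        dist = scaled_slope_distribution(slopes)
        assert empties.max() < dist.threshold < cells.min()
        # two separated histogram modes with an empty gap between them
        occupied = dist.frequencies > 0
        gap = (~occupied)[np.argmax(occupied) : len(occupied) - np.argmax(occupied[::-1])]
        assert gap.sum() > 10

    def test_empty_and_cell_sums_partition_unity(self):
        rng = np.random.default_rng(2)
        dist = scaled_slope_distribution(rng.lognormal(size=300))
        assert dist.empty_sum + dist.cell_sum == pytest.approx(1.0)
        assert 0.0 <= dist.empty_sum <= 1.0

    def test_degenerate_identical_slopes_flagged_with_full_empty_mass(self):
        dist = scaled_slope_distribution(np.full(10, 0.1))
        assert dist.degenerate
        assert empty_droplet_slope_sum(dist) == 1.0

    def test_too_few_slopes_rejected(self):
        with pytest.raises(ValueError):
            scaled_slope_distribution(np.array([0.5, 0.5]))


class TestEmptyDropletSlopeSum:
    def test_zero_ambient_dataset_has_negligible_empty_mass(self, zero_ambient_dataset):
        from ambiquant import compute_metrics

        metrics = compute_metrics(zero_ambient_dataset.counts, expected_cells=150, model=None)
        assert metrics.empty_droplet_slope_sum < 0.05

    def test_low_ambient_below_high_ambient(self, zero_ambient_dataset, high_ambient_dataset):
        from ambiquant import compute_metrics

        low = compute_metrics(zero_ambient_dataset.counts, expected_cells=150, model=None)
        high = compute_metrics(high_ambient_dataset.counts, expected_cells=150, model=None)
        assert low.empty_droplet_slope_sum < high.empty_droplet_slope_sum

    def test_invariant_to_count_scaling(self, small_dataset):
        from ambiquant import CountMatrix, compute_metrics

        counts = small_dataset.counts
        scaled = CountMatrix(counts.values * 9, counts.barcodes, counts.gene_ids)
        a = compute_metrics(counts, expected_cells=150, model=None)
        b = compute_metrics(scaled, expected_cells=150, model=None)
        assert a.empty_droplet_slope_sum == pytest.approx(b.empty_droplet_slope_sum)
        assert a.inverted_auc_pct == pytest.approx(b.inverted_auc_pct)


class TestGaussianThresholdCoverage:
    def test_converges_to_phi_of_one(self):
        # closed-form oracle: Phi(1) = 0.841345
        coverage = gaussian_threshold_coverage(10**6, seed=0)
        assert coverage == pytest.approx(norm.cdf(1.0), abs=1e-3)

    def test_symmetric_two_point_distribution_is_not_gaussian(self):
        # median + sd of {-1, +1} is exactly +1; only half the mass lies
        # strictly below it, illustrating the Gaussian-only rationale
        values = np.array([-1.0, 1.0] * 500)
        threshold = np.median(values) + values.std()
        assert threshold == pytest.approx(1.0)
        assert (values < threshold).mean() == pytest.approx(0.5)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            gaussian_threshold_coverage(100)
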