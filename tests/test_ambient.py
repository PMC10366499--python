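"""Ambient-gene dropout rule, percent counts ambient, standard QC."""

import numpy as np
import pytest

from ambiquant import (
    QCWarning,
    ambient_gene_set,
    gene_dropout,
    percent_counts_ambient,
    standard_qc,
)

from conftest import make_counts


class TestGeneDropout:
    def test_trivial_rates(self):
        # gene 0 in all barcodes, gene 1 in none, gene 2 in 9 of 10
        dense = np.zeros((10, 3), dtype=int)
        dense[:, 0] = 1
        dense[:9, 2] = 2
        dropout = gene_dropout(make_counts(dense))
        assert np.allclose(dropout, [0.0, 1.0, 0.1])


class TestAmbientGeneSet:
    def test_strict_threshold_boundary(self):
        dropout = np.array([0.00, 0.01, 0.02, 0.50])
        ambient = ambient_gene_set(dropout, ["a", "b", "c", "d"], threshold=0.02)
        assert ambient.n_ambient == 2
        assert list(ambient.ambient_ids) == ["a", "b"]

    def test_zero_ambient_simulation_yields_no_ambient_genes(self, zero_ambient_dataset):
        from ambiquant import truncate_and_normalize

        _, truncated = truncate_and_normalize(zero_ambient_dataset.counts, 150)
        ambient = ambient_gene_set(gene_dropout(truncated), truncated.gene_ids)
        assert ambient.n_ambient == 0

    def test_ambient_gene_count_rises_with_ambient_level(
        self, zero_ambient_dataset, high_ambient_dataset
    ):
        from ambiquant import truncate_and_normalize

        counts = {}
        for name, ds in [("low", zero_ambient_dataset), ("high", high_ambient_dataset)]:
            _, truncated = truncate_and_normalize(ds.counts, 150)
            counts[name] = ambient_gene_set(gene_dropout(truncated), truncated.gene_ids).n_ambient
        assert counts["high"] > counts["low"]


class TestPercentCountsAmbient:
    def test_no_ambient_genes_gives_zero(self):
        counts = make_counts(np.array([[10, 5], [3, 2], [1, 0]]))
        ambient = ambient_gene_set(np.array([0.9, 0.9]), counts.gene_ids)
        pct, avg, avg_umi = percent_counts_ambient(counts, ambient, 2)
        assert np.allclose(pct, 0.0) and avg == 0.0 and avg_umi == 0.0

    def test_all_genes_ambient_gives_hundred(self):
        counts = make_counts(np.array([[10, 5], [3, 2], [1, 0]]))
        ambient = ambient_gene_set(np.array([0.0, 0.0]), counts.gene_ids)
        pct, avg, _ = percent_counts_ambient(counts, ambient, 2)
        assert np.allclose(pct, 100.0) and avg == 100.0

    def test_single_cell_arithmetic(self):
        # 50 total UMIs of which 5 fall in the one ambient gene -> 10%
        counts = make_counts(np.array([[45, 5]]))
        ambient = ambient_gene_set(np.array([0.9, 0.0]), counts.gene_ids)
        pct, avg, avg_umi = percent_counts_ambient(counts, ambient, 1)
        assert avg == pytest.approx(10.0)
        assert avg_umi == pytest.approx(5.0)

    def test_zero_total_cell_warns_and_scores_zero(self):
        counts = make_counts(np.array([[10, 5], [0, 0]]))
        ambient = ambient_gene_set(np.array([0.0, 0.9]), counts.gene_ids)
        with pytest.warns(QCWarning):
            pct, _, _ = percent_counts_ambient(counts, ambient, 2)
        assert pct[1] == 0.0

    def test_matches_scanpy_qc_metrics(self, high_ambient_dataset):
        # independent route: scanpy's calculate_qc_metrics with an
        # 'ambient' gene flag, exactly as real pipelines compute it
        import anndata as ad
        import scanpy as sc

        from ambiquant import truncate_and_normalize

        _, truncated = truncate_and_normalize(high_ambient_dataset.counts, 150)
        ambient = ambient_gene_set(gene_dropout(truncated), truncated.gene_ids)
        assert ambient.n_ambient > 0

        adata = ad.AnnData(X=truncated.values[:150].astype(np.float32))
        adata.var["ambient"] = ambient.mask
        sc.pp.calculate_qc_metrics(
            adata, qc_vars=["ambient"], percent_top=None, log1p=False, inplace=True
        )
        pct, avg, _ = percent_counts_ambient(truncated, ambient, 150)
        assert np.allclose(pct, adata.obs["pct_counts_ambient"].to_numpy(), atol=1e-4)


class TestStandardQC:
    def test_two_cell_arithmetic(self):
        counts = make_counts(
            np.array([[60, 40, 0], [100, 100, 100]]),
            gene_symbols=["MT-CO1", "ACTB", "GAPDH"],
        )
        n_cells, pct_mito, genes_per_cell, umi_per_cell = standard_qc(counts, 2)
        assert n_cells == 2
        assert umi_per_cell == pytest.approx(200.0)  # (100 + 300) / 2
        assert genes_per_cell == pytest.approx(2.5)
        assert pct_mito == pytest.approx((60.0 + 100.0 / 3.0) / 2.0)

    def test_no_mitochondrial_genes_warns_and_zeroes(self):
        counts = make_counts(np.array([[3, 1], [2, 2]]))
        with pytest.warns(QCWarning):
            _, pct_mito, _, _ = standard_qc(counts, 2)
        assert pct_mito == 0.0

    def test_simulated_umi_per_cell_near_truth(self, small_dataset):
        from ambiquant import truncate_and_normalize
        import warnings

        _, truncated = truncate_and_normalize(small_dataset.counts, 150)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", QCWarning)
            _, _, _, umi_per_cell = standard_qc(truncated, 150)
        expected = 600 + 30  # biological center + mean ambient level
        assert umi_per_cell == pytest.approx(expected, rel=0.05)
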