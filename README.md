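# ambiquant

Contamination-focused quality metrics for **unfiltered** droplet
scRNA-seq count matrices.

In droplet single-cell RNA-seq, ambient RNA — cell-free transcripts from
dead and dying cells — is co-encapsulated into every droplet. Empty
droplets end up with counts and real cells with a contaminating
admixture, and the damage varies enormously between dissociation
protocols, fixation chemistries and tissues. `ambiquant` scores a raw
barcode × gene UMI matrix on a continuous contamination scale *before*
any barcode filtering, so that datasets and whole cohorts can be
compared, triaged or flagged early. It is aimed at anyone generating or
re-analyzing droplet data: core facilities tuning protocols,
computational groups screening public datasets, QC steps in pipelines.

## The method in brief

Barcodes are ranked by total UMI count; the dataset is truncated to
4× the estimated real-cell number (knee of the cumulative-count curve,
or user-supplied) and the cumulative curve is normalized to (0, 1]².
Let `c_i` be the normalized cumulative count at normalized rank `x_i`,
and `d_i = c_i − x_i` the vertical secant distance to the diagonal.
Six metrics, each increasing with contamination:

| metric | definition | range |
|---|---|---|
| empty-droplet scaled slope sum | mass of the midpoint-scaled 100-bin slope histogram at/below `median(slopes) + sd(slopes)` | [0, 1] |
| inverted max. secant distance | `1 − max_i d_i` | [0, 1] |
| inverted secant-line st. dev. | `0.5 − sd(d)` (population sd) | (0, 0.5] |
| inverted AUC percentage | `2 × (1 − AUC)` of the normalized curve | [0, 1] |
| number of ambient genes | genes with dropout rate < 2% across retained barcodes | ≥ 0 |
| avg. percent counts ambient | mean % of a cell's UMIs in ambient genes | [0, 100] |

A clean dataset's curve bows far above the diagonal (steep cell region,
flat empty region); contamination flattens the increments and pulls the
curve toward the diagonal, driving every metric up. An **overall score**
in [0, 1] (0 = perfect signal-to-noise, 1 = all noise) combines five
bounded features with PCA-derived weights calibrated on simulated
sweeps; four standard QC summaries (cells, UMIs/cell, genes/cell,
% mitochondrial) round out the report. A droplet simulator with
controllable ambient level (the calibration/validation substrate) and a
depth downsampler are included. See `docs/methods.md` for the full
model and its assumptions.

## Worked example

```python
from ambiquant import SimulationParams, simulate_dataset, compute_metrics

base = SimulationParams(n_cells_center=500, n_droplets_center=3000,
                        biological_umi_center=2000, n_genes=1000,
                        randomize=False, seed=7)
for label, level in [("clean", 30.0), ("contaminated", 1500.0)]:
    ds = simulate_dataset(base.replace(ambient_umi_level=level))
    m = compute_metrics(ds.counts, sample_id=label)
    print(label, m.empty_droplet_slope_sum, m.inverted_auc_pct,
          m.avg_pct_counts_ambient, m.overall_score)
```

prints (identical biology in both datasets; only the ambient level differs):

```
clean         0.059   0.2834    0.0     0.2498
contaminated  0.583   0.6793   41.29    0.6610
```

The clean dataset (~30 ambient UMIs per droplet, noise-to-signal 0.016)
sits near the low end of every metric: almost no scaled slope mass below
the empty-droplet threshold, a strongly bowed curve, no ambient genes.
At ambient level 1500 (noise-to-signal 0.78) the curve flattens toward
the diagonal (inverted AUC 0.28 → 0.68), 41% of each cell's counts fall
in ambient genes, and the overall score rises from 0.25 to 0.66. The
scripts in `examples/` walk through scoring, depth robustness,
calibration and cohort batch mode, each printing and explaining its
numbers.

Real data enters the same way from disk:

```bash
ambiquant run --input raw_feature_bc_matrix/ --out report.csv
ambiquant cohort --manifest samples.tsv --out cohort.csv
ambiquant simulate --ambient-level 500 --seed 1 --out sim/
ambiquant calibrate --replicates 50 --seed 1 --out model.json
```

accepting Matrix Market triplets (either orientation, optionally
gzipped), 10x-style HDF5, or `.h5ad`.

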