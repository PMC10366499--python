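"""Score a small cohort of datasets from a sample manifest.

Three simulated samples of increasing contamination are written to disk
as Matrix Market triplets, listed in a manifest TSV, and scored in batch
mode.  The cohort table (one row per sample, metadata carried through)
is what feeds cross-cohort quality comparisons.
"""

import tempfile
import warnings
from pathlib import Path

import pandas as pd

from ambiquant import SimulationParams, run_cohort, simulate_dataset, write_dataset

warnings.simplefilter("ignore")

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    rows = []
    for i, level in enumerate([20.0, 300.0, 2000.0]):
        params = SimulationParams(
            n_cells_center=200, n_droplets_center=1200, biological_umi_center=1000,
            ambient_umi_level=level, n_genes=600, seed=10 + i,
        )
        path = tmp / f"sample{i}"
        write_dataset(simulate_dataset(params), path)
        rows.append({"sample_id": f"sample{i}", "path": str(path),
                     "protocol": ["gentle", "standard", "harsh"][i]})
    manifest = tmp / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)

    result = run_cohort(manifest)
    cols = ["sample_id", "protocol", "empty_droplet_slope_sum", "inverted_auc_pct",
            "n_ambient_genes", "avg_pct_counts_ambient", "overall_score"]
    print(result.table[cols].round(4).to_string(index=False))

print("\nMetric values and the overall score rise with the simulated "
      "contamination level of each sample.")
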