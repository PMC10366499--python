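{
 "feature_names": [
  "empty_droplet_slope_sum",
  "inverted_max_secant",
  "inverted_secant_sd_x2",
  "inverted_auc_pct",
  "frac_counts_ambient"
 ],
 "weights": [
  0.19817306638038415,
  0.20024509336679902,
  0.20108694363536597,
  0.20163185674795334,
  0.19886303986949766
 ],
 "pca_explained_variance": [
  0.9484930225500323,
  0.0470123300943516,
  0.003117245207669394,
  0.0013489121596783388,
  2.4964623607594525e-05,
  3.5253646606726105e-06
 ],
 "provenance": {
  "levels": [
   5.0,
   11.0,
   23.0,
   50.0,
   107.0,
   230.0,
   494.0,
   1063.0,
   2286.0,
   4900.0
  ],
  "replicates": 50,
  "seed": 20260925,
  "n_cells_center": 2000,
  "n_droplets_center": 12000,
  "biological_umi_center": 5000,
  "package_version": "0.1.0",
  "n_datasets": 500
 }
}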