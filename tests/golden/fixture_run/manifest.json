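{
 "hashes": {
  "bridges.tsv": "415358b7fe1a79fc489a662fb9eae7fe5e833b68f0f88aa1d615469c4e8d874a",
  "counts.tsv": "7622fef230634711d14f3e843459a2c06fac3713105dc30d8d0a6168b0124fa9",
  "crossspecies.json": "cda28dd6603a01bbeb6f9125ca5acd953b5658d3650fa7c38356f36d5ab263b1",
  "de_d14.tsv": "7375431f2b5029887fb99609cfc2b67b2514e8222ae610985d17f9a648cbd316",
  "de_d21.tsv": "ea5d189502f021b328f9b95bc737a09f4a461c57636435c1ee95b5859296956e",
  "de_d28.tsv": "b8b55771cf627c60bbae48f55b12b195c34742aff6abec6abe11b9dd250314ba",
  "de_d7.tsv": "1d090db8feb738ca8f6bbacb10d9a6f519226d708b624114f51453e829520f57",
  "deg_sets.json": "1e2e14109a0d56f31f9a632b4486fd2b160ff83e235f069834f2b16e5f36db29",
  "design.tsv": "db704fd51eb58c7a7087de04b022f966bc2a0cd230d0c89d26fec728c13e3629",
  "dm_sets.json": "cb8d473722a458e349e5e34fa6f3db60a2abed6d2ad92dec94181a6a663edf07",
  "gcn_edges.tsv": "04af23fef2695b113cea0ac76b330de5536fd2fa793fd318707434b809010bbd",
  "gcn_nodes.tsv": "514f1b5ada720f18f82460b26fa07a308c9e15a97a2ec1459156bf42e5579e2c",
  "mcn_edges.tsv": "7d954c7ca1e7360ab9aeff42f6738ce38b203dc51329152259f0fcc3e890572a",
  "mcn_nodes.tsv": "3dff4ffdd81e971f261601ab0e10174d82c1dccf27759a188807ccd500cb23d8",
  "metabolites_imputed.tsv": "ae1abb302fffbe87e303cf7f44e2981222faf713839ff9ff715bfe14500725b3",
  "metabolites_raw.tsv": "a39702d44606db23ef9c7518f8a01fd60414a954b5a4d6b4e327e9c9f46d64cd",
  "phenotype_centrality.json": "4e2b5e708f7f97801c439d3884e265d5c011aa688d26ca11261a630fcda44beb",
  "phenotypes.tsv": "c06586be8e1016f38e22b4ff7cd9d3e15af2baf5061c4782608be414d90170fa",
  "reversal.tsv": "16d50de0897add027125f342463bc7da9d7fc8fa4fb457997e050fdb4ebef5b2",
  "track_association.tsv": "852c7ca879b729578e7d5ac7845f5f64f3636b757268945b57e75d607e750a16"
 },
 "outputs": [
  "bridges.tsv",
  "counts.tsv",
  "crossspecies.json",
  "de_d14.tsv",
  "de_d21.tsv",
  "de_d28.tsv",
  "de_d7.tsv",
  "deg_sets.json",
  "design.tsv",
  "dm_sets.json",
  "gcn_edges.tsv",
  "gcn_nodes.tsv",
  "mcn_edges.tsv",
  "mcn_nodes.tsv",
  "metabolites_imputed.tsv",
  "metabolites_raw.tsv",
  "phenotype_centrality.json",
  "phenotypes.tsv",
  "reversal.tsv",
  "track_association.tsv"
 ],
 "run_config": {
  "alpha": 0.05,
  "cc_on_full_network": true,
  "fdr": 0.05,
  "knn_k": 3,
  "min_present": 2,
  "min_timepoints": 2,
  "phenotype_fdr_only": true,
  "resolution": 1.0,
  "seed": 1,
  "top_fraction": 0.25,
  "tpm_min": 5.0,
  "weighted_leiden": false
 },
 "seed": 1,
 "sim_config": {
  "baseline_logmean": 4.5,
  "baseline_logmean_sd": 1.0,
  "groups": [
   "control",
   "d7",
   "d14",
   "d21",
   "d28"
  ],
  "library_size_range": [
   0.8,
   1.2
  ],
  "loading_sd": 1.0,
  "metabolite_baseline_sd": 1.0,
  "metabolite_noise_sd": 0.25,
  "missing_prob": 0.7,
  "missing_threshold_quantile": 0.1,
  "module_fraction": 0.8,
  "module_trajectories": [
   [
    0.0,
    -1.2,
    -2.0,
    -1.5,
    -1.0
   ],
   [
    0.0,
    2.2,
    1.8,
    0.8,
    0.3
   ],
   [
    0.0,
    0.6,
    1.8,
    1.5,
    1.4
   ],
   [
    0.0,
    -0.8,
    -0.3,
    1.5,
    1.7
   ],
   [
    0.0,
    1.2,
    -0.2,
    -1.0,
    -1.4
   ]
  ],
  "n_genes": 30,
  "n_metabolites": 12,
  "n_modules": 3,
  "nb_dispersion": 0.05,
  "phenotype_couplings": [
   [
    "stiffness_index",
    2,
    1,
    0.0
   ],
   [
    "FVC",
    0,
    1,
    0.2
   ]
  ],
  "replicates": 3,
  "seed": 1
 },
 "timings_s": {
  "crossspecies": 0.011,
  "differential": 0.018,
  "integrate": 0.026,
  "metabolomics": 0.034,
  "networks": 0.024,
  "reversal": 0.011,
  "simulate": 0.008
 },
 "version": "0.1.0"
}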