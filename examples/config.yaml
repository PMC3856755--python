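# Smoke-scale pipeline configuration for `trophicsdm run-all`.
seed: 3
synthetic:
  n_plants: 10
  n_butterflies: 12
  n_sites: 40
mcmc:
  n_iterations: 2000
  burn_in: 1000
  thinning: 5
sdm:
  techniques: [glm]
  predictors: [abiotic, foodweb]
  folds: 3
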