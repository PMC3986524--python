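{
  "with_covariates": true,
  "n_permutations": 10000,
  "permutations_per_task": 1,
  "score": "r2",
  "cv": {"n_iter": 10, "test_fraction": 0.2, "seed": 0},
  "pipeline": [
    {"name": "filter", "component_ref": "collinearity_filter", "parameters": {}},
    {"name": "kbest", "component_ref": "select_k_best", "parameters": {"k": 1000}},
    {"name": "ridge", "component_ref": "ridge", "parameters": {"alpha": 0.0001}}
  ],
  "grid": {
    "axes": {
      "kbest__k": [100, 500, 1000, 5000, 10000],
      "ridge__alpha": [0.0001, 0.01, 1.0]
    }
  }
}
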