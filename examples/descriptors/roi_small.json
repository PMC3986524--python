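{
  "with_covariates": true,
  "n_permutations": 99,
  "permutations_per_task": 33,
  "score": "r2",
  "cv": {"n_iter": 10, "test_fraction": 0.2, "seed": 0},
  "pipeline": [
    {"name": "kbest", "component_ref": "select_k_best", "parameters": {"k": 50}},
    {"name": "ridge", "component_ref": "ridge", "parameters": {"alpha": 0.0001}}
  ]
}
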