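{
  "n_docs": 50,
  "n_proteins": 4,
  "n_diseases": 2,
  "n_context": 2,
  "n_generic": 3,
  "n_noise": 1,
  "n_true_ppi": 2,
  "n_true_gd": 1,
  "context_per_pair": 2,
  "topic_probabilities": [0.4, 0.4, 0.2],
  "n_affine_ppi": 1,
  "n_affine_gd": 1,
  "affine_start_rank": 1,
  "generic_max_freq": 0.6,
  "seed": 7,
  "analysis": {"n_random": 3, "reference_pairs": 10}
}
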