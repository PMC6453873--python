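{
  "version": "published-1",
  "boundary": "strict",
  "candidate_markers": ["c_peptide", "bmi", "ag15", "hscrp", "fasting_glucose"],
  "terminal_pair": ["HNF1A", "GCK"],
  "steps": [
    {
      "target_group": "T1D",
      "markers": ["c_peptide"],
      "weights": [1.0],
      "direction": "lower_is_positive",
      "threshold": 0.6,
      "auc": {"auc": 0.976, "variance": null, "ci_low": 0.962, "ci_high": 0.989, "n_pos": 99, "n_neg": 257},
      "sensitivity": 0.929,
      "specificity": 0.910
    },
    {
      "target_group": "T2D",
      "markers": ["c_peptide", "bmi"],
      "weights": [1.0, 0.16],
      "direction": "higher_is_positive",
      "threshold": 6.29,
      "auc": {"auc": 0.917, "variance": null, "ci_low": 0.881, "ci_high": 0.952, "n_pos": 92, "n_neg": 165},
      "sensitivity": 0.848,
      "specificity": 0.891
    },
    {
      "target_group": "HNF1A",
      "markers": ["ag15", "hscrp"],
      "weights": [1.0, 1.56],
      "direction": "lower_is_positive",
      "threshold": 10.16,
      "auc": {"auc": 0.863, "variance": null, "ci_low": 0.809, "ci_high": 0.917, "n_pos": 77, "n_neg": 88},
      "sensitivity": 0.831,
      "specificity": 0.727
    }
  ]
}
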