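# Desk-scale pipeline configuration: 80 cases, light search budget.
# Omitted keys keep their defaults; unknown keys are rejected.
seed: 7
out_dir: results/demo
generator:
  n_cases: 80
search:
  n_trials: 5
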