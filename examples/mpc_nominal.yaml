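# Full-horizon (open-loop) D-optimal design on the nominal chemostat model.
pipeline: design_mpc
seed: 1
nlp:
  multistart_count: 6
  max_iterations: 200
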