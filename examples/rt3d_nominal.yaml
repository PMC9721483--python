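# Scaled-down recurrent TD3 training run at the nominal parametrisation.
# The published-scale protocol uses 17500 episodes; 400 suffice to see clear
# learning progress on a workstation.
pipeline: train_rt3d
seed: 3
observation: IIIa
n_episodes: 400
scaling:
  population_divisor: 5.0e+11   # peak population under the nominal yields (~4.8e11 cells/L)
agent:
  batch_size: 128
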