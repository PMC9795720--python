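task: task2
seed: 0
strategy: thompson
schedule:
  rounds: 1
  n_init: 10
  n_iterations: 40
  n_batch: 5
oracle:
  kind: synthetic_activity
  sigma_chemist: 0.0
  seed: 0
  theta_star: null
generator:
  kind: pool_resampler
  library_size: 3000
  library_seed: 0
  temperature: 0.02
  score_threshold: 0.4
  n_eval: 1024
components: null
aggregation: product
sampler:
  nwalkers: 32
  nsteps: 250
  nburn: 250
gp:
  kernel: tanimoto
  sigma0: 0.1
  fp_radius: 3
  fp_nbits: 2048
  candidate_cap: 1000
  optimize_hyperparameters: false
  feedback_scale: unit
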