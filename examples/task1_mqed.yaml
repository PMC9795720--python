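task: task1
seed: 0
strategy: thompson
schedule:
  rounds: 2
  n_init: 10
  n_iterations: 10
  n_batch: 10
oracle:
  kind: mqed
  sigma_chemist: 0.0
  seed: 0
  theta_star: null
generator:
  kind: pool_resampler
  library_size: 1500
  library_seed: 0
  temperature: 0.05
  score_threshold: 0.4
  n_eval: 512
components:
- name: MW
  weight: 0.14285714285714285
  low: 100.0
  high: 600.0
  alpha1: null
  alpha2: null
- name: SlogP
  weight: 0.14285714285714285
  low: -2.0
  high: 6.0
  alpha1: null
  alpha2: null
- name: HBD
  weight: 0.14285714285714285
  low: 0.0
  high: 6.0
  alpha1: null
  alpha2: null
- name: HBA
  weight: 0.14285714285714285
  low: 0.0
  high: 11.0
  alpha1: null
  alpha2: null
- name: PSA
  weight: 0.14285714285714285
  low: 0.0
  high: 160.0
  alpha1: null
  alpha2: null
- name: RotatableBonds
  weight: 0.14285714285714285
  low: 0.0
  high: 11.0
  alpha1: null
  alpha2: null
- name: AromaticRings
  weight: 0.14285714285714285
  low: 0.0
  high: 5.0
  alpha1: null
  alpha2: null
aggregation: product
sampler:
  nwalkers: 32
  nsteps: 120
  nburn: 120
gp:
  kernel: tanimoto
  sigma0: 0.1
  fp_radius: 3
  fp_nbits: 2048
  candidate_cap: 2000
  optimize_hyperparameters: false
  feedback_scale: unit
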