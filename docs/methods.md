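# Methods

This note documents the models, the simulated study conditions, the
numerical choices and the known limitations of `molelicit`.

## The elicitation problem

A goal-directed molecule generator needs a scoring function
S: ℳ → [0, 1] expressing a chemist's (partly tacit) goal. We treat the
chemist as an oracle that can be queried with molecules, and learn S from
few queries — a reward-elicitation problem with an exploration–exploitation
trade-off, since queries should both pin down S and concentrate on
molecules that matter.

## Task 1: Bayesian adaptation of MPO desirability intervals

**Model.** The score is an MPO aggregate of K = 7 physicochemical
components (MW, SlogP, HBD, HBA, TPSA, rotatable bonds, aromatic rings;
Lipinski definitions for HBD/HBA). Each component passes through a
double-sigmoid desirability φ(x; LOW, HIGH, α₁, α₂) — a smooth plateau at 1
on [LOW, HIGH] — and components combine as a weighted geometric mean with
weights summing to 1. Only (LOW_k, HIGH_k) are inferred; steepnesses α and
weights w are fixed. Binary feedback is modelled as
y | x ~ Bernoulli(S_θ(x)): the chemist approves with probability equal to
their tacit score. Actively selected queries are treated as i.i.d. in the
likelihood; this is a deliberate simplification and can bias the posterior
when acquisition is adaptive.

**Priors.** LOW_k ~ N(LOW₀ₖ, σₖ²), HIGH_k ~ N(HIGH₀ₖ, σₖ²) with
σₖ = (HIGH₀ₖ − LOW₀ₖ)/8, so the prior sd scales with how wide the user's
initial guess is. The model is parameterized as (LOW, DELTA) with
HIGH = LOW + DELTA; the change of variables has unit Jacobian, so the prior
density is evaluated directly at LOW and LOW + DELTA, and DELTA > 0 is
enforced as sampler support (a truncation of the induced prior).

**Inference.** Affine-invariant ensemble MCMC (emcee), vectorized over
walkers; default 32 walkers × 250 retained steps after 250 burn-in (8000
draws). Within an elicitation run, each refit warm-starts its walkers from
the previous posterior's draws: the posterior moves only slightly per
10-query batch, and warm starts are what make short per-iteration chains
(120 + 120 steps in the shipped run configs) give converged posterior
means. Bernoulli probabilities are clamped to [1e−9, 1 − 1e−9] so the
log-likelihood stays finite when a sampled θ drives S to 0 or 1. The point
estimate is the posterior mean (minimum-MSE), with HIGH = mean(LOW) +
mean(DELTA) guaranteeing HIGH > LOW. A mean acceptance fraction below 0.05
is flagged as a convergence warning in the returned diagnostics.

**Correctness anchor.** On K = 1 problems the MCMC posterior means are
checked against dense grid quadrature of the same unnormalized density
(tolerance 0.05·σ); the quadrature is independent of the sampler but shares
the density code, so it validates the sampling, not the model definition —
the model definition is itself pinned by direct likelihood/prior unit tests.

**Defaults.** θ₀ intervals are wide drug-like ranges (MW 100–600,
SlogP −2–6, HBD 0–6, HBA 0–11, TPSA 0–160, rotatable bonds 0–11, aromatic
rings 0–5). Fixed steepnesses are set per component so that each sigmoid
edge completes its 5%→95% rise over ~5% of the prior interval width —
sharp enough that the interval is meaningful, smooth enough for gradientless
exploration. Both are config-overridable.

## Task 2: GP chemist's component

**Model.** f ~ GP(0, k) with Gaussian feedback noise σ₀ (default 0.1 on
the [0, 1] feedback scale; the noise-sensitivity experiments corrupt the
oracle with σ ∈ {0, 0.15, 0.30} and cap feedback to [0, 1]). Kernels:
Tanimoto on binary Morgan fingerprints (radius 3, 2048 bits — ECFP6-style;
similarity of two all-zero fingerprints is defined as 1) with an optional
learnable output scale, or squared-exponential on the 7 descriptors.
Posterior mean/variance use a cached Cholesky factorization of
(K + σ₀²I), refreshed on every data change; a single 1e−8 diagonal jitter
retry guards near-singular Gram matrices. Hyperparameter optimization
(marginal-likelihood maximization: scalar bounded search for the output
scale, a log-spaced lengthscale grid for the squared-exponential case) is
off by default in the loops — with ≤ 210 noisy labels on a [0, 1] scale the
unit output scale is adequate and fixed hyperparameters keep runs exactly
reproducible.

**Thompson draws.** One joint posterior sample over the candidate set,
from the factorized posterior covariance (escalating jitter if needed).
When the pool exceeds the candidate cap, a random subsample of the pool is
drawn jointly per batch and the remainder is excluded for that batch only.
A batch shares a single draw (greedy top-n of one ranking); this
"one belief per batch" rule can understate Thompson sampling relative to
per-slot redraws and is kept deliberately, matching the batched protocol.
The exported scoring function clips the GP mean to [0, 1] at the boundary
only; inside the GP, predictions are untransformed.

## Query strategies

Random (uniform without replacement), uncertainty (Task 1: binary entropy
of the Monte-Carlo marginal predictive, not expected conditional entropy;
Task 2: predictive variance — Gaussian entropy is monotone in it),
exploitation (posterior-predictive mean score), Thompson (one belief draw).
All ranking ties break by pool index; entropies are symmetrized and rounded
to 12 decimals so H(p) and H(1−p) tie exactly despite floating point. A
molecule is never queried twice in a run.

## Simulated study conditions

**Schedules.** Task 1: R = 2 rounds, each 10 random initialization queries
plus 10 iterations × batch 10 → 110 feedback records per round, 220 total.
Task 2: N₀ = 10 initial molecules, then 200 queries in batches of 5
(40 iterations). Evaluation checkpoints propose up to 1024 molecules
(reducible; the shipped experiment configs use 256–512) and report their
mean oracle score.

**Oracles.** The Task 1 chemist scores by *modified QED*: the published QED
recipe with mean property weights, except the structural-ALERTS weight is 0
and the logP desirability curve is translated by −1.5 (optimum moves from
~2.8 to ~1.3), making low-logP molecules desirable a priori. Reversing both
deltas reproduces the published QED exactly (regression-guarded). The
Task 2 chemist is a synthetic activity oracle — a logistic transform of a
seeded linear functional of fingerprint bits, normalized by the square root
of the popcount — deterministic, smooth in fingerprint space, and spread
over [0, 1] (sd ≥ 0.15 on a diverse 1000-molecule pool). It replaces a
trained receptor-activity classifier, which would require external assay
data; `external_model_adapter` wraps such a model when available. For
parameter-recovery experiments an MPO oracle with known intervals θ* plays
the chemist, and recovery is scored by MRAE: the mean over all 2K
parameters of |θ̂ − θ*| normalized by the true interval width of the
parameter's component.

**Generator stand-in.** In place of an RL-trained generative agent, a pool
resampler proposes from a fixed synthetic library with probability
∝ exp(score/T), implemented as Gumbel-top-k (exact for these weights,
without replacement); T → 0 recovers top-n. The round-0 baseline
("prior agent") is a uniform library sample, and each round's candidate
pool keeps proposals with score ≥ 0.4 (top-up to the schedule's need if the
filter is too strict). The library is a combinatorial scaffold × substituent
enumeration (~12 heteroaromatic cores, ~50 substituents) spanning MW
~95–520, SlogP −1–7.5, TPSA 0–165. It contains valid, broadly drug-like
molecules but not the scaffold diversity, activity cliffs or
synthesizability profile of a real screening collection — so passing
experiments demonstrate the elicitation machinery under controlled
conditions, not performance on real chemistry.

**Pool size matters.** The original protocol queries ~200 molecules out of
hundreds of thousands; active selection only beats random when the budget
cannot cover the pool. The Task 2 defaults therefore use a 3000-molecule
library against the 210-query budget (the largest ratio that keeps a full
multi-seed experiment in minutes on one CPU) with a Thompson candidate cap
of 1000. Shrinking the pool toward the budget washes out the differences
between strategies.

**Reproducibility.** Every random stream is derived from the run seed via
named seed sequences (`default_rng([seed, stage, iteration])`), emcee
states are seeded explicitly, and CSV-mediated sessions reuse the same
stream derivation — a session driven by oracle-generated labels reproduces
the fully simulated run bit-for-bit, and repeated runs of any config+seed
produce byte-identical metrics files.

## Known limitations

- The i.i.d. likelihood under adaptive querying is biased by construction;
  the bias is accepted, and shows up as occasional non-monotone MRAE
  trajectories at small budgets.
- Only (LOW, HIGH) are inferred; steepnesses, weights and the set of
  components are fixed inputs.
- The GP is exact (dense); runs are O(N³) in labels and candidate-cap size,
  fine at elicitation scale (hundreds), unsuitable for tens of thousands.
- One chemist, one consistent latent score: inter-expert disagreement,
  drift, learning and fatigue are not modelled (feedback noise is the only
  error channel).
- Desk-scale stand-ins (pool resampler, synthetic oracles) preserve the
  structure of the original experiments, not their absolute numbers; only
  schedule counts, exactness checks and qualitative orderings are asserted.
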