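"""Elicitation loops: orchestrating rounds of generation, querying and
inference, plus the evaluation metrics.

Task 1 runs R rounds. Each round generates a fresh candidate pool with the
current MPO scoring function (through the pool-resampler generator),
initializes the user model with random queries, then iterates batched query
selection -> binary feedback -> posterior inference. The round ends by
updating the scoring function to the posterior-mean intervals, and the
quality of each round's proposals is measured as their average oracle score.

Task 2 runs a single elicitation session: an initial random dataset D_0,
then batched query selection -> continuous (possibly noisy) feedback -> GP
refit; at every iteration the current chemist's component is plugged in as
the generator's scoring function and the proposals' average oracle score is
recorded, giving the elicitation curve.

The generator is a pool resampler standing in for an RL-trained generative
model: it samples a fixed library without replacement with probability
proportional to exp(score / temperature) (Gumbel-top-k, exact for these
weights), so higher-scoring molecules are proposed more often and the
temperature plays the role of the RL exploration budget.

All randomness is derived from the run seed through named seed sequences,
so an entire run is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import CandidatePool, Task1Belief, Task2Belief, random_query, select_batch
from .chem_io import Molecule
from .config import RunConfig
from .gp import ContinuousFeedbackDataset, KernelSpec, gp_fit, gp_predict, gp_refit
from .library import generate_library
from .oracles import (
    MPOOracle,
    MQEDOracle,
    SyntheticActivityOracle,
    binary_feedback,
    noisy_feedback,
)
from .scoring import DesirabilityParams, MPOScoringFunction, ScoringComponent
from .user_model import (
    BinaryFeedbackDataset,
    PosteriorSamples,
    PriorSpec,
    SamplerConfig,
    posterior_point_estimate,
    sample_posterior,
)


# ---------------------------------------------------------------------------
# schedule / trace containers

@dataclass(frozen=True)
class InteractionSchedule:
    """Rounds and per-round query budget of an elicitation run."""

    rounds: int = 1
    n_init: int = 10
    n_iterations: int = 10
    n_batch: int = 10

    @property
    def per_round_total(self) -> int:
        return self.n_init + self.n_iterations * self.n_batch

    @property
    def total_budget(self) -> int:
        return self.rounds * self.per_round_total


@dataclass
class ElicitationTrace:
    """Per-iteration record of an elicitation run, serializable to JSON/CSV."""

    task: str
    seed: int
    config_hash: str
    entries: list[dict] = field(default_factory=list)
    rounds: list[dict] = field(default_factory=list)

    def record(self, **row) -> None:
        self.entries.append(row)

    @property
    def n_feedback_total(self) -> int:
        return int(self.entries[-1]["n_feedback"]) if self.entries else 0

    def metric_curve(self, metric: str):
        xs = [e["n_feedback"] for e in self.entries if metric in e]
        ys = [e[metric] for e in self.entries if metric in e]
        return np.array(xs, float), np.array(ys, float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "task": self.task,
                "seed": self.seed,
                "config_hash": self.config_hash,
                "entries": self.entries,
                "rounds": self.rounds,
            },
            indent=2,
            default=float,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def metrics_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# metrics

def mrae(theta_hat: tuple[np.ndarray, np.ndarray],
         theta_true: tuple[np.ndarray, np.ndarray]) -> float:
    """Mean relative absolute error of estimated desirability intervals.

    Each of the 2K parameter errors is normalized by the true interval
    width HIGH*_k - LOW*_k of its component.
    """
    low_hat, high_hat = (np.asarray(a, float) for a in theta_hat)
    low_true, high_true = (np.asarray(a, float) for a in theta_true)
    width = high_true - low_true
    if np.any(width <= 0):
        raise ValueError("true interval widths must be positive")
    errs = np.concatenate(
        [np.abs(low_hat - low_true) / width, np.abs(high_hat - high_true) / width]
    )
    return float(errs.mean())


def average_oracle_score(mols: list[Molecule], oracle) -> float:
    """Arithmetic mean oracle score of a non-empty set of molecules."""
    if not mols:
        raise ValueError("empty molecule set")
    return float(np.mean(oracle.score_many(mols)))


def auec(xs, ys) -> float:
    """Area under the elicitation curve, normalized by the iteration span.

    A constant curve at c yields c; needs at least two checkpoints.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if xs.size < 2:
        raise ValueError("need at least two checkpoints")
    return float(np.trapezoid(ys, xs) / (xs[-1] - xs[0]))


# ---------------------------------------------------------------------------
# generator stand-in

def pool_resampler_propose(
    library: list[Molecule],
    scoring_fn,
    n: int,
    temperature: float = 0.05,
    seed=0,
    scores: np.ndarray | None = None,
) -> list[Molecule]:
    """Sample n library molecules without replacement, p ~ exp(score / T).

    Implemented as Gumbel-top-k on score/T, which draws exactly from the
    successive-softmax (Plackett-Luce) process; T -> 0 recovers top-n by
    score. ``scores`` may be passed to avoid rescoring the library.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if len(library) < n:
        raise ValueError(f"library of {len(library)} too small for n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if scores is None:
        scores = np.array([float(scoring_fn(m)) for m in library])
    keys = scores / temperature + rng.gumbel(size=len(library))
    top = np.argpartition(-keys, n - 1)[:n]
    top = top[np.argsort(-keys[top], kind="stable")]
    return [library[i] for i in top]


# ---------------------------------------------------------------------------
# oracle construction

def make_oracle(config: RunConfig):
    kind = config.oracle.kind
    if kind == "mqed":
        return MQEDOracle()
    if kind == "synthetic_activity":
        return SyntheticActivityOracle(seed=config.oracle.seed)
    if kind == "mpo":
        if not config.oracle.theta_star:
            raise ValueError("oracle.theta_star required for kind='mpo'")
        template = config.scoring_template()
        comps = []
        for c in template.components:
            lo, hi = config.oracle.theta_star[c.name]
            comps.append(
                ScoringComponent(
                    descriptor=c.descriptor, weight=c.weight,
                    params=DesirabilityParams(lo, hi, c.params.alpha1, c.params.alpha2),
                    name=c.name,
                )
            )
        return MPOOracle(MPOScoringFunction(comps, template.aggregation))
    raise ValueError(f"oracle kind {kind!r} requires an explicit model object")


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([seed, *tags])


# ---------------------------------------------------------------------------
# Task 1

def run_task1(config: RunConfig, library: list[Molecule] | None = None,
              oracle=None) -> ElicitationTrace:
    """Run the Task 1 elicitation protocol; returns the trace.

    Per round: pool generation with the current scoring function, n_init
    random queries, n_iterations batches of strategy-selected queries with
    posterior inference after every batch, then a scoring-function update
    to the posterior-mean intervals and a proposal-quality evaluation.
    """
    if config.task != "task1":
        raise ValueError("config.task must be 'task1'")
    sched = config.schedule
    gen = config.generator
    if library is None:
        library = generate_library(gen.library_size, gen.library_seed)
    if oracle is None:
        oracle = make_oracle(config)
    theta_true = getattr(oracle, "theta_true", None)
    oracle_scores = oracle.score_many(library)

    sf = config.scoring_template()
    sampler_cfg = SamplerConfig(
        nwalkers=config.sampler.nwalkers,
        nsteps=config.sampler.nsteps,
        nburn=config.sampler.nburn,
    )
    trace = ElicitationTrace("task1", config.seed, config.config_hash())

    # round 0: proposals of the unadapted generator (uniform library sample)
    rng0 = _rng(config.seed, 0)
    n_eval = min(gen.n_eval, len(library))
    base_idx = rng0.choice(len(library), size=n_eval, replace=False)
    trace.rounds.append({
        "round": 0,
        "avg_oracle_score": float(np.mean(oracle_scores[base_idx])),
        "n_proposals": int(n_eval),
    })

    n_feedback = 0
    for r in range(1, sched.rounds + 1):
        prior = PriorSpec.from_scoring_function(sf)
        lib_scores = sf.score_molecules(library)
        n_pool = min(len(library), max(10 * sched.per_round_total, 500))
        proposals = pool_resampler_propose(
            library, sf, n_pool, gen.temperature, _rng(config.seed, r, 0),
            scores=lib_scores,
        )
        # the pool holds the round's high-scoring proposals
        prop_scores = sf.score_molecules(proposals)
        keep = prop_scores >= gen.score_threshold
        if keep.sum() < sched.per_round_total:
            order = np.argsort(-prop_scores, kind="stable")
            keep = np.zeros(len(proposals), bool)
            keep[order[: max(sched.per_round_total, 1)]] = True
        pool = CandidatePool([m for m, k in zip(proposals, keep) if k])

        D = BinaryFeedbackDataset()
        fb_rng = _rng(config.seed, r, 1)
        init = random_query(pool, sched.n_init, _rng(config.seed, r, 2))
        D.extend(init, [binary_feedback(oracle.score(m), fb_rng) for m in init])
        n_feedback += len(init)

        samples = sample_posterior(
            D, prior, sf, sampler_cfg, seed=_derived_seed(config.seed, r, 0)
        )
        theta_hat = posterior_point_estimate(samples)
        _record_task1(trace, r, 0, n_feedback, theta_hat, samples, theta_true)

        for t in range(1, sched.n_iterations + 1):
            belief = Task1Belief(samples, sf)
            batch = select_batch(
                pool, config.strategy, sched.n_batch, belief,
                _rng(config.seed, r, 3, t),
            )
            D.extend(batch, [binary_feedback(oracle.score(m), fb_rng) for m in batch])
            n_feedback += len(batch)
            warm = np.hstack([samples.low, samples.delta])
            samples = sample_posterior(
                D, prior, sf, sampler_cfg, seed=_derived_seed(config.seed, r, t),
                init=warm,
            )
            theta_hat = posterior_point_estimate(samples)
            _record_task1(trace, r, t, n_feedback, theta_hat, samples, theta_true)

        sf = sf.with_intervals(*theta_hat)
        lib_scores = sf.score_molecules(library)
        round_props = pool_resampler_propose(
            library, sf, n_eval, gen.temperature, _rng(config.seed, r, 4),
            scores=lib_scores,
        )
        round_scores = sf.score_molecules(round_props)
        high = [m for m, s in zip(round_props, round_scores)
                if s >= gen.score_threshold] or round_props
        idx = {m.smiles: i for i, m in enumerate(library)}
        avg = float(np.mean([oracle_scores[idx[m.smiles]] for m in high]))
        trace.rounds.append(
            {"round": r, "avg_oracle_score": avg, "n_proposals": len(high)}
        )
    return trace


def _derived_seed(seed: int, r: int, t: int) -> int:
    return int(np.random.default_rng([seed, r, t, 99]).integers(2**31 - 1))


def _record_task1(trace, r, t, n_feedback, theta_hat, samples: PosteriorSamples,
                  theta_true) -> None:
    row = {
        "round": r,
        "iteration": t,
        "n_feedback": n_feedback,
        "posterior_sd_mean": float(
            np.mean([samples.low.std(axis=0).mean(), samples.high.std(axis=0).mean()])
        ),
        "acceptance": samples.acceptance,
    }
    low_hat, high_hat = theta_hat
    for k, (lo, hi) in enumerate(zip(low_hat, high_hat)):
        row[f"low_{k}"] = float(lo)
        row[f"high_{k}"] = float(hi)
    if theta_true is not None:
        row["mrae"] = mrae(theta_hat, theta_true)
    trace.record(**row)


# ---------------------------------------------------------------------------
# Task 2

def run_task2(config: RunConfig, library: list[Molecule] | None = None,
              oracle=None) -> ElicitationTrace:
    """Run the Task 2 elicitation protocol; returns the trace.

    D_0 is n_init randomly queried molecules; each iteration queries a
    strategy-selected batch, adds (noisy) continuous feedback and refits
    the GP; the evaluation checkpoint proposes molecules with the current
    chemist's component as scoring function and records their average
    oracle score.
    """
    if config.task != "task2":
        raise ValueError("config.task must be 'task2'")
    sched = config.schedule
    gen = config.generator
    if library is None:
        library = generate_library(gen.library_size, gen.library_seed)
    if oracle is None:
        oracle = make_oracle(config)
    sigma = config.oracle.sigma_chemist
    oracle_scores = oracle.score_many(library)

    kernel = KernelSpec(
        kind=config.gp.kernel,
        fp_radius=config.gp.fp_radius,
        fp_nbits=config.gp.fp_nbits,
    )
    trace = ElicitationTrace("task2", config.seed, config.config_hash())

    pool = CandidatePool(list(library))
    fb_rng = _rng(config.seed, 1)
    init = random_query(pool, sched.n_init, _rng(config.seed, 0))
    D = ContinuousFeedbackDataset(
        list(init), [noisy_feedback(oracle.score(m), sigma, fb_rng) for m in init]
    )
    state = gp_fit(D, kernel=kernel, sigma0=config.gp.sigma0,
                   optimize=config.gp.optimize_hyperparameters)

    lib_features = state.kernel.features(library)
    idx_of = {m.smiles: i for i, m in enumerate(library)}

    def checkpoint(t: int, n_queries: int):
        mean, _ = gp_predict(state, lib_features)
        f_scores = np.clip(mean, 0.0, 1.0)
        props = pool_resampler_propose(
            library, None, min(gen.n_eval, len(library)), gen.temperature,
            _rng(config.seed, 2, t), scores=f_scores,
        )
        avg = float(np.mean([oracle_scores[idx_of[m.smiles]] for m in props]))
        trace.record(
            iteration=t,
            n_feedback=sched.n_init + n_queries,
            n_queries=n_queries,
            avg_oracle_score=avg,
            n_train=state.n_train,
        )

    checkpoint(0, 0)
    n_queries = 0
    for t in range(1, sched.n_iterations + 1):
        belief = Task2Belief(state, candidate_cap=config.gp.candidate_cap)
        batch = select_batch(
            pool, config.strategy, sched.n_batch, belief, _rng(config.seed, 3, t)
        )
        ys = [noisy_feedback(oracle.score(m), sigma, fb_rng) for m in batch]
        n_queries += len(batch)
        if config.gp.optimize_hyperparameters:
            D.extend(batch, ys)
            state = gp_fit(D, kernel=kernel, sigma0=config.gp.sigma0, optimize=True)
        else:
            state = gp_refit(state, batch, ys)
        checkpoint(t, n_queries)

    trace.rounds.append({
        "round": 1,
        "avg_oracle_score": trace.entries[-1]["avg_oracle_score"],
        "n_proposals": min(gen.n_eval, len(library)),
    })
    trace.gp_state = state  # final chemist's component, exposed for reuse
    return trace


def run(config: RunConfig, **kwargs) -> ElicitationTrace:
    """Dispatch to :func:`run_task1` or :func:`run_task2`."""
    return run_task1(config, **kwargs) if config.task == "task1" else run_task2(config, **kwargs)
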