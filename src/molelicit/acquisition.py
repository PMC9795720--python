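"""Query-selection strategies over a pool of unlabeled molecules.

Four strategies are provided: random sampling, uncertainty sampling
(maximum predictive entropy), pure exploitation (maximum expected score) and
Thompson sampling (maximum score under one random posterior draw). Batches
are selected greedily: one ranking per iteration, top n taken — so a
Thompson batch shares a single belief draw, which can understate its
performance relative to random sampling but matches the elicitation
protocol. Ties are broken by pool index order. A molecule is never queried
twice within a run.

Strategies see the model through a small belief interface
(:class:`Task1Belief` over posterior parameter draws, :class:`Task2Belief`
over a GP state), so the same code drives both elicitation tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_io import Molecule, descriptor_matrix
from .gp import GPState, gp_predict, gp_sample
from .scoring import MPOScoringFunction
from .user_model import PosteriorSamples, _mpo_scores, predictive_scores

STRATEGIES = ("random", "uncertainty", "exploit", "thompson")


class PoolExhaustedError(RuntimeError):
    pass


@dataclass
class CandidatePool:
    """Unlabeled molecules with queried-set bookkeeping."""

    molecules: list[Molecule]
    _available: np.ndarray = field(init=False, repr=False)
    _X: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self):
        self._available = np.ones(len(self.molecules), dtype=bool)

    def __len__(self) -> int:
        return int(self._available.sum())

    @property
    def available_indices(self) -> np.ndarray:
        return np.flatnonzero(self._available)

    def available_molecules(self) -> list[Molecule]:
        return [self.molecules[i] for i in self.available_indices]

    def descriptor_matrix(self) -> np.ndarray:
        if self._X is None:
            self._X = descriptor_matrix(self.molecules)
        return self._X

    def take(self, indices: np.ndarray) -> list[Molecule]:
        """Mark global indices as queried and return their molecules."""
        if np.any(~self._available[indices]):
            raise ValueError("molecule already queried")
        self._available[indices] = False
        return [self.molecules[i] for i in indices]


class Task1Belief:
    """Posterior belief over MPO parameters, adapted for acquisition.

    Predictive mean is the Monte-Carlo average of S_theta over draws;
    uncertainty is the binary entropy of that marginal predictive; a
    Thompson draw scores the pool under one stored posterior draw chosen
    uniformly at random.
    """

    def __init__(self, samples: PosteriorSamples, template: MPOScoringFunction,
                 max_draws: int = 500):
        self.samples = samples
        self.template = template
        self.max_draws = max_draws

    def mean(self, X: np.ndarray) -> np.ndarray:
        return predictive_scores(X, self.samples, self.template, self.max_draws)

    def uncertainty(self, X: np.ndarray) -> np.ndarray:
        p = np.clip(self.mean(X), 1e-12, 1 - 1e-12)
        # symmetrize and round so H(p) and H(1-p) tie exactly despite
        # floating-point noise; ties then fall to pool order
        q = np.minimum(p, 1.0 - p)
        return np.round(-(q * np.log(q) + (1 - q) * np.log1p(-q)), 12)

    def thompson(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.samples.n_draws == 0:
            raise ValueError("empty posterior")
        i = int(rng.integers(self.samples.n_draws))
        low = self.samples.low[i : i + 1]
        high = self.samples.high[i : i + 1]
        return _mpo_scores(np.atleast_2d(X), low, high, self.template)[0]

    def features(self, pool: CandidatePool, indices: np.ndarray) -> np.ndarray:
        return pool.descriptor_matrix()[indices]


class Task2Belief:
    """GP posterior belief adapted for acquisition.

    Uncertainty ranks by predictive variance (Gaussian entropy is monotone
    in variance). A Thompson draw is one joint posterior sample over the
    candidates; when the candidate set exceeds ``candidate_cap`` a random
    subsample is drawn jointly and the rest are excluded from that batch.
    """

    def __init__(self, state: GPState, candidate_cap: int = 2000):
        self.state = state
        self.candidate_cap = candidate_cap
        self._feat_cache: dict[int, np.ndarray] = {}

    def mean(self, X: np.ndarray) -> np.ndarray:
        mean, _ = gp_predict(self.state, X)
        return np.atleast_1d(mean)

    def uncertainty(self, X: np.ndarray) -> np.ndarray:
        _, var = gp_predict(self.state, X)
        return np.atleast_1d(var)

    def thompson(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        X = np.atleast_2d(X)
        m = X.shape[0]
        if m > self.candidate_cap:
            keep = rng.choice(m, size=self.candidate_cap, replace=False)
            vals = np.full(m, -np.inf)
            vals[keep] = gp_sample(self.state, X[keep], rng)
            return vals
        return gp_sample(self.state, X, rng)

    def features(self, pool: CandidatePool, indices: np.ndarray) -> np.ndarray:
        key = id(pool)
        if key not in self._feat_cache:
            self._feat_cache[key] = self.state.kernel.features(pool.molecules)
        return self._feat_cache[key][indices]


def _top_n(scores: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n largest scores; ties broken by position (stable)."""
    order = np.argsort(-scores, kind="stable")
    return order[:n]


def random_query(pool: CandidatePool, n: int, seed) -> list[Molecule]:
    """n distinct molecules uniformly without replacement."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    avail = pool.available_indices
    if avail.size < n:
        raise PoolExhaustedError(f"pool has {avail.size} < {n} molecules")
    pick = rng.choice(avail.size, size=n, replace=False)
    return pool.take(avail[pick])


def _ranked_query(pool: CandidatePool, scores_fn, n: int) -> list[Molecule]:
    avail = pool.available_indices
    if avail.size < n:
        raise PoolExhaustedError(f"pool has {avail.size} < {n} molecules")
    scores = scores_fn(avail)
    return pool.take(avail[_top_n(scores, n)])


def uncertainty_query(pool: CandidatePool, model, n: int) -> list[Molecule]:
    """Top-n by predictive uncertainty (entropy / variance)."""
    return _ranked_query(
        pool, lambda idx: model.uncertainty(model.features(pool, idx)), n
    )


def exploit_query(pool: CandidatePool, model, n: int) -> list[Molecule]:
    """Top-n by expected score under the current belief."""
    return _ranked_query(
        pool, lambda idx: model.mean(model.features(pool, idx)), n
    )


def thompson_query(pool: CandidatePool, model, n: int, seed) -> list[Molecule]:
    """Top-n under one random draw from the current belief."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _ranked_query(
        pool, lambda idx: model.thompson(model.features(pool, idx), rng), n
    )


def select_batch(
    pool: CandidatePool,
    strategy: str,
    n_batch: int,
    model=None,
    seed=0,
) -> list[Molecule]:
    """Greedy batch selection: one ranking, top n_batch, removed from pool."""
    if strategy == "random":
        return random_query(pool, n_batch, seed)
    if model is None:
        raise ValueError(f"strategy {strategy!r} requires a fitted model")
    if strategy == "uncertainty":
        return uncertainty_query(pool, model, n_batch)
    if strategy == "exploit":
        return exploit_query(pool, model, n_batch)
    if strategy == "thompson":
        return thompson_query(pool, model, n_batch, seed)
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
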