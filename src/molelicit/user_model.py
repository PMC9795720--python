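"""Task 1 probabilistic user model: inferring desirability intervals from
binary feedback.

The chemist is assumed to approve a molecule (y = 1) with probability equal
to their tacit MPO score, giving the observation model

    y | x ~ Bernoulli(S_theta(x)),

where S_theta aggregates double-sigmoid desirabilities with unknown
(LOW_k, HIGH_k) per component and fixed steepnesses and weights. Priors are
independent Normals centred on the chemist's initial guesses,

    LOW_k ~ N(LOW_0k, sigma_k^2),  HIGH_k ~ N(HIGH_0k, sigma_k^2),
    sigma_k = (HIGH_0k - LOW_0k) / 8,

and the model is parameterized as (LOW, DELTA) with HIGH = LOW + DELTA and
DELTA > 0 enforced as sampler support (unit-Jacobian change of variables, so
the prior density is evaluated directly at LOW and LOW + DELTA). The
posterior is sampled with an affine-invariant ensemble MCMC sampler; the
point estimate used to update the scoring function is the posterior mean,
which minimizes mean squared parameter error.

Actively collected feedback is treated as i.i.d. in the likelihood — the
same simplification the elicitation protocol makes, which may bias the
posterior when queries are chosen adaptively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from scipy.stats import norm

from .chem_io import Molecule, descriptor_matrix
from .scoring import MPOScoringFunction, double_sigmoid_batch

#: Clamp for Bernoulli probabilities so the log-likelihood stays finite.
EPS = 1e-9


@dataclass(frozen=True)
class PriorSpec:
    """Normal priors on (LOW_k, HIGH_k), centred on the initial guesses.

    ``sigma`` defaults to (high0 - low0) / 8 per component.
    """

    low0: np.ndarray
    high0: np.ndarray
    sigma: np.ndarray = None

    def __post_init__(self):
        low0 = np.atleast_1d(np.asarray(self.low0, dtype=float))
        high0 = np.atleast_1d(np.asarray(self.high0, dtype=float))
        if np.any(high0 <= low0):
            raise ValueError("high0 must exceed low0 for every component")
        sigma = self.sigma
        if sigma is None:
            sigma = (high0 - low0) / 8.0
        else:
            sigma = np.broadcast_to(
                np.asarray(sigma, dtype=float), low0.shape
            ).copy()
            if np.any(sigma <= 0):
                raise ValueError("sigma must be positive")
        object.__setattr__(self, "low0", low0)
        object.__setattr__(self, "high0", high0)
        object.__setattr__(self, "sigma", sigma)

    @property
    def n_components(self) -> int:
        return self.low0.size

    @classmethod
    def from_scoring_function(cls, sf: MPOScoringFunction) -> "PriorSpec":
        """Prior centred on the intervals currently in *sf* (round re-centring)."""
        low0 = np.array([c.params.low for c in sf.components])
        high0 = np.array([c.params.high for c in sf.components])
        return cls(low0=low0, high0=high0)


@dataclass
class BinaryFeedbackDataset:
    """Binary molecule-feedback records with a cached descriptor matrix."""

    molecules: list[Molecule] = field(default_factory=list)
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0))
    _X: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=float)
        if self.labels.size and not np.all(np.isin(self.labels, (0.0, 1.0))):
            raise ValueError("Task 1 labels must be strictly binary")
        if len(self.molecules) != self.labels.size:
            raise ValueError("molecules and labels length mismatch")

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def X(self) -> np.ndarray:
        if self._X is None or self._X.shape[0] != len(self.molecules):
            self._X = descriptor_matrix(self.molecules)
        return self._X

    def extend(self, mols: list[Molecule], labels) -> None:
        self.molecules.extend(mols)
        self.labels = np.concatenate([self.labels, np.asarray(labels, float)])
        if self.labels.size and not np.all(np.isin(self.labels, (0.0, 1.0))):
            raise ValueError("Task 1 labels must be strictly binary")
        self._X = None


def _mpo_scores(X: np.ndarray, low: np.ndarray, high: np.ndarray,
                template: MPOScoringFunction) -> np.ndarray:
    """S_theta for a batch of parameter vectors.

    X: (N, 7) descriptors; low/high: (M, K); returns (M, N) scores using the
    template's fixed steepnesses, weights and aggregation.
    """
    idx = template.descriptor_indices
    a1 = np.array([c.params.alpha1 for c in template.components])
    a2 = np.array([c.params.alpha2 for c in template.components])
    w = template.weights
    cols = X[:, idx]  # (N, K)
    phi = double_sigmoid_batch(
        cols[None, :, :], low[:, None, :], high[:, None, :], a1, a2
    )  # (M, N, K)
    if template.aggregation == "product":
        with np.errstate(divide="ignore"):
            logphi = np.log(np.maximum(phi, 1e-300))
        s = np.exp(np.einsum("k,mnk->mn", w, logphi))
        s[np.any(phi == 0.0, axis=2)] = 0.0
    else:
        s = np.einsum("k,mnk->mn", w, phi)
    return np.clip(s, 0.0, 1.0)


def log_likelihood(D: BinaryFeedbackDataset, theta: np.ndarray,
                   template: MPOScoringFunction) -> np.ndarray:
    """Bernoulli log-likelihood of the feedback under theta.

    *theta* is (2K,) or (M, 2K) laid out as [LOW_1..K, DELTA_1..K]; returns a
    scalar or (M,). Probabilities are clamped to [EPS, 1-EPS]. Empty data
    gives 0.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    K = theta.shape[1] // 2
    if len(D) == 0:
        out = np.zeros(theta.shape[0])
        return out if out.size > 1 else float(out[0])
    low, delta = theta[:, :K], theta[:, K:]
    s = _mpo_scores(D.X, low, low + delta, template)
    s = np.clip(s, EPS, 1.0 - EPS)
    y = D.labels
    ll = np.sum(y * np.log(s) + (1.0 - y) * np.log1p(-s), axis=1)
    return ll if ll.size > 1 else float(ll[0])


def log_prior(theta: np.ndarray, prior: PriorSpec) -> np.ndarray:
    """Log prior density at theta = [LOW, DELTA]; -inf outside DELTA > 0."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    K = prior.n_components
    low, delta = theta[:, :K], theta[:, K:]
    lp = np.full(theta.shape[0], -np.inf)
    ok = np.all(delta > 0, axis=1)
    if np.any(ok):
        lp_low = norm.logpdf(low[ok], prior.low0, prior.sigma).sum(axis=1)
        lp_high = norm.logpdf(low[ok] + delta[ok], prior.high0, prior.sigma).sum(axis=1)
        lp[ok] = lp_low + lp_high
    return lp if lp.size > 1 else float(lp[0])


@dataclass
class SamplerConfig:
    """Ensemble-sampler budget. Defaults give >= 8000 retained draws."""

    nwalkers: int = 32
    nsteps: int = 250
    nburn: int = 250
    thin: int = 1


@dataclass
class PosteriorSamples:
    """Retained posterior draws of (LOW_k, DELTA_k) plus diagnostics."""

    low: np.ndarray    # (S, K)
    delta: np.ndarray  # (S, K)
    acceptance: float = float("nan")
    diverged: bool = False

    @property
    def high(self) -> np.ndarray:
        return self.low + self.delta

    @property
    def n_draws(self) -> int:
        return self.low.shape[0]

    def subsample(self, max_draws: int) -> "PosteriorSamples":
        """Deterministic stride subsample for cheaper predictive averaging."""
        if self.n_draws <= max_draws:
            return self
        idx = np.linspace(0, self.n_draws - 1, max_draws).astype(int)
        return PosteriorSamples(self.low[idx], self.delta[idx],
                                self.acceptance, self.diverged)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draws (component, parameter, draw, value) for audit."""
        S, K = self.low.shape
        rows = []
        for name, arr in (("LOW", self.low), ("HIGH", self.high)):
            for k in range(K):
                rows.append(pd.DataFrame({
                    "component": k, "parameter": name,
                    "draw": np.arange(S), "value": arr[:, k],
                }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def sample_posterior(
    D: BinaryFeedbackDataset,
    prior: PriorSpec,
    template: MPOScoringFunction,
    sampler_config: SamplerConfig | None = None,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> PosteriorSamples:
    """Draw from p(theta | D) by affine-invariant ensemble MCMC.

    Empty *D* reduces to sampling the (truncated) prior. Reproducible for a
    fixed seed. A mean acceptance fraction below 0.05 is flagged as a
    convergence warning in ``diverged`` (not fatal).

    *init* optionally warm-starts the walkers from draws of a previous
    posterior (rows of [LOW, DELTA]); in a sequential elicitation loop the
    posterior moves only slightly per batch, so warm starts cut the burn-in
    needed for converged point estimates.
    """
    cfg = sampler_config or SamplerConfig()
    K = prior.n_components
    ndim = 2 * K
    nwalkers = max(cfg.nwalkers, 2 * ndim + 2)
    nwalkers += nwalkers % 2

    def log_prob(theta):
        lp = np.atleast_1d(log_prior(theta, prior))
        out = np.where(np.isfinite(lp), lp, -np.inf)
        finite = np.isfinite(lp)
        if np.any(finite):
            th = np.atleast_2d(theta)[finite]
            out[finite] += np.atleast_1d(log_likelihood(D, th, template))
        return out

    rs = np.random.RandomState(seed)
    width = prior.high0 - prior.low0
    if init is not None and init.shape[0] >= nwalkers and init.shape[1] == ndim:
        pick = rs.choice(init.shape[0], size=nwalkers, replace=False)
        p0 = init[pick].copy()
        p0[:, K:] = np.maximum(p0[:, K:], 1e-3 * width)
    else:
        p0 = np.empty((nwalkers, ndim))
        p0[:, :K] = prior.low0 + 0.2 * prior.sigma * rs.randn(nwalkers, K)
        p0[:, K:] = np.abs(
            width + 0.2 * np.sqrt(2.0) * prior.sigma * rs.randn(nwalkers, K)
        )
        p0[:, K:] = np.maximum(p0[:, K:], 1e-3 * width)

    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, vectorize=True)
    state = emcee.State(p0, random_state=np.random.RandomState(seed + 1).get_state())
    state = sampler.run_mcmc(state, cfg.nburn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, cfg.nsteps, thin_by=cfg.thin, progress=False)

    chain = sampler.get_chain(flat=True)  # (S, 2K)
    acc = float(np.mean(sampler.acceptance_fraction))
    return PosteriorSamples(
        low=chain[:, :K], delta=chain[:, K:],
        acceptance=acc, diverged=acc < 0.05,
    )


def posterior_point_estimate(samples: PosteriorSamples) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean point estimate (low_hat, high_hat), with high > low.

    HIGH is mean(LOW) + mean(DELTA); positivity of every DELTA draw
    guarantees the ordering.
    """
    if samples.n_draws < 1:
        raise ValueError("need at least one draw")
    low_hat = samples.low.mean(axis=0)
    high_hat = low_hat + samples.delta.mean(axis=0)
    return low_hat, high_hat


def predictive_scores(
    X: np.ndarray,
    samples: PosteriorSamples,
    template: MPOScoringFunction,
    max_draws: int = 500,
) -> np.ndarray:
    """Posterior-predictive expected score E_theta[S_theta(x)] for each row of X.

    Monte-Carlo average over (a stride subsample of) the stored draws.
    """
    sub = samples.subsample(max_draws)
    s = _mpo_scores(np.atleast_2d(X), sub.low, sub.high, template)
    return s.mean(axis=0)


def predictive_score(
    mol: Molecule,
    samples: PosteriorSamples,
    template: MPOScoringFunction,
    max_draws: int = 500,
) -> float:
    """Posterior-predictive expected score of a single molecule."""
    return float(predictive_scores(mol.descriptors[None, :], samples, template, max_draws)[0])
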