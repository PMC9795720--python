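"""Task 2 chemist's component: Gaussian-process regression on molecules.

A GP prior f ~ GP(0, k) is placed over the chemist's latent evaluation of a
molecular property, with a Gaussian feedback likelihood y ~ N(f(x), sigma0^2).
Two kernels are supported: the Tanimoto kernel on binary Morgan fingerprints,

    k(a, b) = <a, b> / (<a, a> + <b, b> - <a, b>),

optionally scaled by a learnable output variance, and the squared-exponential
kernel on descriptor vectors. The posterior at a test point is

    mean = k_*^T (K + sigma0^2 I)^{-1} y
    var  = k(x_*, x_*) - k_*^T (K + sigma0^2 I)^{-1} k_*,

computed through a cached Cholesky factorization that is refreshed whenever
the training data change. Joint posterior draws over a candidate set (for
Thompson sampling) come from the factorized posterior covariance.

Predictions are not clipped here; the exported scoring-function wrapper
clips to [0, 1] at the boundary where f is handed to a molecule generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError
from scipy.optimize import minimize_scalar

from .chem_io import Molecule, descriptor_matrix, fingerprint_matrix

JITTER = 1e-8


def tanimoto_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Tanimoto similarity between binary vectors or matrices of them.

    Accepts (d,) or (n, d) for each argument; broadcasts to an (n, m) Gram
    matrix. The similarity of two all-zero vectors is defined as 1.
    """
    A = np.atleast_2d(np.asarray(a, dtype=float))
    B = np.atleast_2d(np.asarray(b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint length mismatch")
    cross = A @ B.T
    na = np.sum(A * A, axis=1)[:, None]
    nb = np.sum(B * B, axis=1)[None, :]
    denom = na + nb - cross
    out = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), 1.0)
    if np.ndim(a) == 1 and np.ndim(b) == 1:
        return float(out[0, 0])
    return out


def sq_exp_kernel(a, b, lengthscale: float = 1.0, variance: float = 1.0):
    """Squared-exponential kernel variance * exp(-||a-b||^2 / (2 l^2))."""
    if lengthscale <= 0:
        raise ValueError("lengthscale must be positive")
    A = np.atleast_2d(np.asarray(a, dtype=float))
    B = np.atleast_2d(np.asarray(b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature length mismatch")
    d2 = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    out = variance * np.exp(-np.maximum(d2, 0.0) / (2.0 * lengthscale**2))
    if np.ndim(a) == 1 and np.ndim(b) == 1:
        return float(out[0, 0])
    return out


@dataclass
class KernelSpec:
    """Kernel choice plus hyperparameters.

    tanimoto: ``variance`` is a single output scale (fingerprint features);
    squared_exponential: ``lengthscale`` and ``variance`` (descriptor
    features, standardized internally by ``feature_scale``).
    """

    kind: str = "tanimoto"
    variance: float = 1.0
    lengthscale: float = 1.0
    fp_radius: int = 3
    fp_nbits: int = 2048

    def __post_init__(self):
        if self.kind not in ("tanimoto", "squared_exponential"):
            raise ValueError(f"unknown kernel {self.kind!r}")

    def features(self, mols: list[Molecule]) -> np.ndarray:
        if self.kind == "tanimoto":
            return fingerprint_matrix(mols, self.fp_radius, self.fp_nbits).astype(float)
        return descriptor_matrix(mols)

    def gram(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        if self.kind == "tanimoto":
            return self.variance * tanimoto_kernel(A, B)
        return sq_exp_kernel(A, B, self.lengthscale, self.variance)

    def diag(self, A: np.ndarray) -> np.ndarray:
        if self.kind == "tanimoto":
            return np.full(A.shape[0], self.variance, dtype=float)
        return np.full(A.shape[0], self.variance, dtype=float)


@dataclass
class ContinuousFeedbackDataset:
    """Continuous molecule-feedback records (labels in [0, 1])."""

    molecules: list[Molecule] = field(default_factory=list)
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=float)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 1):
            raise ValueError("Task 2 labels must lie in [0, 1]")
        if len(self.molecules) != self.labels.size:
            raise ValueError("molecules and labels length mismatch")

    def __len__(self) -> int:
        return len(self.molecules)

    def extend(self, mols: list[Molecule], labels) -> None:
        labels = np.asarray(labels, dtype=float)
        if labels.size and (labels.min() < 0 or labels.max() > 1):
            raise ValueError("Task 2 labels must lie in [0, 1]")
        self.molecules.extend(mols)
        self.labels = np.concatenate([self.labels, labels])


@dataclass
class GPState:
    """Fitted GP posterior with a cached Cholesky factorization."""

    kernel: KernelSpec
    sigma0: float
    X: np.ndarray          # (N, d) training features
    y: np.ndarray          # (N,)
    molecules: list[Molecule] = field(default_factory=list)
    _cho: tuple | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_train(self) -> int:
        return self.X.shape[0]

    def _factorize(self):
        if self._cho is None:
            K = self.kernel.gram(self.X, self.X)
            A = K + self.sigma0**2 * np.eye(self.n_train)
            try:
                self._cho = cho_factor(A, lower=True)
            except LinAlgError:
                self._cho = cho_factor(
                    A + JITTER * np.eye(self.n_train), lower=True
                )
            self._alpha = cho_solve(self._cho, self.y)
        return self._cho, self._alpha


def gp_fit(
    D: ContinuousFeedbackDataset,
    kernel: KernelSpec | None = None,
    sigma0: float = 0.1,
    optimize: bool = False,
) -> GPState:
    """Fit the GP: build the Gram matrix and factorize (K + sigma0^2 I).

    An empty dataset yields the prior state (mean 0, variance k(x,x)).
    With ``optimize=True`` the kernel output variance is set by maximizing
    the log marginal likelihood (scalar search; for the squared-exponential
    kernel the lengthscale is profiled over a log-spaced grid as well).
    """
    kernel = kernel or KernelSpec()
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    X = (
        kernel.features(D.molecules)
        if len(D)
        else np.zeros((0, 1))
    )
    y = np.asarray(D.labels, dtype=float)
    if optimize and len(D) >= 2:
        kernel = _optimize_hyperparameters(kernel, X, y, sigma0)
    return GPState(kernel=kernel, sigma0=float(sigma0), X=X, y=y,
                   molecules=list(D.molecules))


def _log_marginal_likelihood(kernel: KernelSpec, X, y, sigma0) -> float:
    n = X.shape[0]
    K = kernel.gram(X, X) + sigma0**2 * np.eye(n)
    try:
        L = cholesky(K, lower=True)
    except LinAlgError:
        return -np.inf
    alpha = cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * np.log(2 * np.pi)
    )


def _optimize_hyperparameters(kernel: KernelSpec, X, y, sigma0) -> KernelSpec:
    def neg_lml_variance(log_v, base):
        k = replace(base, variance=float(np.exp(log_v)))
        return -_log_marginal_likelihood(k, X, y, sigma0)

    if kernel.kind == "tanimoto":
        res = minimize_scalar(
            neg_lml_variance, bounds=(np.log(1e-3), np.log(1e3)),
            args=(kernel,), method="bounded",
        )
        return replace(kernel, variance=float(np.exp(res.x)))
    # squared_exponential: grid over lengthscale, scalar opt of variance
    best, best_lml = kernel, -np.inf
    scale = float(np.median(np.std(X, axis=0))) or 1.0
    for ls in scale * np.logspace(-1, 2, 10):
        res = minimize_scalar(
            neg_lml_variance, bounds=(np.log(1e-3), np.log(1e3)),
            args=(replace(kernel, lengthscale=float(ls)),), method="bounded",
        )
        cand = replace(kernel, lengthscale=float(ls), variance=float(np.exp(res.x)))
        lml = _log_marginal_likelihood(cand, X, y, sigma0)
        if lml > best_lml:
            best, best_lml = cand, lml
    return best


def gp_refit(state: GPState, mols: list[Molecule], labels) -> GPState:
    """Return a new state with records appended (factorization refreshed)."""
    labels = np.asarray(labels, dtype=float)
    Xnew = state.kernel.features(mols)
    if state.n_train == 0:
        X = Xnew
    else:
        X = np.vstack([state.X, Xnew])
    return GPState(
        kernel=state.kernel, sigma0=state.sigma0, X=X,
        y=np.concatenate([state.y, labels]),
        molecules=state.molecules + list(mols),
    )


def _test_features(state: GPState, x) -> np.ndarray:
    if isinstance(x, Molecule):
        return state.kernel.features([x])
    if isinstance(x, list):
        return state.kernel.features(x)
    return np.atleast_2d(np.asarray(x, dtype=float))


def gp_predict(state: GPState, x) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at test point(s).

    *x* may be a Molecule, a list of Molecules, or a feature matrix. Returns
    (mean, variance) as floats for a single input, arrays otherwise.
    Variances are floored at 0 against round-off.
    """
    Xs = _test_features(state, x)
    prior_var = state.kernel.diag(Xs)
    if state.n_train == 0:
        mean, var = np.zeros(Xs.shape[0]), prior_var
    else:
        cho, alpha = state._factorize()
        Ks = state.kernel.gram(Xs, state.X)  # (m, N)
        mean = Ks @ alpha
        v = cho_solve(cho, Ks.T)  # (N, m)
        var = np.maximum(prior_var - np.sum(Ks * v.T, axis=1), 0.0)
    single = isinstance(x, Molecule) or (
        not isinstance(x, list) and np.ndim(x) == 1
    )
    if single:
        return float(mean[0]), float(var[0])
    return mean, var


def gp_sample(state: GPState, X, seed: int | np.random.Generator = 0) -> np.ndarray:
    """One joint draw from the GP posterior over candidate set *X*.

    The posterior covariance over the candidates is factorized (Cholesky
    with escalating jitter) and multiplied with seeded standard normals.
    """
    Xs = _test_features(state, X)
    m = Xs.shape[0]
    Kss = state.kernel.gram(Xs, Xs)
    if state.n_train == 0:
        mean = np.zeros(m)
        cov = Kss
    else:
        cho, alpha = state._factorize()
        Ks = state.kernel.gram(Xs, state.X)
        mean = Ks @ alpha
        cov = Kss - Ks @ cho_solve(cho, Ks.T)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(m)
    jitter = JITTER
    for _ in range(8):
        try:
            L = cholesky(cov + jitter * np.eye(m), lower=True)
            return mean + L @ z
        except LinAlgError:
            jitter *= 100.0
    raise LinAlgError("posterior covariance not factorizable")  # pragma: no cover


def as_scoring_function(state: GPState):
    """Export the chemist's component as a SMILES/Molecule -> [0,1] scorer.

    The GP mean is clipped to [0, 1] at this boundary only.
    """

    def score(x) -> float:
        if isinstance(x, str):
            x = Molecule.from_smiles(x)
        mean, _ = gp_predict(state, x)
        return float(np.clip(mean, 0.0, 1.0))

    return score


def state_to_dict(state: GPState) -> dict:
    """Serialize the training records and hyperparameters (resumable)."""
    return {
        "kernel": {
            "kind": state.kernel.kind,
            "variance": state.kernel.variance,
            "lengthscale": state.kernel.lengthscale,
            "fp_radius": state.kernel.fp_radius,
            "fp_nbits": state.kernel.fp_nbits,
        },
        "sigma0": state.sigma0,
        "records": [
            {"smiles": m.smiles, "label": float(y)}
            for m, y in zip(state.molecules, state.y)
        ],
    }


def state_from_dict(d: dict) -> GPState:
    kernel = KernelSpec(**d["kernel"])
    mols = [Molecule.from_smiles(r["smiles"]) for r in d["records"]]
    D = ContinuousFeedbackDataset(mols, [r["label"] for r in d["records"]])
    return gp_fit(D, kernel=kernel, sigma0=d["sigma0"])
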