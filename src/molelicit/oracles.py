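"""Simulated chemists answering elicitation queries.

Three ground-truth scorers are provided:

* :class:`MQEDOracle` — a modified QED drug-likeness score (Task 1): the
  published QED recipe with the mean property weights, except that the
  structural-ALERTS component gets weight 0 and the logP desirability curve
  is translated so its optimum sits near 1.5 instead of the published ~3.
* :class:`SyntheticActivityOracle` — a deterministic pseudo-activity score
  (Task 2): a logistic transform of a seeded linear functional of Morgan
  fingerprint bits. It preserves the structure of a trained
  activity-prediction oracle (smooth in fingerprint space, spread over
  [0, 1]) without requiring external assay data; the adapter below restores
  fidelity for users who have a trained model.
* :class:`MPOOracle` — a chemist whose tacit score is an MPO scoring
  function with known parameters theta*, used for parameter-recovery
  experiments.

Feedback channels: binary feedback is a Bernoulli draw with probability
equal to the oracle score; continuous feedback adds Gaussian noise with
standard deviation sigma_chemist and caps the result to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit.Chem import QED
from scipy.special import expit

from .chem_io import Molecule
from .scoring import MPOScoringFunction

#: QED mean property weights with the ALERTS component zeroed.
_MQED_WEIGHTS = {
    "MW": 0.66, "ALOGP": 0.46, "HBA": 0.05, "HBD": 0.61,
    "PSA": 0.06, "ROTB": 0.65, "AROM": 0.48, "ALERTS": 0.0,
}
#: Translation applied to the logP axis: the desirability of logP x becomes
#: the published desirability of x + 1.5, moving the optimum from ~3 to ~1.5.
_LOGP_SHIFT = 1.5


def _qed_from_properties(props, weights: dict, logp_shift: float) -> float:
    """Weighted-geometric-mean QED from an RDKit QEDproperties tuple."""
    total, wsum = 0.0, 0.0
    for name, w in weights.items():
        if w == 0.0:
            continue
        value = getattr(props, name)
        if name == "ALOGP":
            value = value + logp_shift
        d = QED.ads(value, QED.adsParameters[name])
        total += w * np.log(max(d, 1e-12))
        wsum += w
    return float(np.exp(total / wsum))


def mqed_score(mol: Molecule) -> float:
    """Modified QED in [0, 1]: ALERTS weight 0, logP optimum moved to ~1.5."""
    props = QED.properties(mol.rdkit)
    return _qed_from_properties(props, _MQED_WEIGHTS, _LOGP_SHIFT)


def qed_reference_score(mol: Molecule) -> float:
    """Unmodified mean-weighted QED through the same code path.

    Regression guard: with the logP shift reversed and the ALERTS weight
    restored this must equal RDKit's own ``QED.qed``.
    """
    weights = dict(_MQED_WEIGHTS, ALERTS=0.95)
    props = QED.properties(mol.rdkit)
    return _qed_from_properties(props, weights, 0.0)


def binary_feedback(score: float, rng: np.random.Generator) -> int:
    """Bernoulli(score) feedback draw."""
    if not 0.0 <= score <= 1.0:
        raise ValueError("score must lie in [0, 1]")
    return int(rng.random() < score)


def noisy_feedback(score: float, sigma_chemist: float, rng: np.random.Generator) -> float:
    """score + N(0, sigma^2), capped to [0, 1]; identity when sigma = 0."""
    if sigma_chemist < 0:
        raise ValueError("sigma_chemist must be >= 0")
    if sigma_chemist == 0:
        return float(score)
    return float(np.clip(score + sigma_chemist * rng.standard_normal(), 0.0, 1.0))


class MQEDOracle:
    """Simulated Task 1 chemist scoring by modified QED."""

    name = "mqed"

    def score(self, mol: Molecule) -> float:
        return mqed_score(mol)

    def score_many(self, mols: list[Molecule]) -> np.ndarray:
        return np.array([self.score(m) for m in mols])


@dataclass
class SyntheticActivityOracle:
    """Deterministic pseudo-activity oracle on fingerprint space.

    score(x) = expit(gain * w . fp(x) / sqrt(popcount(fp(x)))) with w a
    fixed seeded standard-normal vector, so structurally similar molecules
    (shared fingerprint bits) receive similar scores. ``gain`` is
    calibrated so a diverse pool spreads over [0, 1] with sd >= 0.15.
    """

    seed: int = 0
    radius: int = 3
    nbits: int = 2048
    gain: float = 2.0
    name: str = "synthetic_activity"

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        self._w = rng.standard_normal(self.nbits)

    def score(self, mol: Molecule) -> float:
        fp = mol.fingerprint(self.radius, self.nbits).astype(float)
        count = max(float(fp.sum()), 1.0)
        return float(expit(self.gain * (self._w @ fp) / np.sqrt(count)))

    def score_many(self, mols: list[Molecule]) -> np.ndarray:
        return np.array([self.score(m) for m in mols])


@dataclass
class MPOOracle:
    """Simulated chemist whose tacit score is a known MPO scoring function."""

    scoring_function: MPOScoringFunction
    name: str = "mpo"

    def score(self, mol: Molecule) -> float:
        return self.scoring_function(mol)

    def score_many(self, mols: list[Molecule]) -> np.ndarray:
        return self.scoring_function.score_molecules(mols)

    @property
    def theta_true(self) -> tuple[np.ndarray, np.ndarray]:
        low = np.array([c.params.low for c in self.scoring_function.components])
        high = np.array([c.params.high for c in self.scoring_function.components])
        return low, high


class ExternalModelOracle:
    """Wrap a user-supplied SMILES -> probability model as an oracle.

    *model* may be a callable or expose ``predict`` / ``predict_proba``.
    Outputs outside [0, 1] are rejected.
    """

    name = "external_model"

    def __init__(self, model):
        if callable(model):
            self._fn = model
        elif hasattr(model, "predict_proba"):
            self._fn = lambda s: float(model.predict_proba([s])[0][-1])
        elif hasattr(model, "predict"):
            self._fn = lambda s: float(model.predict([s])[0])
        else:
            raise TypeError("model must be callable or expose predict/predict_proba")

    def score(self, mol: Molecule) -> float:
        out = float(self._fn(mol.smiles))
        if not 0.0 <= out <= 1.0:
            raise ValueError(f"external model returned {out}, outside [0, 1]")
        return out

    def score_many(self, mols: list[Molecule]) -> np.ndarray:
        return np.array([self.score(m) for m in mols])


def external_model_adapter(model) -> ExternalModelOracle:
    """Adapter hook for a trained activity model (e.g. an RF classifier)."""
    return ExternalModelOracle(model)
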