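"""Desirability transforms and multi-parameter-optimization (MPO) aggregation.

Each scoring component maps one physicochemical property c_k(x) through a
double-sigmoid desirability function

    phi(x; theta) = 10^(a1 x) / (10^(a1 x) + 10^(a1 LOW))
                  - 10^(a2 x) / (10^(a2 x) + 10^(a2 HIGH)),

with theta = [LOW, HIGH, a1, a2]: a smooth plateau near 1 on [LOW, HIGH],
falling to 0 outside, with edge steepnesses a1 (rising) and a2 (falling).
Component scores are aggregated into S(x) in [0, 1] as a weighted geometric
mean (product mode) or weighted arithmetic mean (sum mode).

Numerics: each base-10 logistic term equals expit(ln10 * a * (x - bound)),
so the transform is evaluated through `scipy.special.expit` and never forms
10^(a x) explicitly; the difference is clipped to [0, 1] (for unequal
steepnesses the raw difference can go marginally negative far outside the
interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .chem_io import DESCRIPTOR_NAMES, Molecule, descriptor_matrix

LN10 = np.log(10.0)


@dataclass(frozen=True)
class DesirabilityParams:
    """The four double-sigmoid parameters of one scoring component."""

    low: float
    high: float
    alpha1: float
    alpha2: float

    def __post_init__(self):
        if not self.high > self.low:
            raise ValueError(f"high ({self.high}) must exceed low ({self.low})")
        if not (self.alpha1 > 0 and np.isfinite(self.alpha1)):
            raise ValueError("alpha1 must be finite and positive")
        if not (self.alpha2 > 0 and np.isfinite(self.alpha2)):
            raise ValueError("alpha2 must be finite and positive")


def double_sigmoid(x, params: DesirabilityParams):
    """Evaluate the double-sigmoid desirability at *x* (scalar or array)."""
    x = np.asarray(x, dtype=float)
    rise = expit(LN10 * params.alpha1 * (x - params.low))
    fall = expit(LN10 * params.alpha2 * (x - params.high))
    return np.clip(rise - fall, 0.0, 1.0)


def double_sigmoid_batch(x, low, high, alpha1, alpha2):
    """Vectorized double sigmoid with broadcasting over all arguments.

    Used by the Task 1 user model to score a whole dataset under a whole
    batch of sampled parameter vectors in one shot.
    """
    rise = expit(LN10 * alpha1 * (x - low))
    fall = expit(LN10 * alpha2 * (x - high))
    return np.clip(rise - fall, 0.0, 1.0)


def aggregate(scores, weights, mode: str = "product") -> float:
    """Aggregate component scores in [0,1] with positive weights.

    product: [prod phi_k^w_k]^(1/sum w) (weighted geometric mean);
    sum: sum w_k phi_k / sum w (weighted arithmetic mean).
    """
    scores = np.asarray(scores, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("scores must lie in [0, 1]")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    w = weights / weights.sum()
    if mode == "product":
        if np.any(scores == 0.0):
            return 0.0
        return float(np.exp(np.sum(w * np.log(scores))))
    if mode == "sum":
        return float(np.sum(w * scores))
    raise ValueError(f"unknown aggregation mode {mode!r}")


@dataclass(frozen=True)
class ScoringComponent:
    """One MPO component: descriptor index, weight and desirability params."""

    descriptor: int | str
    weight: float
    params: DesirabilityParams
    name: str = ""

    def __post_init__(self):
        if isinstance(self.descriptor, str):
            object.__setattr__(
                self, "descriptor", DESCRIPTOR_NAMES.index(self.descriptor)
            )
        if not self.weight > 0:
            raise ValueError("weight must be positive")
        if not self.name:
            object.__setattr__(self, "name", DESCRIPTOR_NAMES[self.descriptor])


@dataclass
class MPOScoringFunction:
    """Weighted aggregation of K desirability-transformed components.

    Weights are normalized to sum to 1 at construction (the adaptive Task 1
    setting constrains them so); raw generator-style weights in [1, inf) are
    accepted and normalized the same way.
    """

    components: list[ScoringComponent]
    aggregation: str = "product"
    _w: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if not self.components:
            raise ValueError("at least one component required")
        if self.aggregation not in ("product", "sum"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        w = np.array([c.weight for c in self.components], dtype=float)
        self._w = w / w.sum()

    @property
    def weights(self) -> np.ndarray:
        """Normalized component weights (sum to 1)."""
        return self._w

    @property
    def descriptor_indices(self) -> np.ndarray:
        return np.array([c.descriptor for c in self.components], dtype=int)

    def score_descriptors(self, desc: np.ndarray):
        """Score from a descriptor vector (7,) or matrix (N, 7)."""
        desc = np.atleast_2d(np.asarray(desc, dtype=float))
        cols = desc[:, self.descriptor_indices]  # (N, K)
        low = np.array([c.params.low for c in self.components])
        high = np.array([c.params.high for c in self.components])
        a1 = np.array([c.params.alpha1 for c in self.components])
        a2 = np.array([c.params.alpha2 for c in self.components])
        phi = double_sigmoid_batch(cols, low, high, a1, a2)  # (N, K)
        if self.aggregation == "product":
            with np.errstate(divide="ignore"):
                logphi = np.log(phi)
            s = np.exp(np.sum(self._w * logphi, axis=1))
            s[np.any(phi == 0.0, axis=1)] = 0.0
        else:
            s = np.sum(self._w * phi, axis=1)
        return np.clip(s, 0.0, 1.0)

    def __call__(self, mol: Molecule) -> float:
        return float(self.score_descriptors(mol.descriptors)[0])

    def score_molecules(self, mols: list[Molecule]) -> np.ndarray:
        return self.score_descriptors(descriptor_matrix(mols))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "aggregation": self.aggregation,
            "components": [
                {
                    "name": c.name,
                    "descriptor": DESCRIPTOR_NAMES[c.descriptor],
                    "weight": float(c.weight),
                    "low": float(c.params.low),
                    "high": float(c.params.high),
                    "alpha1": float(c.params.alpha1),
                    "alpha2": float(c.params.alpha2),
                }
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MPOScoringFunction":
        comps = [
            ScoringComponent(
                descriptor=c["descriptor"],
                weight=c["weight"],
                params=DesirabilityParams(
                    c["low"], c["high"], c["alpha1"], c["alpha2"]
                ),
                name=c.get("name", ""),
            )
            for c in d["components"]
        ]
        return cls(components=comps, aggregation=d.get("aggregation", "product"))

    def with_intervals(self, low: np.ndarray, high: np.ndarray) -> "MPOScoringFunction":
        """Copy of this scoring function with new (LOW, HIGH) per component.

        Steepnesses, weights and aggregation are kept fixed — this is the
        update applied after each round of Task 1 inference.
        """
        comps = [
            ScoringComponent(
                descriptor=c.descriptor,
                weight=c.weight,
                params=DesirabilityParams(
                    float(lo), float(hi), c.params.alpha1, c.params.alpha2
                ),
                name=c.name,
            )
            for c, lo, hi in zip(self.components, low, high)
        ]
        return MPOScoringFunction(components=comps, aggregation=self.aggregation)


def score_molecule(mol: Molecule, scoring_function: MPOScoringFunction) -> float:
    """Score one molecule under an MPO scoring function."""
    return scoring_function(mol)
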