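"""Run configuration: schema-validated settings for elicitation experiments.

Configs are plain YAML/JSON documents validated with pydantic; unknown keys
are rejected so typos fail loudly before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .chem_io import DESCRIPTOR_NAMES
from .scoring import DesirabilityParams, MPOScoringFunction, ScoringComponent

LN10 = float(np.log(10.0))

#: Default initial desirability intervals theta_0: deliberately wide,
#: loosely-informative drug-like ranges per descriptor.
DEFAULT_THETA0: dict[str, tuple[float, float]] = {
    "MW": (100.0, 600.0),
    "SlogP": (-2.0, 6.0),
    "HBD": (0.0, 6.0),
    "HBA": (0.0, 11.0),
    "PSA": (0.0, 160.0),
    "RotatableBonds": (0.0, 11.0),
    "AromaticRings": (0.0, 5.0),
}


def steepness_for_width(width: float, edge_fraction: float = 0.05) -> float:
    """Fixed sigmoid steepness so one edge rises over ~edge_fraction of the
    prior interval width (5%-to-95% rise of the base-10 logistic)."""
    rise = 2.0 * np.log(19.0)  # logit span of the 5-95% rise
    return float(rise / (LN10 * edge_fraction * width))


class ComponentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    weight: float = Field(gt=0)
    low: float
    high: float
    alpha1: Optional[float] = Field(default=None, gt=0)
    alpha2: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if self.high <= self.low:
            raise ValueError(f"component {self.name}: high must exceed low")
        if self.name not in DESCRIPTOR_NAMES:
            raise ValueError(
                f"unknown descriptor {self.name!r}; choose from {DESCRIPTOR_NAMES}"
            )
        return self


class ScheduleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rounds: int = Field(default=1, ge=1)
    n_init: int = Field(default=10, ge=0)
    n_iterations: int = Field(default=10, ge=0)
    n_batch: int = Field(default=10, ge=1)

    @property
    def per_round_total(self) -> int:
        return self.n_init + self.n_iterations * self.n_batch

    @property
    def total_budget(self) -> int:
        return self.rounds * self.per_round_total


class OracleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["mqed", "synthetic_activity", "mpo", "external_model"] = "mqed"
    sigma_chemist: float = Field(default=0.0, ge=0)
    seed: int = 0
    # kind == "mpo": the simulated chemist's true intervals per component name
    theta_star: Optional[dict[str, tuple[float, float]]] = None


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["pool_resampler"] = "pool_resampler"
    library_size: int = Field(default=2000, ge=10)
    library_seed: int = 0
    temperature: float = Field(default=0.05, gt=0)
    score_threshold: float = Field(default=0.4, ge=0, le=1)
    n_eval: int = Field(default=1024, ge=1)


class SamplerBudget(BaseModel):
    model_config = ConfigDict(extra="forbid")

    nwalkers: int = Field(default=32, ge=4)
    nsteps: int = Field(default=250, ge=10)
    nburn: int = Field(default=250, ge=10)


class GPConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kernel: Literal["tanimoto", "squared_exponential"] = "tanimoto"
    sigma0: float = Field(default=0.1, gt=0)
    fp_radius: int = Field(default=3, ge=1)
    fp_nbits: int = Field(default=2048, ge=64)
    candidate_cap: int = Field(default=2000, ge=10)
    optimize_hyperparameters: bool = False
    feedback_scale: Literal["unit", "likert5"] = "unit"


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    task: Literal["task1", "task2"]
    seed: int = 0
    strategy: Literal["random", "uncertainty", "exploit", "thompson"] = "thompson"
    schedule: ScheduleConfig = ScheduleConfig()
    oracle: OracleConfig = OracleConfig()
    generator: GeneratorConfig = GeneratorConfig()
    components: Optional[list[ComponentConfig]] = None
    aggregation: Literal["product", "sum"] = "product"
    sampler: SamplerBudget = SamplerBudget()
    gp: GPConfig = GPConfig()

    @model_validator(mode="after")
    def _check(self):
        if self.task == "task1" and not self.components:
            object.__setattr__(self, "components", default_components())
        if self.task == "task2" and self.oracle.kind == "mqed":
            # mqed is fine for task2 too, but the default task2 oracle is the
            # synthetic activity model; no action needed here.
            pass
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def scoring_template(self) -> MPOScoringFunction:
        """Build the initial MPO scoring function (theta_0) from the config."""
        comps = []
        for c in self.components:
            width = c.high - c.low
            a = steepness_for_width(width)
            comps.append(
                ScoringComponent(
                    descriptor=c.name,
                    weight=c.weight,
                    params=DesirabilityParams(
                        c.low, c.high, c.alpha1 or a, c.alpha2 or a
                    ),
                    name=c.name,
                )
            )
        return MPOScoringFunction(components=comps, aggregation=self.aggregation)


def default_components() -> list[ComponentConfig]:
    """Equal-weight components over all 7 descriptors at theta_0."""
    return [
        ComponentConfig(name=name, weight=1.0 / len(DEFAULT_THETA0),
                        low=lo, high=hi)
        for name, (lo, hi) in DEFAULT_THETA0.items()
    ]


def default_task1_config(**overrides) -> RunConfig:
    """The Task 1 study protocol: 2 rounds of 10 init + 10 x 10 queries (220
    total), mQED simulated chemist, Thompson sampling."""
    base = dict(
        task="task1",
        strategy="thompson",
        schedule=ScheduleConfig(rounds=2, n_init=10, n_iterations=10, n_batch=10),
        oracle=OracleConfig(kind="mqed"),
    )
    base.update(overrides)
    return RunConfig(**base)


def default_task2_config(**overrides) -> RunConfig:
    """The Task 2 study protocol: 10 initial molecules then 200 queries in
    batches of 5 (40 iterations), synthetic activity oracle.

    The default pool is much larger than the query budget (3000 vs 210) so
    that query selection matters — the original protocol queries 200
    molecules out of a pool of hundreds of thousands.
    """
    base = dict(
        task="task2",
        strategy="thompson",
        schedule=ScheduleConfig(rounds=1, n_init=10, n_iterations=40, n_batch=5),
        oracle=OracleConfig(kind="synthetic_activity"),
        generator=GeneratorConfig(library_size=3000, temperature=0.02),
        gp=GPConfig(candidate_cap=1000),
    )
    base.update(overrides)
    return RunConfig(**base)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
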