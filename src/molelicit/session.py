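"""CSV-mediated Task 2 elicitation sessions.

Replaces a graphical feedback interface with a file round trip: the tool
exports the next query batch as a CSV, a chemist (or an oracle script) fills
in the ``label`` column, and the tool imports it back, refits the chemist's
component and saves the session state. Randomness is derived statelessly
from (seed, iteration), so a CSV-mediated session with oracle-generated
labels reproduces the fully simulated run exactly.

Feedback may be given on the unit scale [0, 1] or on a 1-5 scale
(config ``gp.feedback_scale: likert5``), which is mapped linearly by
(label - 1) / 4.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .acquisition import CandidatePool, Task2Belief, random_query, select_batch
from .config import RunConfig
from .gp import ContinuousFeedbackDataset, GPState, KernelSpec, gp_fit
from .hitl import _rng, make_oracle  # noqa: F401  (make_oracle re-exported for scripts)
from .library import generate_library


class SessionError(RuntimeError):
    pass


class Task2Session:
    """Resumable elicitation session backed by a JSON state file."""

    def __init__(self, config: RunConfig, records=None, pending=None, iteration=0):
        if config.task != "task2":
            raise SessionError("CSV-mediated sessions support task2 configs only")
        self.config = config
        self.records: list[tuple[str, float]] = list(records or [])
        self.pending: list[str] = list(pending or [])
        self.iteration = int(iteration)
        self._library = None

    # -- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": self.config.model_dump(),
            "iteration": self.iteration,
            "records": [{"smiles": s, "label": y} for s, y in self.records],
            "pending": self.pending,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "Task2Session":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            config=RunConfig(**d["config"]),
            records=[(r["smiles"], float(r["label"])) for r in d["records"]],
            pending=d.get("pending", []),
            iteration=d.get("iteration", 0),
        )

    # -- internals --------------------------------------------------------
    @property
    def library(self):
        if self._library is None:
            gen = self.config.generator
            self._library = generate_library(gen.library_size, gen.library_seed)
        return self._library

    def _smiles_to_mol(self):
        return {m.smiles: m for m in self.library}

    def fit_model(self) -> GPState:
        lookup = self._smiles_to_mol()
        mols = [lookup[s] for s, _ in self.records]
        D = ContinuousFeedbackDataset(mols, [y for _, y in self.records])
        cfg = self.config.gp
        kernel = KernelSpec(kind=cfg.kernel, fp_radius=cfg.fp_radius,
                            fp_nbits=cfg.fp_nbits)
        return gp_fit(D, kernel=kernel, sigma0=cfg.sigma0,
                      optimize=cfg.optimize_hyperparameters)

    def _pool(self) -> CandidatePool:
        used = {s for s, _ in self.records} | set(self.pending)
        pool = CandidatePool(list(self.library))
        drop = [i for i, m in enumerate(self.library) if m.smiles in used]
        if drop:
            pool.take(np.array(drop, dtype=int))
        return pool

    # -- protocol steps ---------------------------------------------------
    def export_batch(self, out_csv) -> pd.DataFrame:
        """Select the next batch and write it as a query CSV.

        Iteration 0 is the random initialization batch (D_0); later
        iterations use the configured strategy. The exported CSV has
        columns smiles, acquisition_score, strategy, iteration, label
        (label left empty for the human).
        """
        if self.pending:
            raise SessionError(
                "previous batch awaits feedback; import it before exporting"
            )
        cfg = self.config
        pool = self._pool()
        if self.iteration == 0:
            batch = random_query(pool, cfg.schedule.n_init, _rng(cfg.seed, 0))
            strategy, scores = "random_init", [float("nan")] * len(batch)
        else:
            if self.iteration > cfg.schedule.n_iterations:
                raise SessionError("query budget exhausted")
            state = self.fit_model()
            belief = Task2Belief(state, candidate_cap=cfg.gp.candidate_cap)
            batch = select_batch(
                pool, cfg.strategy, cfg.schedule.n_batch, belief,
                _rng(cfg.seed, 3, self.iteration),
            )
            strategy = cfg.strategy
            scores = [float(x) for x in belief.mean(state.kernel.features(batch))]
        df = pd.DataFrame({
            "smiles": [m.smiles for m in batch],
            "acquisition_score": scores,
            "strategy": strategy,
            "iteration": self.iteration,
            "label": ["" for _ in batch],
        })
        self.pending = [m.smiles for m in batch]
        if out_csv is not None:
            df.to_csv(out_csv, index=False)
        return df

    def import_feedback(self, in_csv) -> None:
        """Read back a labeled batch, rescale, append and advance."""
        df = pd.read_csv(in_csv)
        if "smiles" not in df.columns or "label" not in df.columns:
            raise SessionError("feedback CSV needs smiles and label columns")
        if not self.pending:
            raise SessionError("no exported batch awaiting feedback")
        pending = set(self.pending)
        seen = {}
        for smiles, label in zip(df["smiles"], df["label"]):
            smiles = str(smiles)
            if smiles not in pending:
                raise SessionError(f"molecule was never exported: {smiles}")
            if pd.isna(label) or label == "":
                raise SessionError(f"unlabeled row for {smiles}")
            seen[smiles] = self._rescale(float(label))
        missing = pending - set(seen)
        if missing:
            raise SessionError(f"missing labels for {sorted(missing)}")
        # preserve export order
        self.records.extend((s, seen[s]) for s in self.pending)
        self.pending = []
        self.iteration += 1

    def _rescale(self, label: float) -> float:
        if self.config.gp.feedback_scale == "likert5":
            if not 1.0 <= label <= 5.0:
                raise SessionError(f"1-5 scale label {label} outside [1, 5]")
            return (label - 1.0) / 4.0
        if not 0.0 <= label <= 1.0:
            raise SessionError(f"label {label} outside [0, 1]")
        return label
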