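"""Elicitation loops, generator stand-in and evaluation metrics."""

import json

import numpy as np
import pytest

from molelicit.config import (
    GeneratorConfig,
    GPConfig,
    OracleConfig,
    RunConfig,
    SamplerBudget,
    ScheduleConfig,
    default_task1_config,
    default_task2_config,
)
from molelicit.hitl import (
    InteractionSchedule,
    auec,
    average_oracle_score,
    mrae,
    pool_resampler_propose,
    run_task1,
    run_task2,
)
from molelicit.oracles import MQEDOracle


SMALL_T1 = dict(
    schedule=ScheduleConfig(rounds=1, n_init=5, n_iterations=2, n_batch=3),
    generator=GeneratorConfig(library_size=150, n_eval=64),
    sampler=SamplerBudget(nwalkers=30, nsteps=30, nburn=30),
)
SMALL_T2 = dict(
    schedule=ScheduleConfig(rounds=1, n_init=5, n_iterations=3, n_batch=4),
    generator=GeneratorConfig(library_size=150, n_eval=64),
    oracle=OracleConfig(kind="synthetic_activity"),
    gp=GPConfig(candidate_cap=100),
)


class TestSchedule:
    def test_totals(self):
        s = InteractionSchedule(rounds=2, n_init=10, n_iterations=10, n_batch=10)
        assert s.per_round_total == 110
        assert s.total_budget == 220

    def test_task2_default_budget(self):
        cfg = default_task2_config()
        assert cfg.schedule.n_iterations * cfg.schedule.n_batch == 200


class TestMetrics:
    def test_mrae_zero_at_truth(self):
        theta = (np.array([1.0, 2.0]), np.array([3.0, 5.0]))
        assert mrae(theta, theta) == 0.0

    def test_mrae_one_interval_width_off(self):
        true = (np.array([0.0]), np.array([10.0]))
        hat = (np.array([10.0]), np.array([20.0]))
        assert mrae(hat, true) == pytest.approx(1.0)

    def test_mrae_half_width_low_only(self):
        true = (np.array([0.0]), np.array([10.0]))
        hat = (np.array([5.0]), np.array([10.0]))
        assert mrae(hat, true) == pytest.approx(0.25)  # mean of {0.5, 0}

    def test_mrae_zero_width_rejected(self):
        with pytest.raises(ValueError):
            mrae((np.array([0.0]), np.array([1.0])), (np.array([2.0]), np.array([2.0])))

    def test_average_oracle_score(self, small_library):
        oracle = MQEDOracle()
        mols = small_library[:4]
        expected = np.mean([oracle.score(m) for m in mols])
        assert average_oracle_score(mols, oracle) == pytest.approx(expected)
        assert average_oracle_score(mols[::-1], oracle) == pytest.approx(expected)
        with pytest.raises(ValueError):
            average_oracle_score([], oracle)

    def test_auec_constant_curve(self):
        assert auec([0, 5, 10], [0.6, 0.6, 0.6]) == pytest.approx(0.6)

    def test_auec_linear_ramp(self):
        assert auec([0, 1], [0.0, 1.0]) == pytest.approx(0.5)

    def test_auec_monotone_curve_at_least_first_value(self):
        ys = [0.2, 0.3, 0.35, 0.6]
        assert auec([0, 1, 2, 3], ys) >= ys[0]
        with pytest.raises(ValueError):
            auec([0], [0.5])


class TestPoolResampler:
    def test_zero_temperature_limit_is_top_n(self, small_library):
        oracle = MQEDOracle()
        scores = oracle.score_many(small_library)
        top = pool_resampler_propose(
            small_library, None, 10, temperature=1e-6, seed=0, scores=scores
        )
        expected = {small_library[i].smiles for i in np.argsort(-scores)[:10]}
        assert {m.smiles for m in top} == expected

    def test_uniform_scores_sample_uniformly(self, small_library):
        lib = small_library[:20]
        counts = np.zeros(20)
        idx = {m.smiles: i for i, m in enumerate(lib)}
        scores = np.full(20, 0.5)
        for seed in range(3000):
            (m,) = pool_resampler_propose(lib, None, 1, 1.0, seed, scores=scores)
            counts[idx[m.smiles]] += 1
        p = counts / 3000
        assert np.all(np.abs(p - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 3000) + 1e-9)

    def test_reweighting_improves_mean_score(self, small_library):
        oracle = MQEDOracle()
        scores = oracle.score_many(small_library)
        lib_mean = scores.mean()
        idx = {m.smiles: i for i, m in enumerate(small_library)}
        prop_means = []
        for seed in range(10):
            props = pool_resampler_propose(
                small_library, None, 30, 0.05, seed, scores=scores
            )
            prop_means.append(np.mean([scores[idx[m.smiles]] for m in props]))
        assert np.mean(prop_means) >= lib_mean

    def test_validation(self, small_library):
        with pytest.raises(ValueError):
            pool_resampler_propose(small_library[:5], None, 10, 0.1, 0)
        with pytest.raises(ValueError):
            pool_resampler_propose(small_library, None, 5, -1.0, 0)


class TestRunTask1:
    def test_feedback_counts_match_schedule(self):
        cfg = default_task1_config(seed=0, **SMALL_T1)
        trace = run_task1(cfg)
        assert trace.n_feedback_total == cfg.schedule.total_budget == 11
        assert len(trace.entries) == cfg.schedule.rounds * (cfg.schedule.n_iterations + 1)

    def test_zero_iterations_only_init_queries(self):
        cfg = default_task1_config(
            seed=0,
            schedule=ScheduleConfig(rounds=1, n_init=5, n_iterations=0, n_batch=3),
            generator=SMALL_T1["generator"],
            sampler=SMALL_T1["sampler"],
        )
        trace = run_task1(cfg)
        assert trace.n_feedback_total == 5
        assert len(trace.entries) == 1

    def test_round_summaries_include_baseline(self):
        cfg = default_task1_config(seed=1, **SMALL_T1)
        trace = run_task1(cfg)
        assert [r["round"] for r in trace.rounds] == [0, 1]
        assert all(0 <= r["avg_oracle_score"] <= 1 for r in trace.rounds)

    def test_mrae_recorded_for_parametric_chemist(self):
        theta_star = {
            "MW": (250.0, 450.0), "SlogP": (0.0, 2.5), "HBD": (0.0, 3.0),
            "HBA": (1.0, 6.0), "PSA": (20.0, 90.0),
            "RotatableBonds": (0.0, 6.0), "AromaticRings": (1.0, 3.0),
        }
        cfg = default_task1_config(
            seed=0, oracle=OracleConfig(kind="mpo", theta_star=theta_star), **SMALL_T1
        )
        trace = run_task1(cfg)
        assert all("mrae" in e for e in trace.entries)
        assert all(e["mrae"] >= 0 for e in trace.entries)

    def test_null_adaptation_when_truth_equals_prior(self):
        """A chemist whose true intervals equal theta_0 induces no systematic
        drift: final MRAE stays within Monte-Carlo noise of initial."""
        from molelicit.config import DEFAULT_THETA0

        cfg = default_task1_config(
            seed=0,
            oracle=OracleConfig(kind="mpo", theta_star={
                k: v for k, v in DEFAULT_THETA0.items()
            }),
            schedule=ScheduleConfig(rounds=1, n_init=10, n_iterations=3, n_batch=10),
            generator=GeneratorConfig(library_size=400, n_eval=64),
            sampler=SamplerBudget(nwalkers=30, nsteps=60, nburn=60),
        )
        finals, initials = [], []
        for seed in range(3):
            trace = run_task1(cfg.model_copy(update={"seed": seed}))
            initials.append(trace.entries[0]["mrae"])
            finals.append(trace.entries[-1]["mrae"])
        # no drift: the final error stays small on the prior-width scale
        assert np.mean(finals) < 0.12

    def test_bit_reproducible(self, tmp_path):
        cfg = default_task1_config(seed=5, **SMALL_T1)
        paths = []
        for name in ("a.csv", "b.csv"):
            trace = run_task1(cfg)
            p = tmp_path / name
            trace.metrics_csv(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestRunTask2:
    def test_query_counts_match_schedule(self):
        cfg = default_task2_config(seed=0, **SMALL_T2)
        trace = run_task2(cfg)
        assert trace.entries[-1]["n_queries"] == 12
        assert trace.entries[-1]["n_train"] == 5 + 12
        assert len(trace.entries) == cfg.schedule.n_iterations + 1

    def test_zero_iterations_gives_initial_checkpoint_only(self):
        cfg = default_task2_config(
            seed=0,
            schedule=ScheduleConfig(rounds=1, n_init=5, n_iterations=0, n_batch=4),
            generator=SMALL_T2["generator"],
            oracle=SMALL_T2["oracle"],
            gp=SMALL_T2["gp"],
        )
        trace = run_task2(cfg)
        assert len(trace.entries) == 1
        assert trace.entries[0]["n_queries"] == 0

    def test_trace_json_roundtrip(self, tmp_path):
        cfg = default_task2_config(seed=0, **SMALL_T2)
        trace = run_task2(cfg)
        p = tmp_path / "trace.json"
        trace.to_json(p)
        loaded = json.loads(p.read_text())
        assert loaded["task"] == "task2"
        assert len(loaded["entries"]) == len(trace.entries)

    def test_final_component_exposed(self):
        cfg = default_task2_config(seed=0, **SMALL_T2)
        trace = run_task2(cfg)
        assert trace.gp_state.n_train == 17

    def test_bit_reproducible(self, tmp_path):
        cfg = default_task2_config(seed=9, **SMALL_T2)
        blobs = []
        for name in ("a.csv", "b.csv"):
            trace = run_task2(cfg)
            p = tmp_path / name
            trace.metrics_csv(p)
            blobs.append(p.read_bytes())
        assert blobs[0] == blobs[1]


class TestConfigValidation:
    def test_unknown_keys_rejected(self):
        with pytest.raises(Exception):
            RunConfig(task="task1", bogus_key=1)

    def test_negative_batch_rejected(self):
        with pytest.raises(Exception):
            ScheduleConfig(n_batch=-1)

    def test_task1_gets_default_components(self):
        cfg = default_task1_config()
        assert len(cfg.components) == 7
        sf = cfg.scoring_template()
        assert sf.weights.sum() == pytest.approx(1.0)
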