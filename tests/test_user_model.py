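"""Task 1 user model: likelihood, priors, MCMC posterior vs grid quadrature."""

import numpy as np
import pytest

from molelicit.scoring import (
    DesirabilityParams,
    MPOScoringFunction,
    ScoringComponent,
)
from molelicit.user_model import (
    BinaryFeedbackDataset,
    PosteriorSamples,
    PriorSpec,
    SamplerConfig,
    log_likelihood,
    log_prior,
    posterior_point_estimate,
    predictive_score,
    predictive_scores,
    sample_posterior,
)


def make_dataset(library, scoring_fn, n, seed):
    """Simulate binary feedback y ~ Bernoulli(S(x)) on random library picks."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(library), size=n, replace=False)
    mols = [library[i] for i in idx]
    p = scoring_fn.score_molecules(mols)
    return BinaryFeedbackDataset(mols, (rng.random(n) < p).astype(float))


def grid_posterior_means(D, prior, template, n_low=241, n_delta=301, span=5.0):
    """Dense grid quadrature of the (LOW, DELTA) posterior for K=1."""
    assert prior.n_components == 1
    s = float(prior.sigma[0])
    low0, high0 = float(prior.low0[0]), float(prior.high0[0])
    lows = np.linspace(low0 - span * s, low0 + span * s, n_low)
    deltas = np.linspace(1e-6, (high0 - low0) + 2 * span * s, n_delta)
    L, Dl = np.meshgrid(lows, deltas, indexing="ij")
    theta = np.column_stack([L.ravel(), Dl.ravel()])
    logp = log_prior(theta, prior) + np.atleast_1d(
        log_likelihood(D, theta, template)
    )
    w = np.exp(logp - logp.max())
    w /= w.sum()
    low_mean = float(w @ theta[:, 0])
    high_mean = float(w @ (theta[:, 0] + theta[:, 1]))
    low_sd = float(np.sqrt(w @ (theta[:, 0] - low_mean) ** 2))
    high_sd = float(np.sqrt(w @ (theta[:, 0] + theta[:, 1] - high_mean) ** 2))
    return (low_mean, high_mean), (low_sd, high_sd)


class TestLogLikelihood:
    def test_single_positive_record(self, small_library, mw_scoring_function):
        m = small_library[0]
        s = mw_scoring_function(m)
        D = BinaryFeedbackDataset([m], [1.0])
        theta = np.array([150.0, 200.0])  # the template's own interval
        assert log_likelihood(D, theta, mw_scoring_function) == pytest.approx(np.log(s))

    def test_mixed_records_multiply(self, small_library, mw_scoring_function):
        m1, m2 = small_library[0], small_library[1]
        s1, s2 = (mw_scoring_function(m) for m in (m1, m2))
        D = BinaryFeedbackDataset([m1, m2], [1.0, 0.0])
        theta = np.array([150.0, 200.0])
        assert log_likelihood(D, theta, mw_scoring_function) == pytest.approx(
            np.log(s1) + np.log(1 - s2)
        )

    def test_empty_dataset_is_zero(self, mw_scoring_function):
        D = BinaryFeedbackDataset()
        assert log_likelihood(D, np.array([150.0, 200.0]), mw_scoring_function) == 0.0

    def test_clamping_keeps_finite(self, small_library, mw_scoring_function):
        # an interval excluding the molecule entirely gives S ~ 0 for y=1
        D = BinaryFeedbackDataset([small_library[0]], [1.0])
        theta = np.array([1e4, 10.0])
        ll = log_likelihood(D, theta, mw_scoring_function)
        assert np.isfinite(ll)

    def test_nonbinary_labels_rejected(self, small_library):
        with pytest.raises(ValueError, match="binary"):
            BinaryFeedbackDataset([small_library[0]], [0.5])


class TestLogPrior:
    def test_one_eighth_rule(self):
        prior = PriorSpec(low0=[100.0], high0=[500.0])
        assert prior.sigma[0] == pytest.approx(50.0)

    def test_mode_at_prior_means(self):
        prior = PriorSpec(low0=[0.0], high0=[8.0])  # sigma = 1
        at_mean = log_prior(np.array([0.0, 8.0]), prior)
        # LOW at +1 sigma, DELTA reduced so HIGH (and its term) is unchanged
        shifted = log_prior(np.array([1.0, 7.0]), prior)
        assert at_mean - shifted == pytest.approx(0.5)

    def test_outside_support(self):
        prior = PriorSpec(low0=[0.0], high0=[8.0])
        assert log_prior(np.array([0.0, -1.0]), prior) == -np.inf

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(low0=[1.0], high0=[0.0])


class TestSamplePosterior:
    def test_prior_recovered_from_empty_data(self, mw_scoring_function):
        prior = PriorSpec(low0=[150.0], high0=[350.0])
        s = sample_posterior(
            BinaryFeedbackDataset(), prior, mw_scoring_function,
            SamplerConfig(nsteps=300, nburn=300), seed=0,
        )
        # the truncation at DELTA > 0 barely bites here (delta0/sd ~ 5.7)
        mcse_low = s.low.std() / np.sqrt(200)  # generous ESS guess
        assert abs(s.low.mean() - 150.0) < 3 * max(mcse_low, 1.0)
        assert abs(s.high.mean() - 350.0) < 3 * max(mcse_low, 1.5)
        assert np.all(s.delta > 0)
        assert s.n_draws >= 500

    def test_posterior_matches_grid_quadrature(self, small_library, mw_scoring_function):
        truth = MPOScoringFunction(
            [ScoringComponent("MW", 1.0, DesirabilityParams(200, 300, 0.05, 0.05))]
        )
        D = make_dataset(small_library, truth, 20, seed=0)
        prior = PriorSpec(low0=[150.0], high0=[350.0])
        (glow, ghigh), _ = grid_posterior_means(D, prior, mw_scoring_function)
        s = sample_posterior(D, prior, mw_scoring_function, SamplerConfig(), seed=1)
        low_hat, high_hat = posterior_point_estimate(s)
        tol = 0.05 * prior.sigma[0]
        assert abs(low_hat[0] - glow) < tol
        assert abs(high_hat[0] - ghigh) < tol

    def test_duplicated_data_shrinks_posterior(self, small_library, mw_scoring_function):
        truth = MPOScoringFunction(
            [ScoringComponent("MW", 1.0, DesirabilityParams(200, 300, 0.05, 0.05))]
        )
        D = make_dataset(small_library, truth, 15, seed=2)
        D2 = BinaryFeedbackDataset(
            D.molecules + D.molecules, np.concatenate([D.labels, D.labels])
        )
        prior = PriorSpec(low0=[150.0], high0=[350.0])
        _, (sd1_low, sd1_high) = grid_posterior_means(D, prior, mw_scoring_function)
        _, (sd2_low, sd2_high) = grid_posterior_means(D2, prior, mw_scoring_function)
        assert sd2_low <= sd1_low + 1e-9
        assert sd2_high <= sd1_high + 1e-9

    def test_seed_reproducible(self, small_library, mw_scoring_function):
        D = make_dataset(small_library, mw_scoring_function, 10, seed=3)
        prior = PriorSpec(low0=[150.0], high0=[350.0])
        cfg = SamplerConfig(nsteps=50, nburn=50)
        a = sample_posterior(D, prior, mw_scoring_function, cfg, seed=7)
        b = sample_posterior(D, prior, mw_scoring_function, cfg, seed=7)
        np.testing.assert_array_equal(a.low, b.low)
        np.testing.assert_array_equal(a.delta, b.delta)

    def test_uncertainty_decreases_with_feedback(self, small_library, mw_scoring_function):
        """Posterior spread narrows between 10 and 100 observations (>= 8/10 seeds)."""
        truth = MPOScoringFunction(
            [ScoringComponent("MW", 1.0, DesirabilityParams(200, 300, 0.05, 0.05))]
        )
        prior = PriorSpec(low0=[150.0], high0=[350.0])
        cfg = SamplerConfig(nsteps=150, nburn=150)
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(small_library), size=100, replace=True)
            mols = [small_library[i] for i in idx]
            p = truth.score_molecules(mols)
            y = (rng.random(100) < p).astype(float)
            sds = []
            for n in (10, 100):
                D = BinaryFeedbackDataset(mols[:n], y[:n])
                s = sample_posterior(D, prior, mw_scoring_function, cfg, seed=seed)
                sds.append(np.mean([s.low.std(), s.high.std()]))
            wins += sds[1] < sds[0]
        assert wins >= 8


class TestPointEstimateAndPredictive:
    def test_mean_of_draws(self):
        s = PosteriorSamples(
            low=np.array([[1.0], [2.0], [3.0]]), delta=np.array([[1.0], [1.0], [4.0]])
        )
        low_hat, high_hat = posterior_point_estimate(s)
        assert low_hat[0] == pytest.approx(2.0)
        assert high_hat[0] == pytest.approx(4.0)  # mean(LOW) + mean(DELTA)

    def test_single_draw_degenerate(self):
        s = PosteriorSamples(low=np.array([[5.0]]), delta=np.array([[2.0]]))
        assert posterior_point_estimate(s) == (pytest.approx([5.0]), pytest.approx([7.0]))

    def test_high_mean_linearity(self, rng):
        s = PosteriorSamples(low=rng.normal(0, 1, (50, 2)), delta=rng.random((50, 2)) + 0.1)
        _, high_hat = posterior_point_estimate(s)
        np.testing.assert_allclose(high_hat, s.high.mean(axis=0), atol=1e-12)

    def test_point_mass_posterior_equals_score(self, small_library, mw_scoring_function):
        m = small_library[0]
        s = PosteriorSamples(low=np.array([[150.0]]), delta=np.array([[200.0]]))
        assert predictive_score(m, s, mw_scoring_function) == pytest.approx(
            mw_scoring_function(m)
        )

    def test_two_draw_average(self, small_library, mw_scoring_function):
        m = small_library[0]
        s = PosteriorSamples(
            low=np.array([[150.0], [1000.0]]), delta=np.array([[200.0], [10.0]])
        )
        per_draw = [
            mw_scoring_function.with_intervals([lo], [hi])(m)
            for lo, hi in [(150.0, 350.0), (1000.0, 1010.0)]
        ]
        assert predictive_score(m, s, mw_scoring_function) == pytest.approx(
            np.mean(per_draw)
        )

    def test_predictive_in_unit_interval(self, small_library, mw_scoring_function, rng):
        s = PosteriorSamples(
            low=rng.normal(150, 25, (200, 1)), delta=rng.random((200, 1)) * 300 + 1
        )
        X = np.array([m.descriptors for m in small_library[:30]])
        p = predictive_scores(X, s, mw_scoring_function)
        assert np.all((p >= 0) & (p <= 1))

    def test_draws_export(self, tmp_path, rng):
        s = PosteriorSamples(low=rng.normal(0, 1, (20, 2)), delta=rng.random((20, 2)) + 0.1)
        out = tmp_path / "draws.csv"
        s.to_csv(out)
        import pandas as pd

        df = pd.read_csv(out)
        assert set(df.columns) == {"component", "parameter", "draw", "value"}
        assert len(df) == 20 * 2 * 2
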