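"""Unit and property tests for the generative observer model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import ndtr

from metanoise import (
    CohortSpec,
    DegenerateNoiseError,
    GenerativeParams,
    beta_shape_params,
    choice_probability,
    confidence_from_p,
    sample_confidence,
    sigma_for_accuracy,
    simulate_cohort,
    simulate_session,
)
from metanoise.measures import RatingCounts, discretize_confidence, type1_stats


class TestChoiceProbability:
    def test_symmetry_at_zero_percept(self):
        assert choice_probability(0.0, GenerativeParams(2.0, 1.3, 0.1)) == 0.5

    def test_direct_evaluation(self):
        p = choice_probability(0.5, GenerativeParams(1.0, 1.0, 0.1))
        assert p == pytest.approx(0.62246, abs=1e-5)

    def test_limits_and_monotonicity(self):
        params = GenerativeParams(1.0, 1.0, 0.1)
        percepts = np.linspace(-30, 30, 101)
        p = choice_probability(percepts, params)
        assert np.all(np.diff(p) > 0)
        assert p[0] == pytest.approx(0.0, abs=1e-12)
        assert p[-1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_sensory_noise_rejected(self):
        with pytest.raises(DegenerateNoiseError):
            choice_probability(0.5, GenerativeParams(1.0, 0.0, 0.1))


class TestConfidenceFromP:
    @pytest.mark.parametrize(
        "p, expected", [(0.5, 0.0), (1.0, 1.0), (0.0, 1.0), (0.25, 0.5), (0.75, 0.5)]
    )
    def test_folding(self, p, expected):
        assert confidence_from_p(p) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0))
    def test_choice_independence_symmetry(self, p):
        assert confidence_from_p(p) == pytest.approx(confidence_from_p(1.0 - p))


class TestBetaShapes:
    def test_uniform_limit_at_half(self):
        alpha, beta = beta_shape_params(0.37, 0.5)
        assert (alpha, beta) == (1.0, 1.0)

    def test_direct_evaluation_and_mode(self):
        alpha, beta = beta_shape_params(0.7, 0.1)
        assert (alpha, beta) == pytest.approx((6.6, 3.4))
        assert (alpha - 1) / (alpha + beta - 2) == pytest.approx(0.7)

    def test_boundary_mode(self):
        alpha, beta = beta_shape_params(0.0, 0.1)
        assert (alpha, beta) == pytest.approx((1.0, 9.0))

    @pytest.mark.parametrize("sigma_m", [0.0, -0.1, 0.51])
    def test_invalid_spread_rejected(self, sigma_m):
        with pytest.raises(ValueError):
            beta_shape_params(0.5, sigma_m)

    def test_mode_identity_on_lattice(self):
        """(alpha-1)/(alpha+beta-2) == c to machine precision on a (c, sigma_m) grid."""
        for c in np.linspace(0, 1, 21):
            for sm in np.linspace(0.01, 0.49, 13):
                alpha, beta = beta_shape_params(c, sm)
                assert (alpha - 1) / (alpha + beta - 2) == pytest.approx(c, abs=1e-14)

    def test_spread_monotone_in_sigma_m(self):
        """E[(X - c)^2] of the report distribution grows with sigma_m at fixed c."""
        for c in (0.2, 0.5, 0.8):
            spreads = []
            for sm in np.linspace(0.05, 0.5, 10):
                alpha, beta = beta_shape_params(c, sm)
                mean = alpha / (alpha + beta)
                var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1))
                spreads.append(var + (mean - c) ** 2)
            assert np.all(np.diff(spreads) > 0)


class TestSampleConfidence:
    def test_noiseless_passthrough(self):
        rng = np.random.default_rng(0)
        out = sample_confidence(np.array([0.3, 0.9]), 0.0, rng)
        assert np.array_equal(out, [0.3, 0.9])

    def test_uniform_at_max_spread(self):
        rng = np.random.default_rng(1)
        draws = sample_confidence(np.full(100_000, 0.7), 0.5, rng)
        assert stats.kstest(draws, "uniform").pvalue > 0.01

    def test_empirical_mode_matches_c(self):
        rng = np.random.default_rng(2)
        draws = sample_confidence(np.full(1_000_000, 0.7), 0.1, rng)
        hist, edges = np.histogram(draws, bins=200, range=(0, 1))
        mode = (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2
        assert mode == pytest.approx(0.7, abs=0.02)


class TestSigmaForAccuracy:
    @pytest.mark.parametrize(
        "target, expected", [(0.6, 1.9737), (0.9, 0.3901)]
    )
    def test_closed_form(self, target, expected):
        assert sigma_for_accuracy(target, 1.0) == pytest.approx(expected, abs=2e-4)

    def test_noise_vanishes_near_perfect_accuracy(self):
        assert sigma_for_accuracy(0.9999) < sigma_for_accuracy(0.99) < 0.25

    @pytest.mark.parametrize("target", [0.5, 0.4, 1.0, 1.2])
    def test_invalid_targets_rejected(self, target):
        with pytest.raises(ValueError):
            sigma_for_accuracy(target)

    def test_monte_carlo_accuracy_at_target(self):
        rng = np.random.default_rng(3)
        for target in (0.6, 0.9):
            params = GenerativeParams(1.0, sigma_for_accuracy(target), 0.1)
            trials = simulate_session(params, 100_000, rng)
            assert trials["correct"].mean() == pytest.approx(target, abs=0.005)


class TestSimulateSession:
    def test_noiseless_observer_is_always_right_and_certain(self):
        params = GenerativeParams(1.0, 0.0, 0.0)
        trials = simulate_session(params, 500, np.random.default_rng(4))
        assert trials["correct"].all()
        assert np.array_equal(trials["confidence"], np.ones(500))

    def test_accuracy_matches_closed_form_across_noise_levels(self):
        rng = np.random.default_rng(5)
        for sigma_s in (0.5, 1.0, 2.0, 4.0):
            params = GenerativeParams(1.0, sigma_s, 0.2)
            trials = simulate_session(params, 100_000, rng)
            expected = ndtr(1.0 / (2.0 * sigma_s))
            assert trials["correct"].mean() == pytest.approx(expected, abs=0.01)

    def test_dprime_recovery(self):
        """Type 1 d' estimated from simulated counts converges to mu/sigma_s."""
        rng = np.random.default_rng(6)
        params = GenerativeParams(1.0, 0.8, 0.1)
        trials = simulate_session(params, 100_000, rng)
        ratings = discretize_confidence(trials["confidence"].to_numpy(), 6)
        counts = RatingCounts.from_trials(trials["stimulus"], trials["choice"], ratings)
        assert type1_stats(counts).d_prime == pytest.approx(1.0 / 0.8, abs=0.05)

    def test_deterministic_under_fixed_seed(self):
        params = GenerativeParams(1.0, 1.5, 0.3)
        a = simulate_session(params, 200, np.random.default_rng(7))
        b = simulate_session(params, 200, np.random.default_rng(7))
        assert a.equals(b)

    def test_confidence_invariant_under_stimulus_relabeling(self):
        """Relabeling the two categories turns each choice probability p
        into 1 - p but leaves the confidence stream identical under the
        same seed (choice independence of confidence)."""
        params = GenerativeParams(1.0, 1.0, 0.2)
        trials = simulate_session(params, 300, np.random.default_rng(8))
        p = choice_probability(trials["percept"].to_numpy(), params)
        conf_orig = sample_confidence(
            confidence_from_p(p), 0.2, np.random.default_rng(9))
        conf_flip = sample_confidence(
            confidence_from_p(1.0 - p), 0.2, np.random.default_rng(9))
        # identical up to 1-ulp folding error in |2p - 1| vs |1 - 2p|
        assert np.allclose(conf_orig, conf_flip, atol=1e-9, rtol=0)


class TestCohorts:
    def test_shape_contract(self):
        spec = CohortSpec(n_subjects=5, n_trials=40, n_sessions=2,
                          sigma_m=0.2, target_accuracy=0.75, seed=10)
        cohort = simulate_cohort(spec)
        assert len(cohort.trials) == 5 * 2 * 40
        assert set(cohort.trials["Session"]) == {0, 1}
        assert len(cohort.subjects) == 5
        sess = cohort.session(3, 1)
        assert len(sess) == 40
        assert (sess["correct"] == (sess["stimulus"] == sess["choice"])).all()

    def test_uniform_sigma_m_spans_range_and_is_fixed_per_subject(self):
        spec = CohortSpec(n_subjects=100, n_trials=2, sigma_m="uniform",
                          target_accuracy=0.75, seed=11)
        cohort = simulate_cohort(spec)
        sm = cohort.subjects["sigma_m"]
        assert sm.min() < 0.05 and sm.max() > 0.45
        assert sm.between(0, 0.5).all()

    def test_seeding_contract(self):
        spec = dict(n_subjects=4, n_trials=30, sigma_m="uniform",
                    target_accuracy=0.7)
        a = simulate_cohort(CohortSpec(**spec, seed=1))
        b = simulate_cohort(CohortSpec(**spec, seed=1))
        c = simulate_cohort(CohortSpec(**spec, seed=2))
        assert a.trials.equals(b.trials)
        assert not a.trials.equals(c.trials)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=2, n_trials=10, target_accuracy=0.5)
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=2, n_trials=10)  # neither accuracy nor sigma_s
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=2, n_trials=10, target_accuracy=0.7,
                       sigma_s=1.0)  # both


class TestGenerativeParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(mu=0.0), dict(mu=-1.0), dict(sigma_s=-0.1),
                   dict(sigma_m=0.51), dict(sigma_m=-0.01)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenerativeParams(**{**dict(mu=1.0, sigma_s=1.0, sigma_m=0.1), **kwargs})

    def test_expected_accuracy(self):
        assert GenerativeParams(1.0, 0.0, 0.0).expected_accuracy == 1.0
        p = GenerativeParams(1.0, sigma_for_accuracy(0.8), 0.0)
        assert p.expected_accuracy == pytest.approx(0.8, abs=1e-12)
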