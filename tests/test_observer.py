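"""The Gaussian recursive observer: fusion algebra, shrinkage, responses."""

import numpy as np
import pytest
from scipy.stats import norm

from tempreg.design import TrialCondition, realize_sequence
from tempreg.observer import (
    BeliefState,
    ObserverParams,
    advance,
    fuse,
    init_belief,
    perceive_final,
    predicted_sd_at_final,
    respond_regular,
    respond_toj,
    shrinkage_weight,
    simulate_session,
    update_environment,
)
from tempreg.design import build_exp1_grid, build_exp2_grid, shuffle_grid


class TestBeliefAlgebra:
    def test_init_centers_one_interval_ahead(self, default_params):
        state = init_belief(0.0, default_params)
        assert state.predicted_onset_mean == 700.0
        assert state.predicted_onset_sd == default_params.initial_prior_sd
        state = init_belief(100.0, default_params)
        assert state.predicted_onset_mean == 800.0

    def test_flat_prior_fusion_returns_observation(self, default_params):
        state = BeliefState(2800.0, 1e9, 700.0)
        mean, _ = fuse(state, 2760.0, default_params)
        assert mean == pytest.approx(2760.0, abs=1e-3)

    def test_equal_precision_fusion_is_midpoint(self):
        params = ObserverParams(sensory_sd=25.0)
        state = BeliefState(2800.0, 25.0, 700.0)
        mean, sd = fuse(state, 2760.0, params)
        assert mean == pytest.approx(2780.0)
        assert sd == pytest.approx(25.0 / np.sqrt(2.0))

    def test_degenerate_limits(self):
        sharp_prior = BeliefState(2800.0, 0.0, 700.0)
        assert fuse(sharp_prior, 2700.0, ObserverParams())[0] == 2800.0
        sharp_sense = ObserverParams(sensory_sd=0.0)
        assert fuse(BeliefState(2800.0, 30.0, 700.0), 2700.0, sharp_sense)[0] == 2700.0
        with pytest.raises(ValueError):
            fuse(sharp_prior, 2700.0, sharp_sense)

    def test_fusion_lies_between_prior_and_observation(self, rng):
        params = ObserverParams(sensory_sd=17.0)
        for _ in range(50):
            m, sp, x = rng.normal(2800, 100), rng.uniform(1, 200), rng.normal(2800, 100)
            mean, _ = fuse(BeliefState(m, sp, 700.0), x, params)
            assert min(m, x) - 1e-9 <= mean <= max(m, x) + 1e-9

    def test_advance_adds_interval_and_grows_uncertainty(self, default_params):
        state = BeliefState(0.0, 50.0, 700.0)
        nxt = advance(state, 2100.0, 10.0, default_params, interval_sd=0.0)
        assert nxt.predicted_onset_mean == 2800.0
        assert nxt.predicted_onset_sd == 10.0
        nxt = advance(state, 2100.0, 40.0, default_params, interval_sd=30.0)
        assert nxt.predicted_onset_sd == pytest.approx(50.0)

    def test_posterior_sd_non_increasing_without_interval_noise(self):
        params = ObserverParams(sensory_sd=20.0, interval_sd=0.0,
                                initial_prior_sd=100.0)
        sd = params.initial_prior_sd
        for _ in range(5):
            _, post_sd = fuse(BeliefState(0.0, sd, 700.0), 0.0, params)
            assert post_sd <= sd
            sd = advance(BeliefState(0.0, sd, 700.0), 0.0, post_sd,
                         params, interval_sd=0.0).predicted_onset_sd


class TestEnvironmentLearning:
    def test_zero_rate_is_identity(self, default_params):
        assert update_environment(default_params, [50.0, -30.0]) == default_params

    def test_full_rate_replaces_with_rms(self):
        params = ObserverParams(env_learning_rate=1.0, interval_sd=7.0)
        updated = update_environment(params, [100.0, -100.0, 100.0])
        assert updated.interval_sd == pytest.approx(100.0)

    def test_half_rate_moves_halfway(self):
        params = ObserverParams(env_learning_rate=0.5, interval_sd=0.0)
        updated = update_environment(params, [100.0])
        assert updated.interval_sd == pytest.approx(50.0)


class TestShrinkage:
    def test_flat_prior_no_noise_percept_is_veridical(self):
        params = ObserverParams(sensory_sd=0.0, initial_prior_sd=1e9,
                                interval_sd=1e9)
        cond = TrialCondition("exp1", "regular", 0.0, -40.0, None, 0)
        seq = realize_sequence(cond, rng=0)
        aniso, onset = perceive_final(seq, params, rng=0)
        assert aniso == pytest.approx(-40.0)
        assert onset == pytest.approx(2760.0)

    def test_sharp_prior_fully_regularises(self):
        params = ObserverParams(sensory_sd=1e6, initial_prior_sd=1.0,
                                interval_sd=0.0)
        cond = TrialCondition("exp1", "regular", 0.0, -40.0, None, 0)
        seq = realize_sequence(cond, rng=0)
        aniso, _ = perceive_final(seq, params, rng=0)
        assert abs(aniso) < 0.1

    def test_monte_carlo_mean_matches_closed_form_w_times_a(self):
        # E[perceived anisochrony] = w*a, w = sp^2/(sp^2+ss^2) at final fusion
        params = ObserverParams(sensory_sd=20.0, initial_prior_sd=150.0,
                                interval_sd=30.0)
        cond = TrialCondition("exp1", "regular", 0.0, -40.0, None, 0)
        seq = realize_sequence(cond, rng=0)
        rng = np.random.default_rng(77)
        draws = np.array(
            [perceive_final(seq, params, rng)[0] for _ in range(10_000)]
        )
        w = shrinkage_weight(params)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - w * (-40.0)) < 3.0 * se
        assert -40.0 < draws.mean() < 0.0

    def test_shrinkage_monotone_in_prior_precision(self):
        # sharper environment statistics never weaken regularisation
        weights = [
            shrinkage_weight(ObserverParams(interval_sd=isd))
            for isd in (0.0, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0)
        ]
        assert all(a <= b for a, b in zip(weights, weights[1:]))

    def test_predicted_sd_closed_form_example(self):
        params = ObserverParams(sensory_sd=20.0, initial_prior_sd=1e9,
                                interval_sd=0.0)
        # flat start: after observing tones 2-4 the prediction sd is the
        # sensory sd shrunk by repeated fusion: 20/sqrt(1), /sqrt(2), ...
        sd = predicted_sd_at_final(params)
        assert sd == pytest.approx(20.0 / np.sqrt(3.0), rel=1e-6)


class TestResponses:
    def test_regular_between_sharp_criteria(self, rng):
        params = ObserverParams(criterion_sd_early=1e-9, criterion_sd_late=1e-9,
                                lapse_rate=0.0)
        assert respond_regular(0.0, params, rng) == "regular"
        assert respond_regular(-200.0, params, rng) == "irregular"
        assert respond_regular(200.0, params, rng) == "irregular"

    def test_regular_probability_matches_analytic_curve(self):
        params = ObserverParams(criterion_early=-100.0, criterion_late=100.0,
                                criterion_sd_early=30.0, criterion_sd_late=30.0,
                                lapse_rate=0.0)
        rng = np.random.default_rng(4)
        n = 100_000
        for x in (-120.0, -80.0, 0.0, 90.0):
            hits = sum(
                respond_regular(x, params, rng) == "regular" for _ in range(n)
            )
            analytic = norm.cdf((x + 100.0) / 30.0) - norm.cdf((x - 100.0) / 30.0)
            assert hits / n == pytest.approx(analytic, abs=4.0 * np.sqrt(0.25 / n))

    def test_toj_order_and_tie_rule(self, rng, noiseless_toj_params):
        assert respond_toj(2800.0, 2900.0, noiseless_toj_params, rng) == "sound_first"
        assert respond_toj(2800.0, 2700.0, noiseless_toj_params, rng) == "light_first"
        assert respond_toj(2800.0, 2800.0, noiseless_toj_params, rng) == "light_first"

    def test_toj_light_first_rate_decreases_with_soa(self):
        params = ObserverParams(visual_latency_sd=40.0, lapse_rate=0.0)
        rng = np.random.default_rng(8)
        rates = []
        for soa in (-80.0, -40.0, 0.0, 40.0, 80.0):
            hits = sum(
                respond_toj(2800.0, 2800.0 + soa, params, rng) == "light_first"
                for _ in range(20_000)
            )
            rates.append(hits / 20_000)
        assert all(a >= b for a, b in zip(rates, rates[1:]))
        assert rates[0] > 0.9 and rates[-1] < 0.1

    def test_lapses_flip_responses(self):
        params = ObserverParams(criterion_sd_early=1e-9, criterion_sd_late=1e-9,
                                lapse_rate=0.5)
        rng = np.random.default_rng(0)
        hits = sum(
            respond_regular(0.0, params, rng) == "regular" for _ in range(20_000)
        )
        assert hits / 20_000 == pytest.approx(0.5, abs=0.02)


class TestSession:
    def test_same_seed_identical_tables(self, default_params):
        grid = shuffle_grid(build_exp2_grid("regular", 1), 5)
        a = simulate_session(grid, default_params, seed=9)
        b = simulate_session(grid, default_params, seed=9)
        assert a.equals(b)

    def test_row_count_matches_grid(self, default_params):
        grid = build_exp1_grid("regular", 8)
        table = simulate_session(grid, default_params, seed=1)
        assert len(table) == 480
        assert set(table["response"]) <= {"regular", "irregular"}

    def test_empty_grid_rejected(self, default_params):
        with pytest.raises(ValueError):
            simulate_session([], default_params, seed=0)

    def test_learning_broadens_prior_in_irregular_environment(self):
        """After an irregular session the learned interval statistics make the
        sensory weight approach 1; a regular session keeps it well below."""
        params = ObserverParams(env_learning_rate=0.2)
        percepts = {}
        for env in ("regular", "irregular"):
            grid = shuffle_grid(build_exp1_grid(env, 4), 3)
            table = simulate_session(grid, params, seed=13)
            # shrinkage visible in perceived anisochrony of late trials at
            # jitter 0, anisochrony ±200 (largest deviants)
            tail = table.iloc[len(table) // 2:]
            cell = tail[(tail["jitter_level_ms"] == 0.0)
                        & (tail["anisochrony_ms"].abs() == 200.0)]
            percepts[env] = (
                cell["perceived_anisochrony_ms"].abs().mean()
                / cell["anisochrony_ms"].abs().mean()
            )
        assert percepts["irregular"] > 0.8
        assert percepts["regular"] < percepts["irregular"]
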