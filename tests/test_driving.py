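"""Lane-keeping dynamics, learned transition model and belief filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multidrive.driving import (
    ConfigurationError,
    DrivingEnv,
    DrivingParams,
    DrivingState,
    TransitionModel,
    belief_correct,
    belief_predict,
    belief_state_key,
    belief_summary,
    driving_reward,
    initial_belief,
    learn_transition_model,
    sample_observation,
    simulate_step,
)


class TestSimulateStep:
    def test_noop_dynamics(self, clean_driving_params, rng):
        state = DrivingState(0.4, 0.0, 60.0)
        nxt = simulate_step(state, 0.0, clean_driving_params, rng)
        assert nxt.lateral_offset_m == pytest.approx(0.4)
        assert nxt.steering == 0.0

    @pytest.mark.parametrize("wheel", [0.01, 0.03, -0.01, 0.1])
    def test_update_rule(self, clean_driving_params, rng, wheel):
        # 60 km/h = 16.667 m/s over a 0.25 s cycle
        state = DrivingState(0.0, 0.0, 60.0)
        nxt = simulate_step(state, wheel, clean_driving_params, rng)
        assert nxt.lateral_offset_m == pytest.approx(16.6667 * 0.25 * wheel, rel=1e-4)
        assert nxt.steering == wheel

    def test_seeded_determinism(self):
        params = DrivingParams()
        traj = []
        for _ in range(2):
            rng = np.random.default_rng(3)
            s = DrivingState(0.0, 0.0, 60.0)
            path = []
            for _ in range(50):
                s = simulate_step(s, 0.01, params, rng)
                path.append(s.lateral_offset_m)
            traj.append(path)
        assert traj[0] == traj[1]

    def test_invalid_action_rejected(self, clean_driving_params, rng):
        with pytest.raises(ConfigurationError):
            simulate_step(DrivingState(0, 0, 60), 0.123, clean_driving_params, rng)

    def test_road_edge_clamps_offset(self, clean_driving_params, rng):
        state = DrivingState(3.4, 0.0, 60.0)
        for _ in range(10):
            state = simulate_step(state, 0.1, clean_driving_params, rng)
        assert state.lateral_offset_m == pytest.approx(
            clean_driving_params.offset_range_m
        )

    def test_speed_scales_displacement(self, rng):
        slow = DrivingParams(speed_kmh=60, sigma_d=0.0, curvature_drift_mps=0.0)
        fast = DrivingParams(speed_kmh=120, sigma_d=0.0, curvature_drift_mps=0.0)
        d_slow = simulate_step(
            DrivingState(0.0, 0.0, 60.0), 0.01, slow, rng
        ).lateral_offset_m
        d_fast = simulate_step(
            DrivingState(0.0, 0.0, 120.0), 0.01, fast, rng
        ).lateral_offset_m
        assert d_fast == pytest.approx(2 * d_slow)

    def test_partial_durations_compose_in_mean(self, clean_driving_params, rng):
        full = simulate_step(
            DrivingState(0.0, 0.0, 60.0), 0.03, clean_driving_params, rng
        )
        half = simulate_step(
            DrivingState(0.0, 0.0, 60.0), 0.03, clean_driving_params, rng,
            duration=0.125,
        )
        half2 = simulate_step(half, 0.03, clean_driving_params, rng, duration=0.125)
        assert half2.lateral_offset_m == pytest.approx(full.lateral_offset_m)


class TestParamsValidation:
    def test_even_bins_rejected(self):
        with pytest.raises(ConfigurationError):
            DrivingParams(n_position_bins=20)

    def test_noop_required(self):
        with pytest.raises(ConfigurationError):
            DrivingParams(action_set=(-0.01, 0.01))

    def test_obs_probability_range(self):
        with pytest.raises(ConfigurationError):
            DrivingParams(p_obs_correct=0.0)
        with pytest.raises(ConfigurationError):
            DrivingParams(p_obs_correct=1.2)

    def test_deviation_bound_accounts_for_car_width(self):
        assert DrivingParams().deviation_bound == pytest.approx(0.85)
        assert DrivingParams(car_width_m=0.0).deviation_bound == pytest.approx(1.75)


class TestLearnTransitionModel:
    def test_deterministic_rows_are_point_masses(self, clean_driving_params, rng):
        p = clean_driving_params
        model = learn_transition_model(p, 20_000, rng)
        visited = np.argwhere(model.counts.sum(axis=2) > 0)
        assert len(visited) > 50
        for from_bin, a_idx in visited:
            expected = p.discretize(
                p.bin_centers[from_bin]
                + p.speed_mps * p.dt_drive_s * p.action_set[a_idx]
            )
            row = model.prob(int(from_bin), int(a_idx))
            assert row[expected] == pytest.approx(1.0)

    def test_all_rows_stochastic(self, rng):
        p = DrivingParams()
        model = learn_transition_model(p, 3_000, rng)
        for a in range(p.n_actions):
            sums = model.matrix(a).sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_conditional_moments_match_generator(self, rng):
        # hold the wheel centered: the spread is the execution noise alone
        p = DrivingParams(
            speed_kmh=60.0,
            sigma_d=0.12,
            curvature_drift_mps=0.0,
            action_set=(0.0,),
        )
        model = learn_transition_model(p, 150_000, rng)
        lateral_sd = p.speed_mps * p.dt_drive_s * p.sigma_d  # meters per cycle
        expected_var = (lateral_sd / p.bin_width) ** 2 + 1 / 12  # + discretization
        center = p.n_position_bins // 2
        for from_bin in range(center - 3, center + 4):
            row = model.prob(from_bin, 0)
            bins = np.arange(p.n_position_bins)
            mean = (bins * row).sum()
            var = ((bins - mean) ** 2 * row).sum()
            assert var == pytest.approx(expected_var, rel=0.15)

    def test_rollout_count_validated(self, clean_driving_params, rng):
        with pytest.raises(ConfigurationError):
            learn_transition_model(clean_driving_params, 0, rng)

    def test_csv_roundtrip(self, tmp_path, rng):
        p = DrivingParams()
        model = learn_transition_model(p, 3_000, rng)
        path = tmp_path / "tau.csv"
        model.to_csv(path)
        back = TransitionModel.from_csv(path, p)
        for a in range(p.n_actions):
            np.testing.assert_allclose(back.matrix(a), model.matrix(a), atol=1e-12)


def _diffusion_model(params: DrivingParams) -> TransitionModel:
    """Unvisited model: every row is the identity-plus-diffusion fallback,
    which is doubly stochastic (edge rows keep the lost mass)."""
    return TransitionModel(params)


class TestBeliefPredict:
    def test_point_mass_through_deterministic_tau(self, clean_driving_params, rng):
        p = clean_driving_params
        model = learn_transition_model(p, 30_000, rng)
        b = initial_belief(p, at_bin=10)
        a_idx = p.action_index(0.03)
        pred = belief_predict(b, a_idx, model)
        expected_bin = p.discretize(
            p.bin_centers[10] + p.speed_mps * p.dt_drive_s * 0.03
        )
        assert pred[expected_bin] == pytest.approx(1.0)

    def test_uniform_invariant_under_doubly_stochastic_tau(self):
        p = DrivingParams()
        model = _diffusion_model(p)
        uniform = np.full(p.n_position_bins, 1.0 / p.n_position_bins)
        pred = belief_predict(uniform, 0, model)
        np.testing.assert_allclose(pred, uniform, atol=1e-12)

    def test_matches_matrix_vector_oracle(self, rng):
        p = DrivingParams()
        model = learn_transition_model(p, 20_000, rng)
        for _ in range(50):
            b = rng.dirichlet(np.ones(p.n_position_bins))
            a_idx = int(rng.integers(p.n_actions))
            mat = model.matrix(a_idx)
            oracle = np.array(
                [
                    sum(mat[i, j] * b[i] for i in range(p.n_position_bins))
                    for j in range(p.n_position_bins)
                ]
            )
            np.testing.assert_allclose(
                belief_predict(b, a_idx, model), oracle, atol=1e-10
            )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_output_is_distribution(self, seed):
        p = DrivingParams()
        model = _diffusion_model(p)
        rng = np.random.default_rng(seed)
        b = rng.dirichlet(np.ones(p.n_position_bins))
        pred = belief_predict(b, int(rng.integers(p.n_actions)), model)
        assert pred.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(pred >= 0)

    def test_entropy_nondecreasing_under_diffusion(self, rng):
        p = DrivingParams()
        model = _diffusion_model(p)
        b = rng.dirichlet(np.ones(p.n_position_bins))
        for _ in range(30):
            nxt = belief_predict(b, 0, model)
            assert belief_summary(nxt).entropy >= belief_summary(b).entropy - 1e-12
            b = nxt


class TestBeliefCorrect:
    def test_perfect_observation(self):
        p = DrivingParams(p_obs_correct=1.0)
        post = belief_correct(np.full(21, 1 / 21), 4, p)
        assert post[4] == pytest.approx(1.0)

    def test_uninformative_likelihood(self):
        p = DrivingParams(n_position_bins=21, p_obs_correct=1 / 21)
        predicted = np.random.default_rng(0).dirichlet(np.ones(21))
        post = belief_correct(predicted, 7, p)
        np.testing.assert_allclose(post, predicted, atol=1e-12)

    def test_two_bin_bayes_by_hand(self):
        # two-bin space, flat prior, 0.9-correct channel:
        # posterior ∝ [0.9*0.5, 0.1*0.5] -> [0.9, 0.1]
        from types import SimpleNamespace

        p2 = SimpleNamespace(n_position_bins=2, p_obs_correct=0.9)
        post = belief_correct(np.array([0.5, 0.5]), 0, p2)
        np.testing.assert_allclose(post, [0.9, 0.1], atol=1e-12)

    def test_zero_normalizer_resets_to_likelihood(self):
        p = DrivingParams(n_position_bins=5, p_obs_correct=1.0)
        degenerate = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        post = belief_correct(degenerate, 3, p)  # impossible under the belief
        assert post[3] == pytest.approx(1.0)

    def test_observation_range_checked(self):
        p = DrivingParams()
        with pytest.raises(ConfigurationError):
            belief_correct(np.full(21, 1 / 21), 21, p)


class TestBeliefSummary:
    def test_point_mass(self):
        b = np.zeros(8)
        b[5] = 1.0
        s = belief_summary(b)
        assert s.map_position == 5 and s.entropy == pytest.approx(0.0, abs=1e-12)

    def test_uniform_ten_bins(self):
        s = belief_summary(np.full(10, 0.1))
        assert s.entropy == pytest.approx(np.log(10), abs=1e-9)
        assert s.entropy == pytest.approx(2.3026, abs=1e-4)

    def test_tie_breaks_to_lowest_index(self):
        s = belief_summary(np.array([0.5, 0.5]))
        assert s.map_position == 0
        assert s.entropy == pytest.approx(np.log(2), abs=1e-9)


class TestDrivingReward:
    def test_zero_inside_lane(self, clean_driving_params):
        assert (
            driving_reward(DrivingState(0.0, 0, 60), clean_driving_params, 0.25)
            == 0.0
        )

    def test_boundary_is_safe(self, clean_driving_params):
        # closed interval: exactly on the bound earns no penalty
        state = DrivingState(clean_driving_params.deviation_bound, 0, 60)
        assert driving_reward(state, clean_driving_params, 0.25) == 0.0

    def test_penalty_proportional_to_duration(self):
        p = DrivingParams(car_width_m=0.0, penalty_rate=1.0)
        assert driving_reward(DrivingState(2.0, 0, 60), p, 0.25) == pytest.approx(
            -0.25
        )

    def test_duration_validated(self, clean_driving_params):
        with pytest.raises(ConfigurationError):
            driving_reward(DrivingState(0, 0, 60), clean_driving_params, 0.0)


class TestBeliefTracking:
    def test_map_matches_truth_with_good_observations(self, rng):
        """Observing every step at p_obs_correct >= 0.9, the filter's MAP
        position should match the true discretized position on at least
        90% of steps after burn-in."""
        p = DrivingParams(speed_kmh=60.0, p_obs_correct=0.9)
        model = learn_transition_model(p, 60_000, rng)
        state = DrivingState(0.0, 0.0, 60.0)
        belief = initial_belief(p)
        hits = 0
        total = 0
        for step in range(600):
            a_idx = int(rng.integers(p.n_actions - 2)) + 1  # skip hard maneuvers
            state = simulate_step(state, p.action_set[a_idx], p, rng)
            belief = belief_predict(belief, a_idx, model)
            belief = belief_correct(belief, sample_observation(state, p, rng), p)
            if step >= 20:
                total += 1
                hits += belief_summary(belief).map_position == p.discretize(
                    state.lateral_offset_m
                )
        assert hits / total >= 0.90


class TestDrivingEnv:
    def test_policy_beats_random_on_offset_and_excursions(self):
        """A SARSA-trained lane keeper must hold the lane better than the
        uniform-random policy over matched seeded episodes."""
        from multidrive.rl import LearningParams, select_action, train_policy

        p = DrivingParams(speed_kmh=60.0)
        rng = np.random.default_rng(11)
        tau = learn_transition_model(p, 25_000, rng)
        env = DrivingEnv(p, tau, episode_steps=80)
        qtable, _ = train_policy(env, LearningParams(n_episodes=1000, seed=11), rng)

        def rollout(policy, seed):
            r = np.random.default_rng(seed)
            env2 = DrivingEnv(
                p, tau, episode_steps=80, obs_burst_prob=0.0,
                exploring_start_prob=0.0,
            )
            key = env2.reset(r)
            offs, out = [], 0
            for _ in range(80):
                if policy == "random":
                    a = int(r.integers(p.n_actions))
                else:
                    a = select_action(qtable, key, 0.05, r)
                key, _, done, _ = env2.step(a, r)
                offs.append(abs(env2.state.lateral_offset_m))
                out += abs(env2.state.lateral_offset_m) > p.deviation_bound
            return np.mean(offs), out

        trained = np.array([rollout("trained", 1000 + i) for i in range(60)])
        random_ = np.array([rollout("random", 1000 + i) for i in range(60)])
        assert trained[:, 0].mean() < random_[:, 0].mean()
        assert trained[:, 1].sum() < random_[:, 1].sum()

    def test_state_key_is_map_and_entropy_bin(self):
        p = DrivingParams()
        b = initial_belief(p)
        key = belief_state_key(b, p)
        assert key == (p.n_position_bins // 2, 0)
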