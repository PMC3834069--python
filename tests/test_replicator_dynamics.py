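"""Replicator dynamics: conservation, regimes, bifurcation, attractors."""

import numpy as np
import pytest

from pggpunish import (
    GameConfig,
    PopulationState,
    classify_regime,
    evolve,
    make_grid_state,
    strategy_success,
    trajectory_frame,
    viability_floor,
)


@pytest.fixture
def floor_config() -> GameConfig:
    # c_m chosen so the viability floor sits at 1 MU: (r-1)*1 = 0.6
    return GameConfig(N=4, r=1.6, e=3.0, E=20.0, c_m=0.6)


class TestStrategySuccess:
    def test_homogeneous_population_is_neutral(self, lab_config):
        st = PopulationState(dc=[2.0], alpha=[0.2], freq=[1.0], c_norm=10.0)
        assert strategy_success((2.0, 0.2), st, lab_config) == pytest.approx(0.0)

    def test_two_strategy_split(self, lab_config):
        w = 0.3
        st = PopulationState(
            dc=[0.0, -2.0], alpha=[0.2, 0.2], freq=[w, 1 - w], c_norm=10.0
        )
        s_norm = strategy_success((0.0, 0.2), st, lab_config)
        s_dev = strategy_success((-2.0, 0.2), st, lab_config)
        g = s_norm - s_dev  # payoff gap between the strategies
        assert s_norm == pytest.approx((1 - w) * g)
        assert s_dev == pytest.approx(-w * g)

    def test_mean_success_is_zero(self, lab_config, rng):
        for _ in range(20):
            n = int(rng.integers(2, 12))
            freq = rng.dirichlet(np.ones(n))
            st = PopulationState(
                dc=rng.uniform(-8, 8, n),
                alpha=rng.uniform(0, 0.4, n),
                freq=freq,
                c_norm=10.0,
            )
            successes = [
                strategy_success((dc, a), st, lab_config)
                for dc, a in zip(st.dc, st.alpha)
            ]
            assert freq @ np.array(successes) == pytest.approx(0.0, abs=1e-9)

    def test_unknown_strategy_rejected(self, lab_config):
        st = PopulationState(dc=[0.0], alpha=[0.1], freq=[1.0], c_norm=10.0)
        with pytest.raises(ValueError):
            strategy_success((3.0, 0.1), st, lab_config)


class TestEvolve:
    def test_homogeneous_state_is_fixed_point(self, lab_config):
        st = PopulationState(dc=[1.5], alpha=[0.2], freq=[1.0], c_norm=10.0)
        traj = evolve(st, lab_config, dt=0.01, steps=50)
        assert all(s.mean_dc == pytest.approx(1.5) for s in traj)

    def test_normalization_and_positivity_each_step(self, floor_config):
        st = make_grid_state(floor_config, alpha=0.18, n_points=41)
        traj = evolve(st, floor_config, dt=0.005, steps=400, mutation_sigma=1.0)
        for s in traj:
            assert s.freq.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(s.freq >= 0)

    def test_defection_regime_descends_to_floor(self, floor_config):
        st = make_grid_state(floor_config, alpha=0.08, c_norm=10.0, n_points=101)
        traj = evolve(st, floor_config, dt=0.002, steps=8000, record_every=500)
        means = [s.mean_contribution for s in traj]
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))  # monotone down
        floor = viability_floor(floor_config)
        assert means[-1] == pytest.approx(floor, abs=0.25)
        assert means[-1] >= floor - 1e-9

    def test_coordination_regime_concentrates_on_initial_median(self, floor_config):
        st = make_grid_state(floor_config, alpha=0.2, c_norm=10.0, n_points=101)
        median0 = st.c_norm + st.median_dc()
        traj = evolve(st, floor_config, dt=0.002, steps=8000, record_every=1000)
        final = traj[-1]
        modal = final.c_norm + final.dc[np.argmax(final.freq)]
        assert modal == pytest.approx(median0)
        assert final.mean_contribution == pytest.approx(median0, abs=0.2)

    def test_skewed_start_attracts_to_median_not_mean(self, floor_config):
        """Black's-theorem check: with a right-skewed initial distribution
        the coordination attractor is the median, away from the mean."""
        n = 101
        weights = np.concatenate([np.full(70, 1.0), np.full(n - 70, 8.0)])
        st = make_grid_state(floor_config, alpha=0.2, n_points=n, freq=weights)
        median0 = st.c_norm + st.median_dc()
        mean0 = st.mean_contribution
        assert abs(median0 - mean0) > 1.0  # genuinely skewed start
        traj = evolve(st, floor_config, dt=0.002, steps=12000, record_every=3000)
        final = traj[-1]
        modal = final.c_norm + final.dc[np.argmax(final.freq)]
        assert modal == pytest.approx(median0)
        assert abs(final.mean_contribution - median0) < abs(
            final.mean_contribution - mean0
        )

    def test_mean_field_moment_identity(self, floor_config):
        """d(mean_dc)/dt equals cov(dc, success) along the trajectory."""
        st = make_grid_state(floor_config, alpha=0.08, n_points=51)
        dt = 0.001
        traj = evolve(st, floor_config, dt=dt, steps=1, record_every=1)
        s0, s1 = traj[0], traj[1]
        from pggpunish.replicator_dynamics import _payoffs_vs_reference

        u = _payoffs_vs_reference(s0, floor_config, s0.median_dc())
        sigma = u - s0.freq @ u
        cov = s0.freq @ (s0.dc * sigma) - s0.mean_dc * (s0.freq @ sigma)
        assert (s1.mean_dc - s0.mean_dc) / dt == pytest.approx(cov, rel=1e-2)

    def test_oversized_step_raises(self, floor_config):
        st = make_grid_state(floor_config, alpha=0.0, n_points=51)
        with pytest.raises(ValueError, match="dt"):
            evolve(st, floor_config, dt=10.0, steps=5)

    def test_trajectory_frame_columns(self, floor_config):
        st = make_grid_state(floor_config, alpha=0.2, n_points=21)
        frame = trajectory_frame(evolve(st, floor_config, dt=0.005, steps=20))
        assert list(frame.columns) == [
            "t", "mean_dc", "mean_alpha", "var_dc", "mean_contribution",
        ]
        assert frame["t"].is_monotonic_increasing


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "alpha, label",
        [(0.1, "defection"), (0.2, "coordination"), (0.125, "defection")],
    )
    def test_lab_game_labels(self, lab_config, alpha, label):
        assert classify_regime(alpha, lab_config) == label

    def test_floor_formulas(self, floor_config):
        assert viability_floor(floor_config) == pytest.approx(1.0)
        assert viability_floor(floor_config, "per_capita") == pytest.approx(
            4 * 0.6 / 1.6
        )

    def test_simulated_switch_brackets_the_threshold(self, floor_config):
        """Coarse alpha scan: modal attractor flips floor -> median within
        one scan step of the closed-form bifurcation (fine scan in the
        acceptance suite)."""
        alphas = np.linspace(0.05, 0.2, 16)
        st0 = make_grid_state(floor_config, alpha=0.0, n_points=101)
        median_dc = st0.median_dc()
        floor_dc = st0.dc[0]
        labels = []
        for a in alphas:
            st = make_grid_state(floor_config, alpha=float(a), n_points=101)
            final = evolve(st, floor_config, dt=0.005, steps=600, record_every=600)[-1]
            modal_dc = final.dc[np.argmax(final.freq)]
            labels.append("median" if abs(modal_dc - median_dc) < abs(modal_dc - floor_dc) else "floor")
        switch = labels.index("median")
        assert alphas[switch - 1] <= 0.125 <= alphas[switch] + 1e-12
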