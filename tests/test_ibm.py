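"""Individual-based simulation: initialisation, density perception,
vertical exchange, horizontal stepping, conservation and determinism."""

import numpy as np
import pytest

from slugdyn import (
    DENSE,
    SPARSE,
    MovementParams,
    SimulationConfig,
    SlugPopulationState,
    init_uniform,
    local_density,
    simulate,
)
from slugdyn.ibm import (
    classify_regime,
    horizontal_step_overground,
    horizontal_step_underground,
    vertical_transition,
)
from slugdyn.compartment import steady_state


def make_state(x, y, over, L=10.0, heading=None):
    x = np.asarray(x, dtype=float)
    return SlugPopulationState(
        x=x,
        y=np.asarray(y, dtype=float),
        heading=np.zeros_like(x) if heading is None else np.asarray(heading),
        over=np.asarray(over, dtype=bool),
        L=L,
    )


class TestInitUniform:
    def test_half_and_half_split(self):
        config = SimulationConfig(Pi=10_000, alpha=0.5, beta=0.5, T=1)
        state = init_uniform(config)
        assert state.n_over == 5000 and state.n_under == 5000

    def test_empty_population(self):
        state = init_uniform(SimulationConfig(Pi=0, T=1))
        assert state.size == 0 and state.n_over == 0

    def test_uniform_coordinate_mean(self):
        n = 10_000
        config = SimulationConfig(Pi=n, alpha=1.0, beta=0.0, T=1, seed=3)
        state = init_uniform(config)
        se = (config.L / np.sqrt(12)) / np.sqrt(n)
        assert abs(state.x.mean() - config.L / 2) < 3 * se
        assert abs(state.y.mean() - config.L / 2) < 3 * se

    def test_rounded_initial_split(self):
        config = SimulationConfig(Pi=101, alpha=0.25, beta=0.75, T=1)
        assert init_uniform(config).n_over == round(0.25 * 101)

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(Pi=-1, T=1)


class TestLocalDensity:
    def test_lone_slug_sees_zero(self):
        state = make_state([5.0], [5.0], [True])
        assert local_density(state, R=1.0) == pytest.approx([0.0])

    def test_count_over_circle_area(self, rng):
        """158 neighbours within 1 m give 158/pi ~ 50.3 > 50: dense."""
        r = 0.95 * np.sqrt(rng.random(158))
        phi = rng.uniform(0, 2 * np.pi, 158)
        x = np.concatenate([[5.0], 5 + r * np.cos(phi)])
        y = np.concatenate([[5.0], 5 + r * np.sin(phi)])
        state = make_state(x, y, [True] * 159)
        D = local_density(state, R=1.0)
        assert D[0] == pytest.approx(158 / np.pi)
        assert classify_regime(D[0], d=50.0) == DENSE

    def test_underground_slugs_invisible(self):
        state = make_state([5.0, 5.1, 5.2], [5.0, 5.0, 5.0],
                           [True, False, False])
        assert local_density(state, R=1.0) == pytest.approx([0.0])

    def test_mean_density_of_uniform_population(self, rng):
        """1000 slugs on 100 m^2: mean perceived density near 10 per m^2
        (slightly below because perception circles spill over the edge)."""
        state = make_state(rng.uniform(0, 10, 1000), rng.uniform(0, 10, 1000),
                           [True] * 1000)
        mean_D = local_density(state, R=1.0).mean()
        assert 8.5 < mean_D < 10.5

    def test_invalid_radius_rejected(self):
        state = make_state([1.0], [1.0], [True])
        with pytest.raises(ValueError):
            local_density(state, R=0.0)


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "D_l, expected",
        [(49.9, SPARSE), (50.0, DENSE), (90.0, DENSE), (0.0, SPARSE)],
    )
    def test_threshold_boundary(self, D_l, expected):
        assert classify_regime(D_l, d=50.0) == expected


class TestVerticalTransition:
    def test_zero_probabilities_leave_state_unchanged(self, rng):
        state = init_uniform(SimulationConfig(Pi=500, T=1, seed=1))
        before = state.over.copy()
        vertical_transition(state, 0.0, 0.0, rng)
        assert np.array_equal(state.over, before)

    def test_certain_transition_swaps_layers(self, rng):
        state = init_uniform(SimulationConfig(Pi=500, T=1, seed=1))
        before = state.over.copy()
        x_before = state.x.copy()
        vertical_transition(state, 1.0, 1.0, rng)
        assert np.array_equal(state.over, ~before)  # simultaneous marking
        assert np.array_equal(state.x, x_before)  # positions untouched

    def test_expected_mover_counts(self, rng):
        """Mean movers per direction over replicates is binomial."""
        n_rep, moved_down = 100, []
        for _ in range(n_rep):
            state = init_uniform(
                SimulationConfig(Pi=10_000, alpha=0.5, beta=0.5, T=1, seed=7))
            before = state.over.copy()
            vertical_transition(state, 0.5, 0.5, rng)
            moved_down.append(np.count_nonzero(before & ~state.over))
        tol = 3 * np.sqrt(5000 * 0.25) / np.sqrt(n_rep)
        assert abs(np.mean(moved_down) - 2500) < tol

    def test_conserves_total(self, rng):
        state = init_uniform(SimulationConfig(Pi=1000, T=1, seed=2))
        vertical_transition(state, 0.3, 0.7, rng)
        assert state.size == 1000


class TestHorizontalSteps:
    def test_zero_movement_probability_freezes_surface(self, rng):
        params = MovementParams(p_ms=0.0, p_md=0.0)
        state = init_uniform(SimulationConfig(Pi=200, alpha=1.0, beta=0.0,
                                              T=1, seed=5))
        x0, y0 = state.x.copy(), state.y.copy()
        horizontal_step_overground(state, params, rng)
        assert np.array_equal(state.x, x0) and np.array_equal(state.y, y0)

    def test_sparse_step_lengths_and_move_fraction(self, rng):
        """Isolated slugs are all in the sparse regime: they move with
        frequency p_ms and their steps are half-normal with scale sigma_s."""
        n, L = 1000, 1000.0
        params = MovementParams()
        state = SlugPopulationState(
            x=rng.uniform(1, L - 1, n), y=rng.uniform(1, L - 1, n),
            heading=rng.uniform(-np.pi, np.pi, n),
            over=np.ones(n, dtype=bool), L=L,
        )
        steps, n_moved, n_ticks = [], 0, 50
        for _ in range(n_ticks):
            x0, y0 = state.x.copy(), state.y.copy()
            horizontal_step_overground(state, params, rng)
            d = np.hypot(state.x - x0, state.y - y0)
            steps.append(d[d > 0])
            n_moved += np.count_nonzero(d > 0)
        steps = np.concatenate(steps)
        mean = params.sigma_s * np.sqrt(2 / np.pi)
        se = params.sigma_s * np.sqrt(1 - 2 / np.pi) / np.sqrt(steps.size)
        assert abs(steps.mean() - mean) < 3 * se
        frac = n_moved / (n * n_ticks)
        assert abs(frac - params.p_ms) < 3 * np.sqrt(0.25 / (n * n_ticks))

    def test_underground_step_lengths(self, rng):
        n, L = 2000, 1000.0
        params = MovementParams()
        state = SlugPopulationState(
            x=rng.uniform(1, L - 1, n), y=rng.uniform(1, L - 1, n),
            heading=rng.uniform(-np.pi, np.pi, n),
            over=np.zeros(n, dtype=bool), L=L,
        )
        steps = []
        for _ in range(50):
            x0, y0 = state.x.copy(), state.y.copy()
            horizontal_step_underground(state, params, rng)
            steps.append(np.hypot(state.x - x0, state.y - y0))
        steps = np.concatenate(steps)
        assert (steps > 0).all()  # no rest state underground
        mean = params.sigma_under * np.sqrt(2 / np.pi)
        se = params.sigma_under * np.sqrt(1 - 2 / np.pi) / np.sqrt(steps.size)
        assert abs(steps.mean() - mean) < 3 * se

    def test_underground_msd_grows_linearly(self, rng):
        """Brownian steps: mean squared displacement ~ sigma^2 t."""
        n, L = 2000, 1000.0
        params = MovementParams()
        state = SlugPopulationState(
            x=rng.uniform(400, 600, n), y=rng.uniform(400, 600, n),
            heading=rng.uniform(-np.pi, np.pi, n),
            over=np.zeros(n, dtype=bool), L=L,
        )
        x0, y0 = state.x.copy(), state.y.copy()
        msd = {}
        for t in range(1, 61):
            horizontal_step_underground(state, params, rng)
            if t in (30, 60):
                msd[t] = np.mean((state.x - x0) ** 2 + (state.y - y0) ** 2)
        assert msd[60] / msd[30] == pytest.approx(2.0, rel=0.15)
        assert msd[60] == pytest.approx(params.sigma_under**2 * 60, rel=0.15)

    @pytest.mark.parametrize("boundary", ["reflect", "periodic"])
    def test_positions_stay_in_domain(self, boundary, rng):
        params = MovementParams(sigma_s=2.0, sigma_d=2.0, sigma_under=2.0)
        state = init_uniform(SimulationConfig(Pi=300, T=1, seed=9, L=1.0))
        for _ in range(30):
            horizontal_step_overground(state, params, rng, boundary)
            horizontal_step_underground(state, params, rng, boundary)
        assert (state.x >= 0).all() and (state.x <= 1.0).all()
        assert (state.y >= 0).all() and (state.y <= 1.0).all()


class TestSimulate:
    def test_conservation_every_tick(self):
        res = simulate(SimulationConfig(Pi=2000, T=100, seed=11))
        assert (res.N + res.P == 2000).all()

    def test_empty_population_time_series(self):
        res = simulate(SimulationConfig(Pi=0, T=10, seed=0))
        assert (res.N == 0).all() and (res.P == 0).all()

    def test_zero_steps_returns_initial_state(self):
        res = simulate(SimulationConfig(Pi=100, T=0, seed=0))
        assert res.N.size == 1 and res.final_state.t == 0

    def test_seed_determinism(self):
        config = SimulationConfig(Pi=500, T=50, seed=123, record_every=10)
        a, b = simulate(config), simulate(config)
        assert np.array_equal(a.N, b.N)
        assert np.array_equal(a.final_state.x, b.final_state.x)
        assert np.array_equal(a.final_state.over, b.final_state.over)
        for (ta, sa), (tb, sb) in zip(a.snapshots, b.snapshots):
            assert ta == tb and np.array_equal(sa.x, sb.x)

    def test_decoupled_layers_keep_sizes(self):
        """p_u = p_d = 0 reduces to two independent planar models."""
        res = simulate(SimulationConfig(Pi=1000, p_u=0.0, p_d=0.0, T=50,
                                        seed=4, alpha=0.3, beta=0.7))
        assert (res.N == res.N[0]).all() and (res.P == res.P[0]).all()

    def test_degenerate_exchange_reaches_balance_in_one_tick(self):
        """p_u + p_d = 1 from a one-sided start: layer sizes hit the
        equilibrium mean immediately (in expectation)."""
        counts = [
            simulate(SimulationConfig(Pi=10_000, p_u=0.5, p_d=0.5, alpha=1.0,
                                      beta=0.0, T=1, seed=100 + k)).N[-1]
            for k in range(20)
        ]
        se = np.sqrt(10_000 * 0.25) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 5000) < 3 * se

    def test_converges_to_compartment_steady_state(self):
        """Time-averaged post-transition N_t matches the analytic N*."""
        p_u, p_d, Pi = 0.5, 0.5, 2000
        res = simulate(SimulationConfig(Pi=Pi, p_u=p_u, p_d=p_d, T=200,
                                        seed=21))
        N_star, _ = steady_state(p_u, p_d, Pi)
        p_hat = p_u / (p_u + p_d)
        tail = res.N[100:]
        assert abs(tail.mean() - N_star) < 3 * np.sqrt(Pi * p_hat * (1 - p_hat))

    def test_snapshot_cadence(self):
        res = simulate(SimulationConfig(Pi=50, T=25, seed=1, record_every=10))
        assert [t for t, _ in res.snapshots] == [0, 10, 20, 25]
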