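"""Unit tests for the continuous honey badger optimizer."""

import numpy as np
import pytest

from lfhba.hba import (
    EPS_DISTANCE,
    Bounds,
    HbaConfig,
    density_factor,
    digging_update,
    direction_flag,
    hba_minimize,
    honey_update,
    init_population,
    intensity,
)


class TestBounds:
    def test_broadcasts_scalars(self):
        b = Bounds(0.0, 1.0, dim=4)
        assert b.lower.shape == (4,) and b.upper.shape == (4,)

    @pytest.mark.parametrize("lo,hi", [(np.nan, 1), (0, np.inf), (2, 1)])
    def test_rejects_bad_bounds(self, lo, hi):
        with pytest.raises(ValueError):
            Bounds(lo, hi, dim=2)

    def test_clamp(self):
        b = Bounds(0.0, 1.0, dim=3)
        out = b.clamp(np.array([-0.5, 0.5, 1.5]))
        assert np.allclose(out, [0.0, 0.5, 1.0])


class TestInitPopulation:
    def test_forced_draw_is_linear_map(self, forced_rng):
        b = Bounds(0.0, 1.0, dim=3)
        pop = init_population(b, HbaConfig(pop_size=2), forced_rng(uniforms=[0.25]))
        assert np.allclose(pop, 0.25)

    def test_degenerate_interval(self, rng):
        b = Bounds(0.7, 0.7, dim=5)
        pop = init_population(b, HbaConfig(pop_size=4), rng)
        assert np.all(pop == 0.7)

    def test_paper_scale_population_reproducible(self):
        b = Bounds(0.0, 1.0, dim=128)
        cfg = HbaConfig(pop_size=50)
        p1 = init_population(b, cfg, np.random.default_rng(3))
        p2 = init_population(b, cfg, np.random.default_rng(3))
        assert p1.shape == (50, 128)
        assert np.all((p1 >= 0) & (p1 <= 1))
        assert np.array_equal(p1, p2)


class TestIntensity:
    def test_zero_attention_force(self, forced_rng):
        pos = np.array([[0.3, 0.4], [0.3, 0.4]])
        I = intensity(pos, np.array([1.0, 1.0]), forced_rng(uniforms=[1.0]))
        assert np.all(I == 0)

    def test_scalar_cancellation(self, forced_rng):
        # S = 4*pi and d^2 = 1 cancel the 4*pi denominator exactly
        s = np.sqrt(4 * np.pi)
        pos = np.array([[0.0], [s]])
        I = intensity(pos, np.array([1.0]), forced_rng(uniforms=[1.0]))
        assert I[0, 0] == pytest.approx(1.0)

    def test_epsilon_guard_on_prey(self, forced_rng):
        pos = np.array([[1.0], [2.0]])  # first badger sits on the prey
        I = intensity(pos, np.array([1.0]), forced_rng(uniforms=[1.0]))
        expected = 1.0 / (4 * np.pi * EPS_DISTANCE)
        assert np.isfinite(I[0, 0]) and I[0, 0] == pytest.approx(expected)


class TestDensityFactor:
    def test_starts_at_C(self):
        assert density_factor(0, 100, 3.7) == pytest.approx(3.7)

    def test_ends_at_C_over_e(self):
        assert density_factor(100, 100, 2.0) == pytest.approx(2 / np.e)
        assert density_factor(100, 100, 2.0) == pytest.approx(0.735759, abs=1e-6)

    def test_strictly_decreasing(self):
        vals = [density_factor(t, 50, 2.0) for t in range(51)]
        assert np.all(np.diff(vals) < 0)

    def test_rejects_zero_horizon(self):
        with pytest.raises(ValueError):
            density_factor(0, 0, 2.0)


class TestDirectionFlag:
    def test_boundary_inclusive(self, forced_rng):
        assert direction_flag(forced_rng(uniforms=[0.5])) == 1
        assert direction_flag(forced_rng(uniforms=[0.500001])) == -1

    def test_fair_coin(self):
        g = np.random.default_rng(0)
        draws = [direction_flag(g) for _ in range(100_000)]
        assert abs(np.mean(draws)) < 3 * np.sqrt(1 / 100_000)


class TestDiggingUpdate:
    def test_vanishing_perturbations(self, forced_rng):
        prey = np.array([0.5, 0.6])
        out = digging_update(
            np.array([0.1, 0.2]), prey, 0.0, 1.0, 1, 6.0,
            forced_rng(uniforms=[0.0]),
        )
        assert np.allclose(out, prey)

    def test_trig_zero_leaves_scaled_prey(self, forced_rng):
        # r4 = r5 = 0 makes (1 - cos 0) = 0, killing the d-term
        prey = np.array([0.5])
        out = digging_update(
            np.array([0.1]), prey, 2.0, 1.0, 1, 6.0, forced_rng(uniforms=[0.0])
        )
        assert np.allclose(out, prey * (1 + 6.0 * 2.0))

    def test_scalar_arithmetic(self, forced_rng):
        out = digging_update(
            np.array([0.0]), np.array([1.0]), 1.0, 1.0, 1, 6.0,
            forced_rng(uniforms=[0.0]),
        )
        assert out[0] == pytest.approx(7.0)


class TestHoneyUpdate:
    def test_zero_draw_returns_prey(self, forced_rng):
        prey = np.array([0.3, 0.9])
        out = honey_update(np.array([0.1, 0.1]), prey, 1.0, 1, forced_rng(uniforms=[0.0]))
        assert np.allclose(out, prey)

    def test_full_draw_reflects(self, forced_rng):
        x, prey = np.array([0.2]), np.array([0.8])
        out = honey_update(x, prey, 1.0, 1, forced_rng(uniforms=[1.0]))
        assert np.allclose(out, 2 * prey - x)

    def test_alpha_limit(self, forced_rng):
        prey = np.array([0.3])
        out = honey_update(np.array([0.9]), prey, 1e-12, 1, forced_rng(uniforms=[1.0]))
        assert np.allclose(out, prey, atol=1e-9)


class TestHbaMinimize:
    def sphere(self, x):
        return float(np.sum(x**2))

    def test_zero_iterations_returns_initial_best(self):
        b = Bounds(-1, 1, dim=3)
        cfg = HbaConfig(pop_size=10, max_iters=0, seed=1)
        _, bf, hist = hba_minimize(self.sphere, b, cfg)
        assert len(hist) == 1 and hist[0] == bf

    def test_sphere_sanity(self):
        # global minimum 0 is known analytically
        vals = []
        for seed in range(5):
            cfg = HbaConfig(pop_size=30, max_iters=200, seed=seed)
            _, bf, _ = hba_minimize(self.sphere, Bounds(-5.12, 5.12, dim=5), cfg)
            vals.append(bf)
        assert np.median(vals) < 1e-2

    @pytest.mark.parametrize("seed", range(4))
    def test_elitism_and_bounds(self, seed):
        b = Bounds(-2, 2, dim=4)
        cfg = HbaConfig(pop_size=12, max_iters=60, seed=seed)
        bx, bf, hist = hba_minimize(self.sphere, b, cfg)
        assert len(hist) == cfg.max_iters + 1
        assert np.all(np.diff(hist) <= 0)
        assert np.all((bx >= b.lower) & (bx <= b.upper))

    def test_bit_identical_reruns(self):
        b = Bounds(-2, 2, dim=4)
        cfg = HbaConfig(pop_size=12, max_iters=40, seed=9)
        r1 = hba_minimize(self.sphere, b, cfg)
        r2 = hba_minimize(self.sphere, b, cfg)
        assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1]
        assert np.array_equal(r1[2], r2[2])

    def test_non_finite_objective_aborts_with_iteration(self):
        calls = {"n": 0}

        def bad(x):
            calls["n"] += 1
            return np.nan if calls["n"] > 15 else float(np.sum(x**2))

        with pytest.raises(RuntimeError, match="iteration"):
            hba_minimize(bad, Bounds(-1, 1, dim=2), HbaConfig(pop_size=10, max_iters=5, seed=0))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pop_size": 0},
            {"density_constant": 0.5},
            {"ability": 0.0},
        ],
    )
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            HbaConfig(**kwargs)
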