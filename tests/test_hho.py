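"""Unit and property tests for the Harris hawks optimizer.

Each update rule is checked against an independent transcription of its
mathematical definition that mirrors the optimizer's documented draw order
on a separately seeded generator.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gamma as sp_gamma

from hho_featsel.hho import (
    HawkPopulation,
    OptimizerConfig,
    SearchSpace,
    escaping_energy,
    exploration_step,
    hard_besiege,
    hard_besiege_dives,
    hho_optimize,
    init_population,
    levy_flight,
    levy_sigma,
    mean_position,
    soft_besiege,
    soft_besiege_dives,
)

from conftest import sphere


def make_population(rng: np.random.Generator, m: int = 6, d: int = 3) -> HawkPopulation:
    positions = rng.uniform(-5, 5, size=(m, d))
    fitness = np.array([sphere(p) for p in positions])
    best = int(np.argmin(fitness))
    return HawkPopulation(positions, fitness, positions[best].copy(), float(fitness[best]))


# ---------------------------------------------------------------- energy


@pytest.mark.parametrize(
    "g0,i,I,expected",
    [(1.0, 0, 10, 2.0), (0.3, 10, 10, 0.0), (-0.5, 5, 10, -0.5)],
)
def test_escaping_energy_values(g0, i, I, expected):
    assert escaping_energy(g0, i, I) == pytest.approx(expected)


def test_escaping_energy_rejects_bad_iteration():
    with pytest.raises(ValueError):
        escaping_energy(0.5, 11, 10)
    with pytest.raises(ValueError):
        escaping_energy(0.5, 0, 0)


@given(st.floats(-1, 1), st.integers(0, 100))
@settings(deadline=None, max_examples=50)
def test_energy_envelope(g0, i):
    """|G| never exceeds its linear decay envelope 2(1 - i/I)."""
    I = 100
    assert abs(escaping_energy(g0, i, I)) <= 2.0 * (1.0 - i / I) + 1e-12


# ------------------------------------------------------------ population


def test_init_population_degenerate_box_collapses():
    eps = 1e-9
    space = SearchSpace(np.zeros(3), np.full(3, eps))
    cfg = OptimizerConfig(pop_size=4, max_iter=1, space=space, seed=0)
    pop = init_population(cfg, sphere)
    assert np.all(np.abs(pop.positions) <= eps)


def test_init_population_within_bounds_and_best_matches_bruteforce():
    space = SearchSpace.cube(10, -3.0, 3.0)
    cfg = OptimizerConfig(pop_size=30, max_iter=1, space=space, seed=5)
    pop = init_population(cfg, sphere)
    assert np.all(pop.positions >= space.lower) and np.all(pop.positions <= space.upper)
    # brute-force loop over the evaluated population
    best = math.inf
    for row in pop.positions:
        best = min(best, sphere(row))
    assert pop.best_fitness == pytest.approx(best)


def test_init_population_rejects_nonfinite_objective():
    space = SearchSpace.cube(2, -1.0, 1.0)
    cfg = OptimizerConfig(pop_size=3, max_iter=1, space=space, seed=1)
    with pytest.raises(ValueError, match="non-finite"):
        init_population(cfg, lambda x: math.nan)


def test_mean_position_matches_explicit_summation():
    rng = np.random.default_rng(3)
    pop = make_population(rng, m=5, d=4)
    acc = np.zeros(4)
    for row in pop.positions:
        acc += row
    np.testing.assert_allclose(mean_position(pop), acc / 5, atol=1e-12)
    same = HawkPopulation(
        np.tile([1.0, 2.0], (3, 1)), np.zeros(3), np.array([1.0, 2.0]), 0.0
    )
    np.testing.assert_allclose(mean_position(same), [1.0, 2.0])


# ----------------------------------------------------------- update rules


def oracle_exploration(pop, k, space, seed):
    """Independent transcription of the exploration rule."""
    rng = np.random.default_rng(seed)
    r = int(rng.integers(pop.size))
    c, n1, n2, n3, n4 = rng.random(5)
    if c >= 0.5:
        val = pop.positions[r] - n1 * np.abs(pop.positions[r] - 2.0 * n2 * pop.positions[k])
    else:
        avg = pop.positions.mean(axis=0)
        val = (pop.best_position - avg) - n3 * (space.lower + n4 * (space.upper - space.lower))
    return np.minimum(np.maximum(val, space.lower), space.upper)


@pytest.mark.parametrize("seed", range(20))
def test_exploration_matches_oracle(seed):
    rng = np.random.default_rng(1000 + seed)
    pop = make_population(rng)
    space = SearchSpace.cube(3, -5.0, 5.0)
    got = exploration_step(pop, 2, space, np.random.default_rng(seed))
    want = oracle_exploration(pop, 2, space, seed)
    np.testing.assert_allclose(got, want, atol=1e-12)


def oracle_soft(current, victim, g, space, seed):
    rng = np.random.default_rng(seed)
    s = 2.0 * (1.0 - rng.random())
    val = (victim - current) - g * np.abs(s * victim - current)
    return np.minimum(np.maximum(val, space.lower), space.upper)


@pytest.mark.parametrize("seed", range(20))
def test_soft_besiege_matches_oracle(seed):
    rng = np.random.default_rng(2000 + seed)
    current = rng.uniform(-5, 5, 2)
    victim = rng.uniform(-5, 5, 2)
    g = rng.uniform(-1, 1)
    space = SearchSpace.cube(2, -5.0, 5.0)
    got = soft_besiege(current, victim, g, space, np.random.default_rng(seed))
    np.testing.assert_allclose(got, oracle_soft(current, victim, g, space, seed), atol=1e-12)


def test_soft_besiege_zero_energy_gives_delta():
    space = SearchSpace.cube(2, -10.0, 10.0)
    current = np.array([1.0, 2.0])
    victim = np.array([3.0, -1.0])
    got = soft_besiege(current, victim, 0.0, space, np.random.default_rng(0))
    np.testing.assert_allclose(got, victim - current)


def test_hard_besiege_cases():
    space = SearchSpace.cube(1, -10.0, 10.0)
    # G=0: hawk lands on the victim
    np.testing.assert_allclose(
        hard_besiege(np.array([4.0]), np.array([1.5]), 0.0, space), [1.5]
    )
    # coincident positions: delta vanishes
    np.testing.assert_allclose(
        hard_besiege(np.array([2.0]), np.array([2.0]), 0.3, space), [2.0]
    )
    # scalar substitution: 1 - 0.4*|1-0| = 0.6
    np.testing.assert_allclose(
        hard_besiege(np.array([0.0]), np.array([1.0]), 0.4, space), [0.6]
    )


# ------------------------------------------------------------ Lévy flight


def test_levy_sigma_matches_gamma_oracle():
    beta = 1.5
    num = sp_gamma(1 + beta) * np.sin(np.pi * beta / 2)
    den = sp_gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    expected = float((num / den) ** (1 / beta))
    assert levy_sigma(beta) == pytest.approx(expected, abs=1e-12)
    assert levy_sigma(beta) == pytest.approx(0.6966, abs=1e-4)


def test_levy_sigma_rejects_bad_beta():
    for bad in (1.0, 2.5, 0.5):
        with pytest.raises(ValueError):
            levy_sigma(bad)


def test_levy_flight_heavy_tail():
    """Mantegna steps have excess kurtosis (heavier tail than Gaussian)."""
    rng = np.random.default_rng(42)
    draws = levy_flight(100_000, rng)
    x = draws / draws.std()
    kurtosis = np.mean(x**4) - 3.0
    assert kurtosis > 0.0


def test_levy_flight_zero_numerator():
    class ZeroU:
        def __init__(self):
            self.calls = 0

        def standard_normal(self, n):
            self.calls += 1
            return np.zeros(n) if self.calls == 1 else np.ones(n)

    step = levy_flight(5, ZeroU())
    np.testing.assert_allclose(step, 0.0)


# ------------------------------------------------------------------ dives


def oracle_soft_dive(current, f_current, victim, g, objective, space, seed):
    rng = np.random.default_rng(seed)
    s = 2.0 * (1.0 - rng.random())
    a = np.minimum(np.maximum(victim - g * np.abs(s * victim - current), space.lower), space.upper)
    fa = objective(a)
    if fa < f_current:
        return a
    v = rng.random(current.size)
    lf = levy_flight(current.size, rng)
    b = np.minimum(np.maximum(a + v * lf, space.lower), space.upper)
    fb = objective(b)
    return b if fb < f_current else current


@pytest.mark.parametrize("seed", range(20))
def test_soft_dive_matches_oracle_branch(seed):
    rng = np.random.default_rng(3000 + seed)
    current = rng.uniform(-5, 5, 2)
    victim = rng.uniform(-1, 1, 2)
    g = rng.uniform(-1, 1)
    space = SearchSpace.cube(2, -5.0, 5.0)
    got, f_got, _ = soft_besiege_dives(
        current, sphere(current), victim, g, sphere, space, np.random.default_rng(seed)
    )
    want = oracle_soft_dive(current, sphere(current), victim, g, sphere, space, seed)
    np.testing.assert_allclose(got, want, atol=1e-12)
    assert f_got == pytest.approx(sphere(got))


def test_soft_dive_constant_objective_keeps_position():
    space = SearchSpace.cube(3, -5.0, 5.0)
    current = np.array([1.0, -2.0, 0.5])
    got, f_got, evals = soft_besiege_dives(
        current, 7.0, np.zeros(3), 0.6, lambda x: 7.0, space, np.random.default_rng(1)
    )
    np.testing.assert_allclose(got, current)
    assert f_got == 7.0 and evals == 2


def test_soft_dive_improves_toward_sphere_minimum():
    space = SearchSpace.cube(2, -10.0, 10.0)
    current = np.array([8.0, 8.0])
    got, f_got, evals = soft_besiege_dives(
        current, sphere(current), np.zeros(2), 0.05, sphere, space, np.random.default_rng(0)
    )
    assert f_got < sphere(current)
    assert evals == 1  # direct move A accepted


def test_hard_dive_uses_flock_mean_and_matches_oracle():
    space = SearchSpace.cube(2, -5.0, 5.0)
    rng_in = np.random.default_rng(9)
    current = rng_in.uniform(-5, 5, 2)
    avg = rng_in.uniform(-5, 5, 2)
    victim = np.array([0.1, -0.2])
    g = 0.3
    got, _, _ = hard_besiege_dives(
        current, sphere(current), victim, avg, g, sphere, space, np.random.default_rng(4)
    )
    # independent transcription with the flock mean in place of the hawk
    rng = np.random.default_rng(4)
    s = 2.0 * (1.0 - rng.random())
    a = np.clip(victim - g * np.abs(s * victim - avg), -5, 5)
    if sphere(a) < sphere(current):
        want = a
    else:
        v = rng.random(2)
        b = np.clip(a + v * levy_flight(2, rng), -5, 5)
        want = b if sphere(b) < sphere(current) else current
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_hard_dive_g_zero_adopts_victim_when_better():
    space = SearchSpace.cube(2, -5.0, 5.0)
    current = np.array([3.0, 3.0])
    victim = np.array([0.5, 0.5])
    got, f_got, _ = hard_besiege_dives(
        current, sphere(current), victim, current, 0.0, sphere, space,
        np.random.default_rng(0),
    )
    np.testing.assert_allclose(got, victim)
    assert f_got == pytest.approx(sphere(victim))


# ------------------------------------------------------------- main loop


def test_optimize_one_iteration_constant_objective():
    cfg = OptimizerConfig(
        pop_size=2, max_iter=1, space=SearchSpace.cube(2, -1.0, 1.0), seed=0
    )
    res = hho_optimize(lambda x: 3.25, cfg)
    assert res.best_fitness == 3.25
    assert res.fitness_history.shape == (1,)


def test_optimize_seeded_determinism(sphere_config):
    r1 = hho_optimize(sphere, sphere_config)
    r2 = hho_optimize(sphere, sphere_config)
    np.testing.assert_array_equal(r1.best_position, r2.best_position)
    np.testing.assert_array_equal(r1.fitness_history, r2.fitness_history)
    assert r1.best_fitness == r2.best_fitness
    assert r1.evaluations == r2.evaluations


def test_optimize_history_monotone_and_bounded(sphere_config):
    res = hho_optimize(sphere, sphere_config)
    assert np.all(np.diff(res.fitness_history) <= 0)
    assert np.all(np.abs(res.best_position) <= 10.0)


def test_optimize_evaluation_budget_linear_in_m_and_i():
    """Evaluation count stays within M*(1 + 2*I): linear, as the complexity
    analysis requires (dives may use up to two evaluations)."""
    m, iters = 8, 40
    cfg = OptimizerConfig(pop_size=m, max_iter=iters, space=SearchSpace.cube(3, -2.0, 2.0), seed=2)
    res = hho_optimize(sphere, cfg)
    assert m + m * iters <= res.evaluations <= m + 2 * m * iters


@pytest.mark.parametrize("seed", range(10))
def test_optimize_recovers_1d_convex_minimum(seed):
    cfg = OptimizerConfig(
        pop_size=10, max_iter=100, space=SearchSpace.cube(1, -4.0, 6.0), seed=seed
    )
    res = hho_optimize(lambda x: float((x[0] - 1.7) ** 2), cfg)
    assert abs(res.best_position[0] - 1.7) < 1e-3


def test_branch_log_respects_energy_gates():
    cfg = OptimizerConfig(
        pop_size=10,
        max_iter=60,
        space=SearchSpace.cube(4, -5.0, 5.0),
        seed=3,
        track_branches=True,
    )
    res = hho_optimize(sphere, cfg)
    assert res.branch_log
    for i, _, branch, g in res.branch_log:
        assert abs(g) <= 2.0 * (1.0 - i / cfg.max_iter) + 1e-12
        if branch == "exploration":
            assert abs(g) >= 1.0
            assert i / cfg.max_iter <= 0.5
        elif branch in ("soft_besiege", "soft_dive"):
            assert 0.5 <= abs(g) < 1.0
        else:
            assert abs(g) < 0.5


def test_result_serializes_to_json(sphere_config):
    import json

    res = hho_optimize(sphere, sphere_config)
    payload = json.loads(res.to_json())
    assert payload["best_fitness"] == res.best_fitness
    assert len(payload["fitness_history"]) == sphere_config.max_iter


def test_config_validation():
    space = SearchSpace.cube(2, 0.0, 1.0)
    with pytest.raises(ValueError):
        OptimizerConfig(pop_size=1, max_iter=5, space=space)
    with pytest.raises(ValueError):
        OptimizerConfig(pop_size=5, max_iter=0, space=space)
    with pytest.raises(ValueError):
        OptimizerConfig(pop_size=5, max_iter=5, space=space, beta=1.0)
    with pytest.raises(ValueError):
        SearchSpace(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
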