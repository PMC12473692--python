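"""Life-table engine: schedules, Euler-Lotka solution, e_xj / v_xj identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agestage.cohort import Cohort, build_age_stage_counts, cohort_arrays, collapse_stages
from agestage.lifetable import (
    FecunditySchedule,
    UndefinedParameterError,
    age_specific_survival,
    compute_demography,
    fecundity_schedule,
    finite_rate,
    intrinsic_rate,
    life_expectancy,
    mean_generation_time,
    net_reproductive_rate,
    preadult_survival,
    reproductive_value,
    solve_euler,
    survival_matrix,
    transition_model,
)
from agestage.simulate import load_preset, simulate_cohort

from conftest import SHORT_ORDER, make_individual


def schedule_of(cohort):
    s = survival_matrix(build_age_stage_counts(cohort))
    return s, fecundity_schedule(cohort, s)


def grid_search_r(phi, lo=-2.0, hi=2.0, rounds=5, points=2001):
    """Independent Euler-root oracle: iterative dense grid on the plain sum."""
    phi = np.asarray(phi, dtype=float)
    ages1 = np.arange(1, phi.size + 1)
    for _ in range(rounds):
        grid = np.linspace(lo, hi, points)
        vals = np.array([np.sum(np.exp(-r * ages1) * phi) - 1.0 for r in grid])
        i = int(np.argmin(np.abs(vals)))
        lo, hi = grid[max(0, i - 1)], grid[min(points - 1, i + 1)]
    return 0.5 * (lo + hi)


class TestSurvivalMatrix:
    def test_proportions(self, tiny_cohort):
        s = survival_matrix(build_age_stage_counts(tiny_cohort))
        assert s.s[0, 0] == 1.0  # everyone starts as an egg
        assert np.isclose(s.s.sum(axis=1)[0], 1.0)

    def test_lx_monotone_and_matches_alive_fraction(self, control_cohort):
        s = survival_matrix(build_age_stage_counts(control_cohort))
        l = age_specific_survival(s)
        assert l[0] == 1.0
        assert np.all(np.diff(l) <= 1e-12)
        alive3 = sum(
            1 for i in control_cohort.individuals
            for o in i.observations if o.alive and o.age == 3
        )
        assert np.isclose(l[3], alive3 / control_cohort.N)

    def test_zero_n_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            survival_matrix(build_age_stage_counts(tiny_cohort), N=0)


class TestFecunditySchedule:
    def test_single_female_mx(self):
        """Only survivor at age 7 lays 7 eggs -> m_7 = 7."""
        c = Cohort(
            (
                make_individual(
                    "f", "female", {"egg": 2, "pupa": 3, "adult": 3},
                    eggs_by_age={7: 7},
                ),
                make_individual("d", "undetermined", {"egg": 2}),
            ),
            SHORT_ORDER,
        )
        _, fs = schedule_of(c)
        assert fs.m[7] == 7.0
        assert fs.m[1] == 0.0

    def test_no_females_no_fecundity(self):
        c = Cohort(
            (make_individual("m", "male", {"egg": 1, "pupa": 1, "adult": 2}),),
            SHORT_ORDER,
        )
        _, fs = schedule_of(c)
        assert np.all(fs.m == 0)
        assert net_reproductive_rate(fs) == 0.0

    def test_r0_equals_mean_lifetime_eggs(self, control_cohort):
        """sum_x l_x m_x == total eggs / N, an exact identity."""
        _, fs = schedule_of(control_cohort)
        total = sum(i.total_eggs for i in control_cohort.individuals)
        assert np.isclose(
            net_reproductive_rate(fs), total / control_cohort.N, atol=1e-12
        )

    def test_two_sex_identity(self, control_cohort, bbfs_cohort):
        """R0 = (adult females / N) * (mean eggs per adult female), exactly."""
        for c in (control_cohort, bbfs_cohort):
            _, fs = schedule_of(c)
            arrs = cohort_arrays(c)
            nf = arrs.is_adult_female.sum()
            mean_eggs = arrs.eggs[arrs.is_adult_female].sum() / nf
            assert np.isclose(
                net_reproductive_rate(fs), nf / c.N * mean_eggs, atol=1e-10
            )


class TestEulerLotka:
    def test_closed_form_point_mass(self):
        """l_x m_x = e concentrated at x=4: exp(-5r) e = 1 -> r = 0.2."""
        phi = np.zeros(6)
        phi[4] = math.e
        assert solve_euler(phi) == pytest.approx(0.2, abs=1e-12)

    def test_r0_of_one_gives_r_zero(self):
        phi = np.zeros(9)
        phi[7] = 1.0
        assert solve_euler(phi) == pytest.approx(0.0, abs=1e-12)

    def test_negative_r_when_r0_below_one(self):
        phi = np.zeros(4)
        phi[2] = 0.5
        r = solve_euler(phi)
        assert r < 0
        assert math.exp(-3 * r) * 0.5 == pytest.approx(1.0, abs=1e-9)

    def test_zero_schedule_raises(self):
        with pytest.raises(UndefinedParameterError):
            solve_euler(np.zeros(5))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_grid_search_oracle(self, seed):
        """Brent solution agrees with a dense grid search to 1e-6."""
        rng = np.random.default_rng(seed)
        phi = np.zeros(20)
        ages = rng.choice(np.arange(5, 20), size=4, replace=False)
        phi[ages] = rng.uniform(0.01, 3.0, size=4)
        r = solve_euler(phi)
        assert r == pytest.approx(grid_search_r(phi), abs=1e-6)

    def test_derived_rates(self):
        assert finite_rate(0.0) == 1.0
        assert mean_generation_time(math.e, 1.0) == pytest.approx(1.0)
        with pytest.raises(UndefinedParameterError):
            mean_generation_time(1.0, 0.0)
        with pytest.raises(ValueError):
            mean_generation_time(0.0, 0.1)


class TestPreadultSurvival:
    def test_extremes(self):
        none_adult = Cohort(
            (make_individual("a", "undetermined", {"egg": 2}),), SHORT_ORDER
        )
        assert preadult_survival(none_adult) == 0.0
        all_adult = Cohort(
            (make_individual("b", "male", {"egg": 1, "pupa": 1, "adult": 1}),),
            SHORT_ORDER,
        )
        assert preadult_survival(all_adult) == 1.0

    def test_matches_direct_count(self, control_cohort):
        direct = sum(
            1 for i in control_cohort.individuals if i.reached("adult")
        )
        assert preadult_survival(control_cohort) == direct / control_cohort.N


class TestTransitionModel:
    def test_deterministic_egg_development(self):
        c = Cohort(
            (
                make_individual("a", "male", {"egg": 2, "pupa": 1, "adult": 1}),
                make_individual("b", "male", {"egg": 2, "pupa": 1, "adult": 1}),
            ),
            SHORT_ORDER,
        )
        tm = transition_model(c)
        egg, pupa = 0, 1
        assert tm.p[0, egg, egg] == 1.0
        assert tm.p[1, egg, pupa] == 1.0

    def test_certain_death(self):
        c = Cohort(
            (make_individual("a", "undetermined", {"egg": 3}),
             make_individual("b", "male", {"egg": 1, "pupa": 1, "adult": 1}),),
            SHORT_ORDER,
        )
        tm = transition_model(c)
        assert tm.p[2, 0].sum() == 0.0  # P(die | egg at age 2) = 1

    def test_counts_match_brute_force_tally(self, control_cohort):
        tm = transition_model(control_cohort)
        arrs = cohort_arrays(control_cohort)
        x = 5
        alive_states = arrs.state[arrs.state[:, x] >= 0, x]
        j = int(alive_states[0])
        here = arrs.state[:, x] == j
        for k in range(len(tm.states)):
            expected = np.sum(arrs.state[here, x + 1] == k) / here.sum()
            assert tm.p[x, j, k] == pytest.approx(expected)


class TestLifeExpectancy:
    def test_deterministic_remaining_days(self):
        """Everyone lives exactly the same schedule: e_xj counts today plus the rest."""
        c = Cohort(
            (
                make_individual("a", "male", {"egg": 2, "pupa": 2, "adult": 2}),
                make_individual("b", "male", {"egg": 2, "pupa": 2, "adult": 2}),
            ),
            SHORT_ORDER,
        )
        e = life_expectancy(transition_model(c))
        assert e[0, 0] == 6.0
        assert e[2, 1] == 4.0
        assert e[5, 3] == 1.0  # adult_male column, last alive day

    def test_e0_is_mean_lifespan(self, control_cohort, bbfs_cohort):
        for c in (control_cohort, bbfs_cohort):
            e = life_expectancy(transition_model(c))
            mean_lifespan = np.mean([i.lifespan for i in c.individuals])
            assert e[0, 0] == pytest.approx(mean_lifespan, abs=1e-9)

    def test_unoccupied_cells_masked(self, tiny_cohort):
        e = life_expectancy(transition_model(tiny_cohort))
        assert e.mask[0, 1]  # nobody is a larva at age 0


class TestReproductiveValue:
    def test_v0_equals_lambda(self, control_cohort):
        s, fs = schedule_of(control_cohort)
        r = intrinsic_rate(fs)
        v = reproductive_value(transition_model(control_cohort), fs, r)
        assert v[0, 0] == pytest.approx(math.exp(r), abs=1e-9)

    def test_post_reproductive_value_zero(self):
        c = Cohort(
            (
                make_individual(
                    "f", "female", {"egg": 1, "pupa": 1, "adult": 4},
                    eggs_by_age={2: 6, 3: 4},
                ),
            ),
            SHORT_ORDER,
        )
        s, fs = schedule_of(c)
        r = intrinsic_rate(fs)
        v = reproductive_value(transition_model(c), fs, r)
        adult_col = list(c.states).index("adult_female")
        assert v[4, adult_col] == pytest.approx(0.0, abs=1e-12)
        assert v[2, adult_col] > 0


class TestStageCollapse:
    def test_population_parameters_invariant(self, control_cohort):
        """R0, r, lambda, T depend only on l_x and m_x, not the stage partition."""
        mapping = {s: "juvenile" for s in ("L1", "L2", "L3", "L4", "pupa")}
        collapsed = collapse_stages(
            control_cohort, mapping, ("egg", "juvenile", "adult")
        )
        d7 = compute_demography(control_cohort)
        d3 = compute_demography(collapsed)
        assert d3.R0 == pytest.approx(d7.R0, abs=1e-12)
        assert d3.r == pytest.approx(d7.r, abs=1e-12)
        assert d3.lam == pytest.approx(d7.lam, abs=1e-12)
        assert d3.T == pytest.approx(d7.T, abs=1e-10)


class TestMonotonicity:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_extra_egg_increases_r0(self, seed):
        """Adding one egg to any adult-female day raises R0 by exactly 1/N."""
        from dataclasses import replace

        c = simulate_cohort(load_preset("control", n=40), seed=seed)
        base = compute_demography(c).R0
        rng = np.random.default_rng(seed)
        females = [
            (i, k)
            for i, ind in enumerate(c.individuals)
            for k, o in enumerate(ind.observations)
            if o.alive and o.stage == "adult" and ind.sex == "female"
        ]
        if not females:
            return
        i, k = females[rng.integers(len(females))]
        ind = c.individuals[i]
        obs = list(ind.observations)
        obs[k] = replace(obs[k], eggs=obs[k].eggs + 1)
        bumped = Cohort(
            c.individuals[:i]
            + (replace(ind, observations=tuple(obs)),)
            + c.individuals[i + 1 :],
            c.stage_order,
        )
        assert compute_demography(bumped).R0 == pytest.approx(
            base + 1.0 / c.N, abs=1e-12
        )

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_removing_nonreproducer_increases_r0(self, seed):
        c = simulate_cohort(load_preset("control", n=40), seed=seed)
        base = compute_demography(c).R0
        if base == 0:
            return
        idx = [i for i, ind in enumerate(c.individuals) if ind.total_eggs == 0]
        if not idx:
            return
        i = idx[np.random.default_rng(seed).integers(len(idx))]
        reduced = Cohort(
            c.individuals[:i] + c.individuals[i + 1 :], c.stage_order
        )
        assert compute_demography(reduced).R0 >= base
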