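"""Cohort schedules, Euler-Lotka solver, stage periods and bootstrap SEs."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aphidfit.lifetable import (
    Cohort,
    DemographySchedules,
    IndividualRecord,
    bootstrap_population_parameters,
    build_schedules,
    finite_rate,
    life_table_report,
    mean_generation_time,
    net_reproductive_rate,
    read_report,
    solve_intrinsic_rate,
    stage_period_stats,
    write_report,
)

from conftest import make_individual


def schedules(l, m):
    l = np.asarray(l, dtype=float)
    m = np.asarray(m, dtype=float)
    s = np.zeros((len(l), 5))
    s[:, 4] = l  # park all survivors in the adult column
    return DemographySchedules(max_age=len(l) - 1, l_x=l, m_x=m, s_xj=s)


# ---------------------------------------------------------------------------
# record and cohort validation


def test_offspring_before_adult_entry_rejected():
    with pytest.raises(ValueError, match="before adult entry"):
        make_individual("x", None, 3, {1: 2})


def test_negative_offspring_rejected():
    with pytest.raises(ValueError, match="negative offspring"):
        IndividualRecord("x", {"N1": 0}, 1, (0, -1))


def test_duplicate_ids_rejected():
    a = make_individual("same", 1, 2, {1: 1})
    with pytest.raises(ValueError, match="duplicate"):
        Cohort(records=(a, a))


def test_empty_cohort_rejected():
    with pytest.raises(ValueError, match="empty"):
        Cohort(records=())


# ---------------------------------------------------------------------------
# schedules


def test_single_individual_schedules_identity():
    c = Cohort(records=(make_individual("a", 2, 2, {2: 3}),))
    s = build_schedules(c)
    assert np.allclose(s.l_x, [1, 1, 1])
    assert np.allclose(s.m_x, [0, 0, 3])


def test_two_individual_hand_count(two_individual_cohort):
    s = build_schedules(two_individual_cohort)
    assert np.allclose(s.l_x, [1, 1, 0.5, 0.5])
    assert np.allclose(s.m_x, [0, 1, 4, 0])
    # stage occupancies sum to l_x at every age
    assert np.allclose(s.s_xj.sum(axis=1), s.l_x)


def test_offspring_conservation_identity(rng):
    # Σ_x l_x m_x = total offspring / n for any cohort
    records = []
    total = 0
    for i in range(30):
        death = int(rng.integers(0, 15))
        adult = int(rng.integers(0, death + 1))
        off = {int(a): int(rng.integers(0, 5)) for a in range(adult, death + 1)}
        total += sum(off.values())
        records.append(make_individual(i, adult, death, off))
    c = Cohort(records=tuple(records))
    s = build_schedules(c)
    assert net_reproductive_rate(s) == pytest.approx(total / 30, abs=1e-12)


# ---------------------------------------------------------------------------
# R0, r, lambda, T


def test_r0_no_reproduction():
    assert net_reproductive_rate(schedules([1], [0])) == 0


def test_r0_hand_value(two_individual_cohort):
    assert net_reproductive_rate(build_schedules(two_individual_cohort)) == pytest.approx(3)


def grid_bisection_oracle(l, m, lo=0.0, hi=3.0, offset=1):
    """Independent dense-grid + bisection root finder for the Euler-Lotka sum."""
    ages = np.arange(len(l)) + offset

    def f(r):
        return sum(math.exp(-r * a) * li * mi for a, li, mi in zip(ages, l, m)) - 1.0

    grid = np.linspace(lo, hi, 20001)
    vals = [f(r) for r in grid]
    for i in range(len(grid) - 1):
        if vals[i] > 0 >= vals[i + 1]:
            a, b = grid[i], grid[i + 1]
            break
    else:
        raise AssertionError("oracle failed to bracket")
    while b - a > 1e-14:
        mid = 0.5 * (a + b)
        if f(mid) > 0:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def test_point_mass_closed_form():
    # survival 1 to age a, fecundity f concentrated at age a: r = ln(f)/(a+1)
    for f, a in [(math.e, 0), (5.0, 3), (2.5, 7)]:
        l = [1.0] * (a + 1)
        m = [0.0] * a + [f]
        r = solve_intrinsic_rate(schedules(l, m))
        assert r == pytest.approx(math.log(f) / (a + 1), abs=1e-10)


def test_replacement_fertility_gives_zero():
    assert solve_intrinsic_rate(schedules([1.0], [1.0])) == pytest.approx(0, abs=1e-10)


def test_solver_matches_grid_oracle():
    l = [1.0, 1.0, 1.0]
    m = [0.0, 2.0, 4.0]
    r = solve_intrinsic_rate(schedules(l, m))
    assert r == pytest.approx(grid_bisection_oracle(l, m), abs=1e-10)


def test_no_reproduction_raises():
    with pytest.raises(ValueError, match="no reproduction"):
        solve_intrinsic_rate(schedules([1.0, 0.5], [0.0, 0.0]))


def test_exponent_convention_switch():
    l = [1.0, 1.0, 1.0]
    m = [0.0, 2.0, 4.0]
    r_shifted = solve_intrinsic_rate(schedules(l, m), exponent_offset=1)
    r_bare = solve_intrinsic_rate(schedules(l, m), exponent_offset=0)
    assert r_bare > r_shifted  # same schedule discounts one day less
    assert r_bare == pytest.approx(grid_bisection_oracle(l, m, offset=0), abs=1e-10)


@given(
    st.lists(
        st.one_of(st.just(0.0), st.floats(0.01, 6.0)), min_size=1, max_size=12
    ),
    st.floats(0.01, 1.0),
)
def test_euler_lotka_residual_property(ms, survival_step):
    """|Σ e^{-r(x+1)} l_x m_x - 1| < 1e-10 for every solvable random schedule."""
    if sum(ms) == 0:
        return
    l = [max(0.0, 1.0 - survival_step * x / len(ms)) for x in range(len(ms))]
    l[0] = 1.0
    m = [mi if li > 0 else 0.0 for mi, li in zip(ms, l)]
    if sum(li * mi for li, mi in zip(l, m)) <= 0:
        return
    sched = schedules(l, m)
    r = solve_intrinsic_rate(sched)
    ages = np.arange(len(l)) + 1
    residual = abs(float(np.exp(-r * ages) @ (sched.l_x * sched.m_x)) - 1.0)
    assert residual < 1e-10


def test_r_monotone_in_fecundity(rng):
    l = [1.0, 0.9, 0.8, 0.7]
    m = [0.0, 1.0, 2.0, 1.0]
    r0 = solve_intrinsic_rate(schedules(l, m))
    for i in range(1, 4):
        bumped = list(m)
        bumped[i] += rng.uniform(0.1, 2.0)
        assert solve_intrinsic_rate(schedules(l, bumped)) > r0


@pytest.mark.parametrize(
    "r, expected",
    [(0.0, 1.0), (0.38, 1.46), (0.30, 1.35), (0.25, 1.28), (0.17, 1.19), (0.29, 1.34), (0.22, 1.25)],
)
def test_finite_rate(r, expected):
    assert round(finite_rate(r), 2) == expected


def test_mean_generation_time():
    assert mean_generation_time(math.e, 1.0) == pytest.approx(1.0)
    assert mean_generation_time(math.e**2, 0.5) == pytest.approx(4.0)
    with pytest.raises(ValueError, match="undefined at replacement"):
        mean_generation_time(2.0, 0.0)


def test_generation_time_composition(two_individual_cohort):
    s = build_schedules(two_individual_cohort)
    r = solve_intrinsic_rate(s)
    assert mean_generation_time(3.0, r) == pytest.approx(
        math.log(3) / grid_bisection_oracle([1, 1, 0.5, 0.5], [0, 1, 4, 0]), abs=1e-9
    )


# ---------------------------------------------------------------------------
# periods


def test_stage_periods_day_counting():
    c = Cohort(records=(make_individual("a", 7, 24, {8: 1}),))
    p = stage_period_stats(c)
    assert p.nymph_period == 7
    assert p.adult_period == 18
    assert p.total_longevity == 25


def test_nymph_death_excluded_from_periods():
    c = Cohort(
        records=(
            make_individual("adult", 7, 24, {8: 1}),
            make_individual("nymph", None, 3, stages={"N2": 2}),
        )
    )
    p = stage_period_stats(c)
    assert p.n_adults == 1
    assert p.nymph_period == 7  # nymph-only individual excluded
    assert p.total_longevity == pytest.approx((25 + 4) / 2)


def test_no_adults_undefined_periods():
    c = Cohort(records=(make_individual("n", None, 3, stages={"N2": 2}),))
    p = stage_period_stats(c)
    assert p.n_adults == 0
    assert math.isnan(p.nymph_period) and math.isnan(p.adult_period)


# ---------------------------------------------------------------------------
# bootstrap


def test_identical_individuals_all_ses_zero():
    recs = tuple(make_individual(i, 2, 4, {3: 5}) for i in range(10))
    pp = bootstrap_population_parameters(Cohort(records=recs), B=50, seed=1)
    for se in (pp.se_R0, pp.se_r, pp.se_lambda, pp.se_T,
               pp.se_nymph_period, pp.se_adult_period, pp.se_total_longevity):
        assert se == pytest.approx(0, abs=1e-12)


def test_bootstrap_deterministic_under_seed(two_individual_cohort):
    a = bootstrap_population_parameters(two_individual_cohort, B=300, seed=42)
    b = bootstrap_population_parameters(two_individual_cohort, B=300, seed=42)
    assert a == b


def test_bootstrap_point_estimates_from_original(two_individual_cohort):
    pp = bootstrap_population_parameters(two_individual_cohort, B=100, seed=0)
    s = build_schedules(two_individual_cohort)
    assert pp.R0 == net_reproductive_rate(s)
    assert pp.r == pytest.approx(solve_intrinsic_rate(s), abs=1e-10)
    assert pp.lambda_ == pytest.approx(math.exp(pp.r))
    assert pp.T == pytest.approx(math.log(pp.R0) / pp.r)


def test_degenerate_resamples_counted():
    # one childless individual: resamples drawing only it have no offspring
    c = Cohort(
        records=(
            make_individual("fertile", 1, 2, {2: 3}),
            make_individual("childless", 1, 2),
        )
    )
    pp = bootstrap_population_parameters(c, B=500, seed=3)
    assert pp.n_degenerate > 0  # P(all-childless resample) = 0.25 per draw
    assert math.isfinite(pp.se_r)


def test_bootstrap_requires_b_at_least_two(two_individual_cohort):
    with pytest.raises(ValueError, match="B must be"):
        bootstrap_population_parameters(two_individual_cohort, B=1)


# ---------------------------------------------------------------------------
# report


def test_report_lambda_consistent_and_roundtrips(tmp_path, two_individual_cohort):
    pp = bootstrap_population_parameters(two_individual_cohort, B=100, seed=0)
    assert pp.lambda_ == pytest.approx(math.exp(pp.r))  # invariant behind the cells
    rep = life_table_report([pp])
    assert rep.shape == (7, 1)
    out = tmp_path / "report.tsv"
    write_report(rep, out)
    back = read_report(out)
    assert back.equals(rep)
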