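import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dspom import (
    HydroParams,
    SpeciesTraits,
    colonization_rate,
    event_probability,
    extinction_rate,
    landscape_matrix,
    metapopulation_capacity,
    persistence_condition,
    run_dspom,
    run_static_spom,
    simulate_hydrology,
    step_occupancy,
    suitability_from_hydro,
)
from dspom.forcing import ForcingSeries


def test_traits_invariants():
    with pytest.raises(ValueError):
        SpeciesTraits(e=-1, c=1, D=100)
    with pytest.raises(ValueError):
        SpeciesTraits(e=1, c=1, D=0)


def test_colonization_rate_cases():
    traits = SpeciesTraits(e=0.0, c=1.0, D=100.0)
    S = np.ones(3)
    d_row = np.array([0.0, 0.0, 50.0])
    # no occupied neighbours
    assert colonization_rate(0, np.zeros(3), S, d_row, traits) == 0.0
    # one occupied neighbour at zero gap with unit suitability and c = 1
    assert colonization_rate(0, np.array([0, 1, 0]), S, d_row, traits) == pytest.approx(1.0)
    # own state excluded from the sum
    assert colonization_rate(0, np.array([1, 0, 0]), S, d_row, traits) == 0.0
    # worked value: c = 1.5, one neighbour at d = 1.5 D
    traits = SpeciesTraits(e=0.0, c=1.5, D=100.0)
    rate = colonization_rate(
        0, np.array([0, 1]), np.ones(2), np.array([0.0, 150.0]), traits
    )
    assert rate == pytest.approx(1.5 * np.exp(-1.5), rel=1e-12)


def test_extinction_rate_cases():
    traits = SpeciesTraits(e=0.0002, c=1.5, D=100.0)
    assert extinction_rate(1.0, traits) == pytest.approx(0.0002)
    assert extinction_rate(0.5, traits) == pytest.approx(0.0004)
    assert extinction_rate(0.0, traits) == np.inf
    assert event_probability(extinction_rate(0.0, traits)) == 1.0


def test_event_probability():
    assert event_probability(0.0) == 0.0
    assert event_probability(np.inf) == 1.0
    assert event_probability(0.1, 1.0) == pytest.approx(1 - np.exp(-0.1), rel=1e-12)
    assert 0.0 <= event_probability(1e6) <= 1.0


def test_landscape_matrix_structure():
    S = np.array([0.0, 0.0, 0.0])
    d = np.zeros((3, 3))
    assert np.all(landscape_matrix(S, d, 100.0) == 0.0)
    # n = 1: zero diagonal
    assert landscape_matrix(np.array([2.0]), np.zeros((1, 1)), 10.0) == np.zeros((1, 1))
    # two-patch closed form
    S = np.array([0.7, 0.7])
    d = np.array([[0.0, 120.0], [120.0, 0.0]])
    M = landscape_matrix(S, d, 80.0)
    assert M[0, 1] == pytest.approx(0.49 * np.exp(-1.5), rel=1e-12)


def test_metapopulation_capacity_against_general_eigensolver():
    """Leading eigenvalue matches the general (non-symmetric) eig route."""
    rng = np.random.default_rng(99)
    assert metapopulation_capacity(np.zeros((4, 4))) == 0.0
    for _ in range(100):
        n = int(rng.integers(2, 13))
        raw = rng.random((n, n))
        M = (raw + raw.T) / 2
        np.fill_diagonal(M, 0.0)
        oracle = float(np.max(np.real(np.linalg.eig(M).eigenvalues)))
        got = metapopulation_capacity(M)
        assert got == pytest.approx(oracle, rel=1e-10)
    # two-patch closed form: eigenvalues are +/- m12
    S, d, D = 0.8, 90.0, 60.0
    M = landscape_matrix(np.array([S, S]), np.array([[0, d], [d, 0.0]]), D)
    assert metapopulation_capacity(M) == pytest.approx(S**2 * np.exp(-d / D), rel=1e-12)


def test_metapopulation_capacity_rejects_asymmetric():
    M = np.array([[0.0, 1.0], [0.5, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        metapopulation_capacity(M)


def test_persistence_condition():
    traits = SpeciesTraits(e=0.0002, c=1.5, D=100.0)
    threshold = traits.e / traits.c
    assert threshold == pytest.approx(0.0002 / 1.5)
    assert persistence_condition(threshold * 1.01, traits) is True
    assert persistence_condition(threshold * 0.99, traits) is False
    assert persistence_condition(0.0, traits) is False
    assert persistence_condition(1.0, SpeciesTraits(e=0.0, c=1.0, D=1.0)) is True
    assert persistence_condition(1.0, SpeciesTraits(e=1.0, c=0.0, D=1.0)) is False
    assert persistence_condition(1.0, SpeciesTraits(e=0.0, c=0.0, D=1.0)) is None


@given(
    d_scale=st.floats(10.0, 500.0),
    D1=st.floats(10.0, 200.0),
    bump=st.floats(0.0, 3.0),
    s_bump=st.floats(0.0, 2.0),
)
@settings(derandomize=True, max_examples=100)
def test_capacity_perron_monotonicity(d_scale, D1, bump, s_bump):
    """lambda_max non-decreasing in D and in pointwise S increases."""
    rng = np.random.default_rng(17)
    n = 6
    xy = rng.random((n, 2)) * d_scale
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    S = rng.random(n) + 0.1
    lam1 = metapopulation_capacity(landscape_matrix(S, d, D1))
    lam2 = metapopulation_capacity(landscape_matrix(S, d, D1 + bump))
    assert lam2 >= lam1 - 1e-12
    S_up = S.copy()
    S_up[2] += s_bump
    lam3 = metapopulation_capacity(landscape_matrix(S_up, d, D1))
    assert lam3 >= lam1 - 1e-12


def test_step_occupancy_frozen_and_absorbing():
    rng = np.random.default_rng(0)
    n = 5
    d = np.zeros((n, n))
    S = np.ones(n)
    p = np.array([1, 0, 1, 0, 1], dtype=bool)
    frozen = SpeciesTraits(e=0.0, c=0.0, D=10.0)
    np.testing.assert_array_equal(step_occupancy(p, S, d, frozen, 1.0, rng), p)
    # all S = 0: everything extinct next step, nothing colonised
    traits = SpeciesTraits(e=0.001, c=5.0, D=10.0)
    out = step_occupancy(p, np.zeros(n), d, traits, 1.0, rng)
    assert not out.any()


def test_single_patch_extinction_time_geometric():
    """Mean extinction time over 1e4 chains matches the geometric mean 1/P_E."""
    traits = SpeciesTraits(e=0.05, c=0.0, D=10.0)
    p_e = event_probability(traits.e / 1.0)
    rng = np.random.default_rng(5)
    R = 10_000
    p = np.ones((R, 1), dtype=bool)
    S = np.ones(1)
    d = np.zeros((1, 1))
    times = np.zeros(R)
    alive = np.ones(R, dtype=bool)
    for t in range(1, 2000):
        p = step_occupancy(p, S, d, traits, 1.0, rng)
        died = alive & ~p[:, 0]
        times[died] = t
        alive &= p[:, 0]
        if not alive.any():
            break
    expected = 1.0 / p_e
    se = np.sqrt((1 - p_e) / p_e**2 / R)
    assert abs(times.mean() - expected) < 3 * se


def _constant_hydro(landscape, T=120):
    forcing = ForcingSeries(rain=np.zeros(T), pet=np.zeros(T))
    return simulate_hydrology(landscape, forcing, HydroParams(k_leak=0.0), h0="full")


def test_dspom_determinism(small_landscape, fluctuating_hydro):
    traits = SpeciesTraits(e=0.01, c=0.05, D=300.0)
    a = run_dspom(small_landscape, fluctuating_hydro, traits, n_realizations=2, seed=21)
    b = run_dspom(small_landscape, fluctuating_hydro, traits, n_realizations=2, seed=21)
    np.testing.assert_array_equal(a[0].p, b[0].p)
    np.testing.assert_allclose(a[1].lambda_max, b[1].lambda_max)


def test_static_dynamic_degeneracy(small_landscape):
    """Under time-constant hydrology the two engines coincide step by step."""
    hydro = _constant_hydro(small_landscape)
    traits = SpeciesTraits(e=0.02, c=0.05, D=300.0)
    dyn, cap_dyn = run_dspom(small_landscape, hydro, traits, n_realizations=5, seed=33)
    stat, cap_stat = run_static_spom(small_landscape, hydro, traits, n_realizations=5, seed=33)
    np.testing.assert_array_equal(dyn.p, stat.p)
    np.testing.assert_allclose(cap_dyn.lambda_max, cap_stat.lambda_max, rtol=1e-9)
    # the static capacity is constant in time by construction
    assert np.ptp(cap_stat.lambda_max) <= 1e-9 * cap_stat.lambda_max[0]


def test_omega_monotone_in_degenerate_trait_limits(small_landscape):
    hydro = _constant_hydro(small_landscape)
    # e = 0: occupancy can only grow, per realization
    grow = SpeciesTraits(e=0.0, c=0.02, D=300.0)
    ens, _ = run_dspom(small_landscape, hydro, grow, n_realizations=10, p0=0.3, seed=8)
    counts = ens.p.sum(axis=2)
    assert np.all(np.diff(counts, axis=1) >= 0)
    # c = 0: occupancy can only shrink
    shrink = SpeciesTraits(e=0.05, c=0.0, D=300.0)
    ens2, _ = run_dspom(small_landscape, hydro, shrink, n_realizations=10, seed=8)
    counts2 = ens2.p.sum(axis=2)
    assert np.all(np.diff(counts2, axis=1) <= 0)
    # global extinction is absorbing
    empty = counts2 == 0
    for r in range(empty.shape[0]):
        if empty[r].any():
            first = int(np.argmax(empty[r]))
            assert empty[r, first:].all()


def test_fs_monotone_in_traits_common_random_numbers(small_landscape):
    """f_S falls with e and rises with c, under common random numbers."""
    hydro = _constant_hydro(small_landscape, T=400)
    fs = {}
    for e in (0.02, 0.2):
        ens, _ = run_dspom(
            small_landscape, hydro, SpeciesTraits(e=e, c=0.01, D=300.0),
            n_realizations=40, seed=13,
        )
        fs[e] = ens.f_S
    assert fs[0.2] <= fs[0.02]
    fs_c = {}
    for c in (0.005, 0.05):
        ens, _ = run_dspom(
            small_landscape, hydro, SpeciesTraits(e=0.05, c=c, D=300.0),
            n_realizations=40, seed=13,
        )
        fs_c[c] = ens.f_S
    assert fs_c[0.05] >= fs_c[0.005]


def test_ensemble_summaries(small_landscape, fluctuating_hydro):
    traits = SpeciesTraits(e=0.01, c=0.05, D=300.0)
    ens, cap = run_dspom(small_landscape, fluctuating_hydro, traits, n_realizations=4, seed=2)
    assert ens.p.shape == (4, fluctuating_hydro.n_days, len(small_landscape))
    assert np.all((ens.omega >= 0) & (ens.omega <= 1))
    np.testing.assert_allclose(ens.omega, ens.p.mean(axis=(0, 2)))
    assert 0.0 <= ens.f_S <= 1.0
    assert np.all(cap.lambda_max >= 0)


def test_suitability_rules(fluctuating_hydro):
    S = suitability_from_hydro(fluctuating_hydro, "area")
    assert S.shape == fluctuating_hydro.A.shape
    assert np.all(S >= 0)
    # zone suitabilities telescope to the whole-area suitability
    total = sum(
        suitability_from_hydro(fluctuating_hydro, rule, reference_area=1.0)
        for rule in ("shallow", "intermediate", "deep")
    )
    np.testing.assert_allclose(total, fluctuating_hydro.A, rtol=1e-12, atol=1e-9)
    with pytest.raises(ValueError):
        suitability_from_hydro(fluctuating_hydro, "bogus")
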