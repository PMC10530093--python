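import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnawaxs.decomposition import (BasisSet, KineticParams,
                                   band_trajectory, decompose_series,
                                   fit_fractions, sequential_kinetics)
from rnawaxs.profiles import ScatteringProfile


# ---------------------------------------------------------------------------
# sequential first-order kinetics
# ---------------------------------------------------------------------------

def test_kinetics_boundary_values():
    f0 = sequential_kinetics(0.0)
    np.testing.assert_allclose(f0, [1.0, 0.0, 0.0], atol=1e-12)
    f_inf = sequential_kinetics(1e6)
    np.testing.assert_allclose(f_inf, [0.0, 0.0, 1.0], atol=1e-9)


def test_duplex_transient_peaks_at_analytic_time():
    params = KineticParams(k1=300.0, k2=60.0)
    t_star = params.t_duplex_max_ms
    assert t_star == pytest.approx(np.log(300 / 60) / (300 - 60) * 1000,
                                   rel=1e-12)
    assert t_star == pytest.approx(6.7, abs=0.05)
    t = np.linspace(0.0, 50.0, 2001)
    f = sequential_kinetics(t, params)
    assert t[np.argmax(f[:, 1])] == pytest.approx(t_star, abs=0.05)


def test_equal_rates_limit_continuous():
    """k1 = k2 uses the analytic limiting form k1*t*exp(-k1*t)."""
    p_eq = KineticParams(k1=100.0, k2=100.0)
    p_near = KineticParams(k1=100.0, k2=100.0 + 1e-4)
    t = np.linspace(0.0, 100.0, 101)
    np.testing.assert_allclose(sequential_kinetics(t, p_eq),
                               sequential_kinetics(t, p_near), atol=1e-6)
    f = sequential_kinetics(10.0, p_eq)
    assert f[1] == pytest.approx(100.0 * 0.010 * np.exp(-1.0), rel=1e-9)


@settings(derandomize=True, max_examples=100)
@given(st.floats(min_value=0.0, max_value=1e4),
       st.floats(min_value=1e-2, max_value=1e3),
       st.floats(min_value=1e-2, max_value=1e3))
def test_kinetic_closure_and_bounds(t, k1, k2):
    """Fractions stay in [0, 1] and sum to exactly 1 for all t, k1, k2."""
    f = sequential_kinetics(t, KineticParams(k1=k1, k2=k2))
    assert f.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(f >= -1e-12) and np.all(f <= 1.0 + 1e-12)


def test_negative_time_rejected():
    with pytest.raises(ValueError):
        sequential_kinetics(-1.0)


# ---------------------------------------------------------------------------
# mixture fitting
# ---------------------------------------------------------------------------

def _toy_basis():
    q = np.linspace(0.1, 2.2, 300)
    return BasisSet({
        "unstructured": ScatteringProfile(q, np.exp(-1.5 * q) + 0.2),
        "duplex": ScatteringProfile(q, np.exp(-q) * (1 + 0.3 * np.cos(6 * q))),
        "triplex": ScatteringProfile(q, np.exp(-0.8 * q) * (1 + 0.4 * np.sin(7 * q))),
    })


def test_pure_state_identity():
    basis = _toy_basis()
    fit = fit_fractions(basis.profiles["triplex"], basis)
    assert fit["fractions"]["triplex"] == pytest.approx(1.0, abs=1e-9)
    assert fit["fractions"]["unstructured"] == pytest.approx(0.0, abs=1e-9)
    assert fit["residual"] == pytest.approx(0.0, abs=1e-8)


def test_noiseless_round_trip_exact():
    basis = _toy_basis()
    q = basis.qgrid
    truth = np.array([0.3, 0.5, 0.2])
    _, A = basis.matrix()
    mix = ScatteringProfile(q, A @ truth)
    fit = fit_fractions(mix, basis)
    got = np.array([fit["fractions"][l] for l in basis.labels])
    np.testing.assert_allclose(got, truth, atol=1e-9)


def test_many_random_noiseless_mixtures_recovered():
    basis = _toy_basis()
    rng = np.random.default_rng(0)
    _, A = basis.matrix()
    q = basis.qgrid
    worst = 0.0
    for _ in range(100):
        truth = rng.dirichlet(np.ones(3))
        fit = fit_fractions(ScatteringProfile(q, A @ truth), basis)
        got = np.array([fit["fractions"][l] for l in basis.labels])
        worst = max(worst, np.abs(got - truth).max())
    assert worst < 1e-8


def test_noisy_mixture_within_tolerance():
    """SNR 30 per bin: each fraction within 0.05, median error < 0.03."""
    basis = _toy_basis()
    rng = np.random.default_rng(1)
    _, A = basis.matrix()
    q = basis.qgrid
    errs = []
    for i in range(20):
        truth = rng.dirichlet(np.ones(3))
        clean = A @ truth
        noisy = clean + rng.normal(0.0, clean / 30.0)
        fit = fit_fractions(ScatteringProfile(q, noisy), basis)
        got = np.array([fit["fractions"][l] for l in basis.labels])
        errs.append(np.abs(got - truth))
    errs = np.array(errs)
    assert errs.max() <= 0.05
    assert np.median(errs) < 0.03


def test_sum1_mode_exactly_normalized():
    basis = _toy_basis()
    q = basis.qgrid
    _, A = basis.matrix()
    mix = ScatteringProfile(q, 3.7 * (A @ np.array([0.2, 0.3, 0.5])))
    fit = fit_fractions(mix, basis, mode="nonneg-sum1")
    total = sum(fit["fractions"].values())
    assert total == pytest.approx(1.0, abs=1e-9)
    assert fit["fractions"]["triplex"] == pytest.approx(0.5, abs=1e-6)


def test_collinear_basis_names_the_pair():
    q = np.linspace(0.1, 2.0, 100)
    base = np.exp(-q)
    bad = BasisSet({"unstructured": ScatteringProfile(q, base),
                    "duplex": ScatteringProfile(q, 2.0 * base),
                    "triplex": ScatteringProfile(q, np.exp(-2 * q))})
    with pytest.raises(ValueError, match="'unstructured' and 'duplex'"):
        fit_fractions(ScatteringProfile(q, base), bad)


def test_decompose_series_orders_time_points():
    basis = _toy_basis()
    q = basis.qgrid
    _, A = basis.matrix()
    pts = [(10.0, ScatteringProfile(q, A @ np.array([0.0, 1.0, 0.0]))),
           (0.0, ScatteringProfile(q, A @ np.array([1.0, 0.0, 0.0])))]
    res = decompose_series(pts, basis)
    assert list(res.t_ms) == [0.0, 10.0]
    df = res.to_frame()
    assert df.loc[0, "f_unstructured"] == pytest.approx(1.0, abs=1e-9)
    assert df.loc[1, "f_duplex"] == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# band trajectories
# ---------------------------------------------------------------------------

def test_constant_series_constant_trajectory():
    q = np.arange(0.3, 2.2, 0.005)
    I = (q / 0.3) ** -2 + 0.3 * np.exp(-0.5 * ((q - 0.8) / 0.04) ** 2)
    prof = ScatteringProfile(q, I)
    t, amp = band_trajectory([(0.0, prof), (10.0, prof), (50.0, prof)],
                             "major-groove")
    assert np.all(amp == amp[0]) and amp[0] > 0


def test_band_outside_grid_rejected():
    q = np.arange(0.9, 2.0, 0.005)
    prof = ScatteringProfile(q, np.exp(-q))
    with pytest.raises(ValueError, match="outside"):
        band_trajectory([(0.0, prof), (1.0, prof)], "major-groove")


def test_single_time_point_rejected():
    q = np.arange(0.3, 2.2, 0.005)
    prof = ScatteringProfile(q, np.exp(-q))
    with pytest.raises(ValueError, match="two"):
        band_trajectory([(0.0, prof)], "major-groove")
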