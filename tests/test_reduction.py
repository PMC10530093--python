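import numpy as np
import pytest
from scipy.optimize import brentq

from rnawaxs.profiles import ScatteringProfile
from rnawaxs.reduction import (DetectorGeometry, ShotStack, acquisition_time_s,
                               build_q_map, normalize_pulse, radial_average,
                               reduce_timepoint, select_shots)
from rnawaxs.synthetic import NoiseConfig, buffer_background, \
    simulate_timepoint_stack


# ---------------------------------------------------------------------------
# geometry / q map
# ---------------------------------------------------------------------------

def test_wavelength_from_energy():
    geom = DetectorGeometry(energy_kev=6.0)
    assert geom.wavelength_A == pytest.approx(2.0664, abs=1e-4)


def test_q_zero_at_beam_center():
    geom = DetectorGeometry(shape=(32, 32), beam_center=(10.0, 12.0),
                            pixel_mm=1.0)
    qmap = build_q_map(geom)
    assert qmap[10, 12] == 0.0


def test_instrument_edge_reaches_q24():
    """Numerically invert q(r) at 6 keV, 106 mm: q = 2.4 at r ~ 111.7 mm."""
    lam = 12.3984 / 6.0

    def q_of_r(r):
        return 4.0 * np.pi / lam * np.sin(0.5 * np.arctan2(r, 106.0))

    r = brentq(lambda r: q_of_r(r) - 2.4, 1.0, 400.0)
    assert r == pytest.approx(111.7, abs=0.5)
    # and the default geometry covers 0.12-2.4
    geom = DetectorGeometry()
    qmap = build_q_map(geom)
    assert qmap.max() >= 2.4


def test_radial_average_matches_bruteforce_oracle():
    """Tiny frame averaged against a per-pixel double loop."""
    rng = np.random.default_rng(4)
    geom = DetectorGeometry(shape=(16, 16), pixel_mm=8.0,
                            beam_center=(0.0, 0.0))
    frame = rng.poisson(50.0, size=(16, 16)).astype(float)
    nbins = 10
    prof = radial_average(frame, geom, nbins=nbins)
    qmap = build_q_map(geom)
    qlo, qhi = qmap.min(), qmap.max()
    edges = np.linspace(qlo, qhi, nbins + 1)
    sums = np.zeros(nbins)
    counts = np.zeros(nbins)
    for i in range(16):
        for j in range(16):
            b = min(int((qmap[i, j] - qlo) / (qhi - qlo) * nbins), nbins - 1)
            sums[b] += frame[i, j]
            counts[b] += 1
    expected = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    np.testing.assert_allclose(prof.I, expected, rtol=1e-12)


def test_radial_average_uniform_and_ring():
    geom = DetectorGeometry(shape=(64, 64), pixel_mm=2.0,
                            beam_center=(0.0, 0.0))
    flat = radial_average(np.full((64, 64), 7.0), geom, nbins=20)
    valid = ~np.isnan(flat.I)
    np.testing.assert_allclose(flat.I[valid], 7.0)

    qmap = build_q_map(geom)
    target = 0.5 * (qmap.min() + qmap.max())
    ring = ((np.abs(qmap - target) < 0.02)).astype(float) * 100.0
    prof = radial_average(ring, geom, nbins=20)
    hot = np.nanargmax(prof.I)
    assert abs(prof.q[hot] - target) < (prof.q[1] - prof.q[0]) * 1.5


def test_all_masked_rejected():
    geom = DetectorGeometry(shape=(16, 16), mask=np.ones((16, 16), bool))
    with pytest.raises(ValueError, match="masked"):
        radial_average(np.ones((16, 16)), geom, nbins=10)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalize_pulse_homogeneity():
    prof = ScatteringProfile(np.linspace(0.1, 1, 10), np.arange(10.0))
    a = normalize_pulse(prof, 1.0)
    np.testing.assert_array_equal(a.I, prof.I)
    doubled = ScatteringProfile(prof.q, 2.0 * prof.I)
    b = normalize_pulse(doubled, 2.0)
    np.testing.assert_allclose(b.I, prof.I)
    with pytest.raises(ValueError):
        normalize_pulse(prof, 0.0)


def test_normalization_shrinks_jitter_variance(basis):
    """Post-normalization per-shot variance drops at every bin."""
    fr = {"unstructured": 1.0, "duplex": 0.0, "triplex": 0.0}
    noise = NoiseConfig(pulse_jitter_rel_sd=0.3, ice_rate=0.0)
    s, _, _ = simulate_timepoint_stack(fr, basis, 300, noise, seed=2)
    raw_var = s.profiles.var(axis=0)
    norm_var = (s.profiles / s.pulse_energy[:, None]).var(axis=0)
    assert np.all(norm_var < raw_var)


# ---------------------------------------------------------------------------
# shot selection
# ---------------------------------------------------------------------------

def _clean_stack(n=50, nbins=40, seed=0):
    rng = np.random.default_rng(seed)
    base = 100.0 + 10.0 * np.sin(np.linspace(0, 3, nbins))
    return rng.poisson(base, size=(n, nbins)).astype(float)


def test_clean_stack_fully_kept():
    keep, log = select_shots(_clean_stack(), spike_k=6.0, drift_m=5.0)
    assert keep.all()
    assert log.entries == []


def test_spike_and_drift_flagging():
    prof = _clean_stack(60)
    prof[7, 13] += 5000.0              # ice spike in one bin
    prof[21] *= 1.2                    # mild global drift: no bin stands
    keep, log = select_shots(prof)     # out, but the total does
    assert not keep[7] and not keep[21]
    assert (7, "spike") in log.entries
    assert (21, "drift") in log.entries
    assert keep.sum() == 58


def test_rejection_monotone_in_k():
    prof = _clean_stack(60)
    prof[5, 3] += 400.0
    keep_tight, _ = select_shots(prof, spike_k=4.0)
    keep_loose, _ = select_shots(prof, spike_k=1e9, drift_m=1e9)
    assert keep_loose.all()
    assert keep_tight.sum() <= keep_loose.sum()


def test_too_few_shots_rejected():
    with pytest.raises(ValueError, match="10"):
        select_shots(_clean_stack(5))


def test_ice_detection_sensitivity_and_specificity(basis):
    """>= 95% of contaminated frames flagged, <= 1% false positives at
    the default spike threshold (2,000 shots, 5% contamination)."""
    fr = {"unstructured": 0.0, "duplex": 0.0, "triplex": 1.0}
    noise = NoiseConfig(ice_rate=0.05)
    s, _, _ = simulate_timepoint_stack(fr, basis, 2000, noise, seed=9)
    norm = s.profiles / s.pulse_energy[:, None]
    keep, log = select_shots(norm, spike_k=6.0, drift_m=5.0)
    flags = s.truth["contaminated"]
    rejected = ~keep
    sens = rejected[flags].mean()
    fpr = rejected[~flags].mean()
    assert sens >= 0.95
    assert fpr <= 0.01


# ---------------------------------------------------------------------------
# full reduction
# ---------------------------------------------------------------------------

def test_self_subtraction_is_zero_within_noise(basis):
    fr = {"unstructured": 1.0, "duplex": 0.0, "triplex": 0.0}
    noise = NoiseConfig(ice_rate=0.0)
    _, b, _ = simulate_timepoint_stack(fr, basis, 400, noise, seed=5)
    as_sample = ShotStack(pulse_energy=b.pulse_energy, role="sample",
                          profiles=b.profiles, qgrid=b.qgrid)
    red = reduce_timepoint(as_sample, b)   # identical data both roles
    ok = np.abs(red.profile.I) <= 3.0 * red.profile.sigma
    assert ok.mean() >= 0.95


def test_scale_zero_returns_sample_mean(basis):
    fr = {"unstructured": 1.0, "duplex": 0.0, "triplex": 0.0}
    s, b, _ = simulate_timepoint_stack(fr, basis, 100,
                                       NoiseConfig(ice_rate=0.0), seed=6)
    red0 = reduce_timepoint(s, b, buffer_scale=0.0)
    norm = s.profiles / s.pulse_energy[:, None]
    keep, _ = select_shots(norm)
    np.testing.assert_allclose(red0.profile.I, norm[keep].mean(axis=0),
                               rtol=1e-12)


def test_signal_recovery_and_bookkeeping(basis):
    """Reduction of (buffer + known signal) recovers the signal within
    3 SEM almost everywhere, and kept + rejected = total per role."""
    fr = {"unstructured": 0.3, "duplex": 0.5, "triplex": 0.2}
    noise = NoiseConfig(ice_rate=0.05)
    s, b, truth = simulate_timepoint_stack(fr, basis, 2000, noise, seed=3)
    red = reduce_timepoint(s, b)
    for role, stack in (("sample", s), ("buffer", b)):
        assert red.n_kept[role] + red.n_rejected[role] == len(stack)
    ok = np.abs(red.profile.I - truth.generating_profile.I) \
        <= 3.0 * red.profile.sigma
    assert ok.mean() >= 0.95


def test_order_invariance(basis):
    fr = {"unstructured": 1.0, "duplex": 0.0, "triplex": 0.0}
    s, b, _ = simulate_timepoint_stack(fr, basis, 200,
                                       NoiseConfig(ice_rate=0.05), seed=8)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(s))
    s2 = ShotStack(pulse_energy=s.pulse_energy[perm], role="sample",
                   profiles=s.profiles[perm], qgrid=s.qgrid)
    r1 = reduce_timepoint(s, b)
    r2 = reduce_timepoint(s2, b)
    np.testing.assert_allclose(r1.profile.I, r2.profile.I, rtol=1e-12)
    assert r1.n_kept == r2.n_kept


def test_sem_scales_with_shot_count(basis):
    """Quadrupling clean shots halves the median SEM (within 10%)."""
    fr = {"unstructured": 1.0, "duplex": 0.0, "triplex": 0.0}
    noise = NoiseConfig(ice_rate=0.0)
    s1, b1, _ = simulate_timepoint_stack(fr, basis, 500, noise, seed=12)
    s4, b4, _ = simulate_timepoint_stack(fr, basis, 2000, noise, seed=13)
    m1 = np.median(reduce_timepoint(s1, b1).profile.sigma)
    m4 = np.median(reduce_timepoint(s4, b4).profile.sigma)
    assert m4 == pytest.approx(m1 / 2.0, rel=0.10)


def test_acquisition_time_matches_rate():
    assert acquisition_time_s(16000, 120.0) == pytest.approx(133.33, abs=0.01)


def test_buffer_background_shape():
    q = np.linspace(0.12, 2.4, 200)
    bg = buffer_background(q, photons=100.0)
    assert np.all(bg > 0)
    assert 1.6 <= q[np.argmax(bg)] <= 2.4   # broad water maximum near 2
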