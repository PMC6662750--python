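import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circaphase.datatypes import MINUTES_PER_DAY, UrineBlock, wrap_minutes
from circaphase.reference import (
    RAD_PER_MIN,
    BSBCFParams,
    CosineParams,
    ExcretionSeries,
    FitError,
    ImplausibleDriftError,
    UndefinedPhaseError,
    bsbcf,
    build_reference,
    center_of_gravity,
    compute_excretion_rate,
    cosine24,
    fit_bsbcf,
    fit_cosine,
    measured_phase_from_fit,
    window_start,
)

TWO_PI = 2 * math.pi


# ---------------------------------------------------------------------------
# BSBCF evaluation


def test_bsbcf_peak_is_b_plus_H():
    p = BSBCFParams(b=2.0, H=50.0, c=0.0, m=0.0, phi=1.0, v=0.0)
    assert bsbcf(p.phi, p) == pytest.approx(52.0)


def test_bsbcf_trough_is_b():
    p = BSBCFParams(b=2.0, H=50.0, c=0.0, m=0.0, phi=1.0, v=0.0)
    assert bsbcf(p.phi + math.pi, p) == pytest.approx(2.0)


def test_bsbcf_matches_independent_evaluation():
    # scalar re-implementation of the printed formula, term by term
    def oracle(t, b, H, c, m, phi, v):
        inner = math.cos(t - phi + v * math.cos(t - phi)) \
            + m * math.cos(2 * t - 2 * phi - math.pi) - c
        return b + H / (2 * (1 - c)) * (inner + abs(inner))

    p = BSBCFParams(b=3.0, H=40.0, c=0.1, m=0.2, phi=2.0, v=0.5)
    ts = np.linspace(0, TWO_PI, 97)
    got = bsbcf(ts, p)
    want = [oracle(t, 3.0, 40.0, 0.1, 0.2, 2.0, 0.5) for t in ts]
    np.testing.assert_allclose(got, want, rtol=1e-12)


@given(
    t=st.floats(0, TWO_PI),
    b=st.floats(0.5, 10),
    H=st.floats(1, 100),
    phi=st.floats(0, TWO_PI),
)
@settings(max_examples=50, deadline=None)
def test_bsbcf_closed_form_limit(t, b, H, phi):
    # with m = v = c = 0 the curve is a rectified cosine: b + H*max(cos(t-phi), 0)
    p = BSBCFParams(b=b, H=H, c=0.0, m=0.0, phi=phi, v=0.0)
    assert bsbcf(t, p) == pytest.approx(b + H * max(math.cos(t - phi), 0.0), abs=1e-9)


def test_bsbcf_c_equal_one_guarded():
    p = BSBCFParams(b=1.0, H=1.0, c=1.0, m=0.0, phi=0.0, v=0.0)
    with pytest.raises(ZeroDivisionError):
        bsbcf(0.0, p)


# ---------------------------------------------------------------------------
# BSBCF fitting


def _mel_profile(params, hours=38, start=0.0):
    t = start + 60.0 * np.arange(hours)
    return t, np.asarray(bsbcf(t * RAD_PER_MIN, params))


def test_fit_bsbcf_recovers_known_parameters():
    true = BSBCFParams(b=2.0, H=50.0, c=0.3, m=0.1, phi=math.pi / 2, v=1.0)
    t, y = _mel_profile(true)
    fit = fit_bsbcf(t, y)
    for name in ("b", "H", "c", "m", "phi", "v"):
        got, want = getattr(fit.params, name), getattr(true, name)
        assert got == pytest.approx(want, rel=0.01, abs=0.01), name
    assert not fit.degenerate


def test_fit_bsbcf_flat_profile_degenerate():
    t = 60.0 * np.arange(38)
    fit = fit_bsbcf(t, np.full(38, 5.0))
    assert fit.degenerate


def test_fit_bsbcf_respects_bounds(rng):
    true = BSBCFParams(b=2.0, H=30.0, c=-0.2, m=0.3, phi=4.0, v=-1.0)
    t, y = _mel_profile(true)
    y = y * np.exp(rng.normal(0, 0.05, y.size))
    fit = fit_bsbcf(t, y)
    fit.params.validate()  # raises if any printed bound is violated


def test_fit_bsbcf_needs_24h():
    with pytest.raises(FitError):
        fit_bsbcf(60.0 * np.arange(10), np.arange(10.0))


# ---------------------------------------------------------------------------
# excretion rate


def test_excretion_rate_morning_block():
    # 100 ng/mL x 240 mL over 07:00-11:00 -> 6000 ng/h at 09:00
    out = compute_excretion_rate([UrineBlock(420.0, 660.0, 240.0, 100.0)])
    assert out.rates[0] == pytest.approx(6000.0)
    assert out.midpoint_times[0] == pytest.approx(540.0)


def test_excretion_rate_overnight_block():
    # 50 ng/mL x 480 mL over 23:00-07:00 -> 3000 ng/h at 03:00
    out = compute_excretion_rate([UrineBlock(1380.0, 1860.0, 480.0, 50.0)])
    assert out.rates[0] == pytest.approx(3000.0)
    assert out.midpoint_times[0] % MINUTES_PER_DAY == pytest.approx(180.0)


def test_excretion_mass_conservation(rng):
    blocks = []
    cur = 0.0
    for _ in range(10):
        dur = rng.choice([240.0, 480.0])
        blocks.append(UrineBlock(cur, cur + dur, float(rng.uniform(50, 400)),
                                 float(rng.uniform(10, 200))))
        cur += dur
    out = compute_excretion_rate(blocks)
    total_from_rates = sum(r * b.duration_hours for r, b in zip(out.rates, blocks))
    total_direct = sum(b.concentration * b.volume for b in blocks)
    assert total_from_rates == pytest.approx(total_direct, rel=1e-12)


def test_zero_duration_block_rejected():
    with pytest.raises(Exception):
        compute_excretion_rate([UrineBlock(0.0, 0.0, 100.0, 10.0)])


# ---------------------------------------------------------------------------
# cosine fitting


def _rates_from(params, midpoints):
    return ExcretionSeries(np.asarray(midpoints, dtype=float),
                           np.asarray(cosine24(np.asarray(midpoints, dtype=float), params)))


def test_fit_cosine_recovers_known_parameters():
    true = CosineParams(a=500.0, b=600.0, phi=240.0)
    mids = 120.0 + 240.0 * np.arange(12)  # 4-h midpoints over 48 h
    fit = fit_cosine(_rates_from(true, mids))
    assert fit.params.a == pytest.approx(500.0, rel=1e-3)
    assert fit.params.b == pytest.approx(600.0, rel=1e-3)
    assert fit.params.phi == pytest.approx(240.0, abs=0.5)


def test_fit_cosine_constant_rates_degenerate():
    mids = 120.0 + 240.0 * np.arange(12)
    fit = fit_cosine(ExcretionSeries(mids, np.full(12, 300.0)))
    assert fit.degenerate


def test_fit_cosine_time_shift_equivariance():
    true = CosineParams(a=400.0, b=500.0, phi=300.0)
    mids = 90.0 + 240.0 * np.arange(12)
    base = fit_cosine(_rates_from(true, mids))
    shifted = fit_cosine(_rates_from(true, mids + 2 * MINUTES_PER_DAY))
    assert wrap_minutes(base.params.phi - shifted.params.phi) == pytest.approx(0.0, abs=0.5)


# ---------------------------------------------------------------------------
# center of gravity


def test_cog_of_cosine_equals_acrophase():
    p = CosineParams(a=1.0, b=2.0, phi=180.0)  # acrophase 03:00
    est = measured_phase_from_fit(p, "aMT6s")
    assert est.clock_time == pytest.approx(180.0, abs=0.5)


def test_cog_translation_equivariance():
    p1 = CosineParams(a=1.0, b=2.0, phi=180.0)
    p2 = CosineParams(a=1.0, b=2.0, phi=240.0)
    e1 = measured_phase_from_fit(p1, "aMT6s")
    e2 = measured_phase_from_fit(p2, "aMT6s")
    assert wrap_minutes(e2.clock_time - e1.clock_time) == pytest.approx(60.0, abs=0.5)


def test_cog_matches_trapezoid_oracle_on_skewed_profile():
    p = BSBCFParams(b=2.0, H=50.0, c=0.2, m=0.15, phi=1.3, v=1.5)
    start = window_start(p)
    # independent oracle: trapezoidal integration on a 0.1-min grid
    tt = np.arange(start, start + MINUTES_PER_DAY, 0.1)
    f = np.asarray(bsbcf(tt * RAD_PER_MIN, p)) - p.b
    oracle = np.trapezoid(tt * f, tt) / np.trapezoid(f, tt)
    est = measured_phase_from_fit(p, "melatonin")
    assert abs(wrap_minutes(est.clock_time - oracle % MINUTES_PER_DAY)) < 1.0


def test_cog_undefined_below_baseline():
    t = np.arange(0, MINUTES_PER_DAY, 1.0)
    with pytest.raises(UndefinedPhaseError):
        center_of_gravity(t, np.full(t.size, 1.0), baseline=2.0)


# ---------------------------------------------------------------------------
# reference construction


def test_stable_reference_tiles_measured_phase():
    p = CosineParams(a=1.0, b=2.0, phi=240.0)
    ref = build_reference(p, (0.0, 4 * MINUTES_PER_DAY), "aMT6s")
    assert ref.drift_per_day == 0.0
    for day in range(3):
        start = day * MINUTES_PER_DAY + (p.phi + 720.0) % MINUTES_PER_DAY
        t = np.arange(start, start + MINUTES_PER_DAY, 1.0)
        est = center_of_gravity(t, ref.value_at(t), baseline=0.0)
        assert wrap_minutes(est.clock_time - ref.measured_phase.clock_time) == \
            pytest.approx(0.0, abs=0.75)


def test_drifting_reference_period():
    # acrophase 04:00, then 06:00 two days later -> +1 h/day, period 25 h
    p = CosineParams(a=1.0, b=2.0, phi=240.0)
    ref = build_reference(p, (0.0, 4 * MINUTES_PER_DAY), "aMT6s",
                          second_acrophase=(360.0, 2))
    assert ref.drift_per_day == pytest.approx(1.0)
    assert ref.measured_phase.clock_time == pytest.approx(360.0, abs=0.5)
    # consecutive acrophases in the waveform are 25 h apart
    peaks = []
    v = ref.values
    for day in range(3):
        seg = slice(day * 1440, (day + 1) * 1440 + 60)
        peaks.append(ref.timestamps[seg][np.argmax(v[seg])])
    diffs = np.diff(peaks)
    assert np.allclose(diffs, 25 * 60.0, atol=2.0)


def test_reference_scaled_to_unit_interval():
    p = CosineParams(a=3.0, b=5.0, phi=240.0)
    ref = build_reference(p, (0.0, 3 * MINUTES_PER_DAY), "aMT6s")
    assert ref.values.min() == pytest.approx(0.0, abs=1e-6)
    assert ref.values.max() == pytest.approx(1.0, abs=1e-6)


def test_reference_noise_requires_rng():
    p = CosineParams(a=1.0, b=2.0, phi=240.0)
    with pytest.raises(ValueError):
        build_reference(p, (0.0, 2 * MINUTES_PER_DAY), "aMT6s", noise_sd=0.01)


def test_implausible_drift_rejected():
    p = CosineParams(a=1.0, b=2.0, phi=240.0)
    with pytest.raises((ImplausibleDriftError, ValueError)):
        build_reference(p, (0.0, 2 * MINUTES_PER_DAY), "aMT6s",
                        second_acrophase=(360.0, 0))


def test_fit_build_cog_round_trip():
    # fit -> build -> CoG recovers the fitted phase to < 1 min, noise-free
    true = CosineParams(a=500.0, b=600.0, phi=310.0)
    mids = 100.0 + 240.0 * np.arange(12)
    fit = fit_cosine(_rates_from(true, mids))
    ref = build_reference(fit, (0.0, 3 * MINUTES_PER_DAY), "aMT6s")
    start = (fit.params.phi + 720.0) % MINUTES_PER_DAY + MINUTES_PER_DAY
    t = np.arange(start, start + MINUTES_PER_DAY, 1.0)
    est = center_of_gravity(t, ref.value_at(t), baseline=0.0)
    assert abs(wrap_minutes(est.clock_time - true.phi)) < 1.0


def test_noisy_waveform_phase_recovery(rng):
    # 20-replicate spot check (full 100-replicate run lives in acceptance)
    p = CosineParams(a=1.0, b=2.0, phi=240.0)
    for _ in range(20):
        ref = build_reference(p, (0.0, 3 * MINUTES_PER_DAY), "aMT6s",
                              noise_sd=0.01, rng=rng)
        start = (p.phi + 720.0) % MINUTES_PER_DAY + MINUTES_PER_DAY
        t = np.arange(start, start + MINUTES_PER_DAY, 1.0)
        est = center_of_gravity(t, ref.value_at(t), baseline=0.0)
        assert abs(wrap_minutes(est.clock_time - 240.0)) < 5.0
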