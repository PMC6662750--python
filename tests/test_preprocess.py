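import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circaphase.datatypes import ChannelSeries, SleepInterval
from circaphase.preprocess import (
    AlignmentError,
    ConfigurationError,
    average_bilateral,
    bin_align,
    bin_channel,
    check_inclusion,
    clean_activity,
    clean_light,
    clean_temperature,
    detrend_scale_temperature,
    fill_gaps,
)


def _temp_series(values, cadence=2.5, site="wrist"):
    values = np.asarray(values, dtype=float)
    return ChannelSeries(np.arange(values.size) * cadence, values, "temperature", site)


def _epochs(blue, off_wrist=None, activity=None):
    blue = np.asarray(blue, dtype=float)
    n = blue.size
    return pd.DataFrame({
        "timestamp": np.arange(n, dtype=float),
        "blue": blue,
        "white_lux": blue,
        "activity": np.asarray(activity, dtype=float) if activity is not None
        else np.full(n, 10.0),
        "off_wrist": np.asarray(off_wrist, dtype=bool) if off_wrist is not None
        else np.zeros(n, dtype=bool),
    })


# ---------------------------------------------------------------------------
# clean_temperature


def test_sub20_sample_removed():
    s = _temp_series([33.0, 19.5, 33.2, 33.1])
    out = clean_temperature(s)
    assert np.isnan(out.values[1])
    assert not np.isnan(out.values[[0, 2, 3]]).any()


def test_in_band_series_is_noop(rng):
    v = 33.0 + np.clip(rng.normal(0, 0.5, 500), -1.2, 1.2)
    out = clean_temperature(_temp_series(v))
    np.testing.assert_array_equal(out.values, v)


def test_3sd_outlier_exact_exclusion_set(rng):
    v = rng.normal(33.0, 0.5, 1000)
    v = 33.0 + (v - 33.0) * np.minimum(1.0, 1.4 / np.abs(v - 33.0))  # cap at 2.8 SD
    v = np.append(v, 40.0)
    out = clean_temperature(_temp_series(v))
    # independent oracle: recompute mean/SD and the exclusion set directly
    mu, sd = v.mean(), v.std()
    expect = np.abs(v - mu) > 3 * sd
    assert expect.sum() == 1 and expect[-1]
    np.testing.assert_array_equal(np.isnan(out.values), expect)


def test_clean_temperature_idempotent(rng):
    v = 33.0 + np.clip(rng.normal(0, 0.4, 800), -1.0, 1.0)
    once = clean_temperature(_temp_series(v))
    twice = clean_temperature(once)
    np.testing.assert_array_equal(once.values, twice.values)


def test_removal_interval_masks_samples():
    s = _temp_series(np.full(100, 33.0))
    out = clean_temperature(s, removal_intervals=[(10.0, 20.0)])
    assert np.isnan(out.values[4:8]).all()  # samples at 10, 12.5, 15, 17.5
    assert not np.isnan(out.values[:4]).any()


# ---------------------------------------------------------------------------
# average_bilateral


def _sensor(site, values, cadence=2.5):
    return _temp_series(values, cadence, site)


def test_bilateral_mean():
    out = average_bilateral([_sensor("wrist", [33.0, 33.0]), _sensor("wrist", [35.0, 35.0])])
    np.testing.assert_allclose(out[0].values, [34.0, 34.0])


def test_single_side_fallback():
    out = average_bilateral([_sensor("wrist", [np.nan, 33.0]), _sensor("wrist", [34.0, 35.0])])
    np.testing.assert_allclose(out[0].values, [34.0, 34.0])


def test_sternum_passthrough():
    out = average_bilateral([_sensor("sternum", [34.2, 34.3])])
    assert out[0].site == "sternum"
    np.testing.assert_allclose(out[0].values, [34.2, 34.3])


def test_eleven_sensor_layout_gives_six_variables():
    sensors = [_sensor(site, [33.0, 33.0]) for site in
               ("shoulder", "shoulder", "wrist", "wrist", "thigh", "thigh",
                "calf", "calf", "foot", "foot", "sternum")]
    assert len(average_bilateral(sensors)) == 6


# ---------------------------------------------------------------------------
# detrend_scale_temperature


def test_constant_series_detrends_to_zero():
    out = detrend_scale_temperature(_temp_series(np.full(2000, 33.0)))
    np.testing.assert_array_equal(out.values, np.zeros(2000))


def test_detrend_recovers_sinusoid_under_linear_trend():
    t = np.arange(0, 4 * 1440, 2.5)
    sin = np.cos(2 * np.pi * t / 1440.0)
    v = 33.0 + sin + 0.001 * t
    out = detrend_scale_temperature(_temp_series(v))
    half = int(720 / 2.5)
    interior = slice(half, -half)
    z, ref = out.values[interior], sin[interior]
    ok = ~np.isnan(z)
    assert np.corrcoef(z[ok], ref[ok])[0, 1] > 0.99


def test_post_z_outlier_removed():
    v = np.full(2000, 33.0)
    v[1000] = 36.0  # lone spike -> huge z after detrending
    out = detrend_scale_temperature(_temp_series(v))
    assert np.isnan(out.values[1000])


# ---------------------------------------------------------------------------
# clean_light


SLEEP = [SleepInterval(0.0, 10.0)]


def test_wake_value_below_one_removed():
    df = _epochs(np.concatenate([np.full(10, 0.005), [0.5, 50.0, 120.0]]))
    out = clean_light(df, SLEEP)
    assert np.isnan(out.values[10])  # wake epoch at 0.5 -> artefact
    assert not np.isnan(out.values[11])


def test_sleep_value_floored_and_logged():
    df = _epochs(np.concatenate([np.full(10, 0.005), np.full(5, 100.0)]))
    out = clean_light(df, SLEEP)
    np.testing.assert_allclose(out.values[:10], -2.0)  # log10(0.01)
    np.testing.assert_allclose(out.values[10:], 2.0)


def test_off_wrist_light_removed():
    off = np.zeros(15, dtype=bool)
    off[12] = True
    df = _epochs(np.concatenate([np.full(10, 0.005), np.full(5, 200.0)]), off_wrist=off)
    out = clean_light(df, SLEEP)
    assert np.isnan(out.values[12])


def test_no_wake_epochs_is_configuration_error():
    df = _epochs(np.full(10, 5.0))
    with pytest.raises(ConfigurationError):
        clean_light(df, [SleepInterval(0.0, 100.0)])


# ---------------------------------------------------------------------------
# clean_activity


def test_negative_activity_clamped_before_scaling(rng):
    act = rng.uniform(0, 100, 200)
    act[50] = -3.2
    out = clean_activity(_epochs(np.full(200, 100.0), activity=act))
    clamped = act.copy()
    clamped[50] = 0.0
    z = (clamped - clamped.mean()) / clamped.std()
    z[np.abs(z) > 2] = np.nan
    np.testing.assert_allclose(out.values, z)


def test_activity_z_outlier_removed(rng):
    act = rng.uniform(40, 60, 500)
    act[100] = 500.0
    out = clean_activity(_epochs(np.full(500, 100.0), activity=act))
    assert np.isnan(out.values[100])


def test_all_equal_counts_zero_variance():
    out = clean_activity(_epochs(np.full(100, 100.0), activity=np.full(100, 7.0)))
    np.testing.assert_array_equal(out.values, np.zeros(100))


# ---------------------------------------------------------------------------
# check_inclusion


def _series_with_mask(n_minutes, missing_mask=None):
    v = 33.0 + np.zeros(n_minutes)
    if missing_mask is not None:
        v[missing_mask] = np.nan
    return ChannelSeries(np.arange(n_minutes, dtype=float), v, "temperature")


def test_excess_missing_fails():
    n = 4 * 1440
    mask = (np.arange(n) % 10) < 6  # 60% missing in short runs
    report = check_inclusion({"light": _series_with_mask(n, mask)})
    assert not report.passed and "missing_fraction" in report.reasons


def test_short_recording_fails():
    report = check_inclusion({"light": _series_with_mask(int(2.5 * 1440))})
    assert not report.passed and "min_span" in report.reasons


def test_long_gap_fails():
    n = 5 * 1440
    mask = np.zeros(n, dtype=bool)
    mask[2 * 1440: 2 * 1440 + 37 * 60] = True  # 37-h gap
    report = check_inclusion({"light": _series_with_mask(n, mask)})
    assert not report.passed and "max_gap" in report.reasons
    assert report.max_gap_hours == pytest.approx(37.0)


def test_clean_recording_passes():
    report = check_inclusion({"light": _series_with_mask(4 * 1440)})
    assert report.passed and report.reasons == []


# ---------------------------------------------------------------------------
# fill_gaps


def test_no_gap_is_noop():
    t = np.arange(3 * 1440, dtype=float)
    v = np.sin(2 * np.pi * t / 1440)
    s = ChannelSeries(t, v, "light")
    out = fill_gaps(s)
    np.testing.assert_array_equal(out.values, v)


def test_45min_gap_filled_plausibly():
    t = np.arange(3 * 1440, dtype=float)
    truth = 33.0 + np.cos(2 * np.pi * t / 1440)
    v = truth.copy()
    gap = slice(2000, 2045)
    v[gap] = np.nan
    out = fill_gaps(ChannelSeries(t, v, "temperature"))
    assert not np.isnan(out.values).any()
    filled = out.values[gap]
    # linear-interpolation oracle across the same gap
    linear = np.interp(t[gap], [t[1999], t[2045]], [truth[1999], truth[2045]])
    rmse_fill = np.sqrt(np.mean((filled - truth[gap]) ** 2))
    rmse_linear = np.sqrt(np.mean((linear - truth[gap]) ** 2))
    assert rmse_fill <= max(3.0 * rmse_linear, 0.05)
    sd = np.nanstd(v)
    assert np.all(np.abs(filled - truth[gap]) < 3.0 * sd)
    # continuity at the gap edges
    assert abs(filled[0] - truth[1999]) < 3.0 * sd


def test_first_day_gap_truncates():
    t = np.arange(4 * 1440, dtype=float)
    v = np.cos(2 * np.pi * t / 1440) + 33.0
    v[600:810] = np.nan  # 3.5-h gap starting hour 10 of day 1
    out = fill_gaps(ChannelSeries(t, v, "temperature"))
    assert out.timestamps[0] == 810.0
    assert not np.isnan(out.values).any()


def test_truncation_spares_later_gaps():
    t = np.arange(4 * 1440, dtype=float)
    v = np.cos(2 * np.pi * t / 1440) + 33.0
    v[3000:3240] = np.nan  # 4-h gap on day 3: interpolated, not truncated
    out = fill_gaps(ChannelSeries(t, v, "temperature"))
    assert out.timestamps[0] == 0.0
    assert not np.isnan(out.values).any()


# ---------------------------------------------------------------------------
# binning and alignment


def test_single_bin_center_and_value():
    t = np.arange(360.0, 390.0)  # 06:00-06:29
    s = ChannelSeries(t, np.full(30, 2.0), "light")
    binned = bin_channel(s)
    assert list(binned.index) == [375.0]  # centre 06:15
    assert binned.iloc[0] == 2.0


def test_alignment_cuts_to_shortest_stream():
    n = int(1.5 * 1440)
    light = ChannelSeries(np.arange(n - 120, dtype=float), np.ones(n - 120), "light")
    temp = ChannelSeries(np.arange(0, n, 2.5), np.full(int(n / 2.5), 33.0), "temperature")
    out = bin_align({"light": light, "temp": temp})
    assert out.bin_centers[-1] < n - 120


def test_short_aligned_span_rejected():
    n = int(0.9 * 1440)
    ch = ChannelSeries(np.arange(n, dtype=float), np.ones(n), "light")
    with pytest.raises(AlignmentError, match="minimum length"):
        bin_align({"light": ch})


@given(st.floats(min_value=-100, max_value=100, allow_nan=False))
@settings(max_examples=25, deadline=None)
def test_binning_preserves_constants(value):
    t = np.arange(2 * 1440, dtype=float)
    s = ChannelSeries(t, np.full(t.size, value), "light")
    binned = bin_channel(s)
    np.testing.assert_allclose(binned.to_numpy(), value)
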