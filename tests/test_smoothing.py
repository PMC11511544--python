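"""Moving-average and Gaussian smoothing, including the printed-table
alignment regression.

The packaged filtered tables were cut from a longer recording; an
offset-search oracle establishes that filtered row i equals the mean of raw
rows i+1..i+5, and the regression then asserts that alignment over every
fully printed window of all channels and phases.
"""

import numpy as np
import pytest

from vitalglove import (
    CHANNELS,
    EdgePolicy,
    FilterKind,
    FilterSpec,
    gaussian_kernel,
    gaussian_smooth,
    load_fixture,
    moving_average,
    smooth_session,
)

PHASE_PAIRS = [
    ("raw_resting", "ma_resting"),
    ("raw_walking", "ma_walking"),
    ("raw_running", "ma_running"),
]


def block_mean_oracle(x, window):
    """Plain-loop sliding mean, independent of the implementation."""
    return np.array(
        [sum(x[j : j + window]) / window for j in range(len(x) - window + 1)]
    )


def find_alignment_offset(raw, filtered, window=5, tol=0.005):
    """Return the unique row offset aligning block means with the filtered
    table, or None."""
    hits = []
    for off in range(-window, window + 1):
        errs = []
        for i in range(len(filtered)):
            lo = i + off
            if lo < 0 or lo + window > len(raw):
                continue
            errs.append(abs(filtered[i] - raw[lo : lo + window].mean()))
        if len(errs) >= 10 and max(errs) <= tol:
            hits.append(off)
    return hits[0] if len(hits) == 1 else None


class TestMovingAverage:
    def test_first_resting_window(self, raw_resting):
        # mean of raw rows 2..6 must reproduce the first filtered cell, 76.48
        hr = raw_resting.channel("hr_bpm")
        assert hr[1:6].mean() == pytest.approx(76.48, abs=0.005)
        assert moving_average(hr, 5)[1] == pytest.approx(76.48, abs=0.005)

    def test_second_running_window(self, raw_running):
        # mean of raw rows 3..7 -> 100.55
        assert moving_average(raw_running.channel("hr_bpm"), 5)[2] == pytest.approx(
            100.55, abs=0.005
        )

    def test_output_length_complete_only(self):
        out = moving_average(np.arange(10.0), 5, EdgePolicy.COMPLETE_ONLY)
        assert len(out) == 6
        assert out[0] == pytest.approx(2.0)

    def test_constant_series_is_fixed_point(self):
        x = np.full(20, 3.25)
        for policy in EdgePolicy:
            assert moving_average(x, 5, policy) == pytest.approx(x[: 20 - 4 * (policy is EdgePolicy.COMPLETE_ONLY)])

    def test_matches_plain_loop_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        for window in (1, 3, 5, 9):
            assert np.allclose(
                moving_average(x, window), block_mean_oracle(x, window), atol=1e-12
            )

    def test_output_bounded_by_window_extremes(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=100)
        out = moving_average(x, 5)
        for j, v in enumerate(out):
            assert x[j : j + 5].min() - 1e-12 <= v <= x[j : j + 5].max() + 1e-12

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            moving_average([1.0, 2.0], 5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            moving_average(np.arange(10.0), 4)


class TestTableAlignmentRegression:
    @pytest.mark.parametrize("raw_name,ma_name", PHASE_PAIRS)
    def test_offset_search_finds_plus_one(self, raw_name, ma_name):
        raw = load_fixture(raw_name).channel("hr_bpm")
        filt = load_fixture(ma_name).channel("hr_bpm")
        assert find_alignment_offset(raw, filt) == 1

    @pytest.mark.parametrize("raw_name,ma_name", PHASE_PAIRS)
    @pytest.mark.parametrize("channel", CHANNELS)
    def test_all_printed_windows_reproduce_filtered_cells(
        self, raw_name, ma_name, channel
    ):
        raw = load_fixture(raw_name).channel(channel)
        filt = load_fixture(ma_name).channel(channel)
        means = moving_average(raw, 5)  # means[j] = mean(raw[j..j+4])
        # filtered row i (0-based) aligns with window starting at raw row i+1
        for i in range(25):
            assert filt[i] == pytest.approx(means[i + 1], abs=0.005), (
                f"{ma_name}.{channel} row {i + 1}"
            )


class TestGaussian:
    def test_kernel_is_normalized_and_symmetric(self):
        k = gaussian_kernel(2.0, truncate=4.0)
        assert len(k) == 17
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(k, k[::-1])
        assert k.argmax() == 8

    def test_constant_series_is_fixed_point(self):
        x = np.full(40, 7.5)
        assert gaussian_smooth(x, 2.0) == pytest.approx(x, abs=1e-12)

    def test_impulse_mass_conserved_under_reflect(self):
        x = np.zeros(41)
        x[20] = 1.0
        out = gaussian_smooth(x, 2.0, edge_policy=EdgePolicy.REFLECT)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=120)
        sigma, truncate = 2.0, 4.0
        half = 8
        k = np.exp(-np.arange(-half, half + 1) ** 2 / (2 * sigma**2))
        k /= k.sum()
        # explicit-loop valid convolution
        expected = np.array(
            [np.dot(x[j : j + 2 * half + 1], k[::-1]) for j in range(len(x) - 2 * half)]
        )
        got = gaussian_smooth(x, sigma, truncate, EdgePolicy.COMPLETE_ONLY)
        assert np.allclose(got, expected, atol=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_smooth(np.arange(30.0), sigma=0.0)


class TestSmoothSession:
    def test_resting_session_first_smoothed_hr(self, raw_resting):
        spec = FilterSpec(
            kind=FilterKind.MOVING_AVERAGE, edge_policy=EdgePolicy.COMPLETE_ONLY
        )
        smoothed = smooth_session(raw_resting, spec)
        # complete_only window 0 covers raw rows 1..5; the printed filtered
        # row 1 is the window over rows 2..6
        assert smoothed.channel("hr_bpm")[1] == pytest.approx(76.48, abs=0.005)
        assert len(smoothed) == 26

    def test_walking_session_first_smoothed_hr(self, raw_walking):
        spec = FilterSpec(
            kind=FilterKind.MOVING_AVERAGE, edge_policy=EdgePolicy.COMPLETE_ONLY
        )
        assert smooth_session(raw_walking, spec).channel("hr_bpm")[1] == pytest.approx(
            83.18, abs=0.005
        )

    def test_identity_spec_preserves_session(self, raw_running):
        spec = FilterSpec(kind=FilterKind.MOVING_AVERAGE, window=1)
        smoothed = smooth_session(raw_running, spec)
        for c in CHANNELS:
            assert smoothed.channel(c) == pytest.approx(raw_running.channel(c))
        assert smoothed.phase == raw_running.phase

    def test_alert_column_is_not_smoothed(self, raw_running):
        spec = FilterSpec(kind=FilterKind.GAUSSIAN, edge_policy=EdgePolicy.REFLECT)
        smoothed = smooth_session(raw_running, spec)
        assert np.array_equal(
            smoothed.channel("alert"), raw_running.channel("alert")
        )

    @pytest.mark.parametrize("kind", list(FilterKind))
    def test_smoothing_reduces_hr_variance_on_running_fixture(self, raw_running, kind):
        spec = FilterSpec(kind=kind, edge_policy=EdgePolicy.REFLECT)
        smoothed = smooth_session(raw_running, spec)
        assert smoothed.channel("hr_bpm").var() < raw_running.channel("hr_bpm").var()

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(window=4)
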