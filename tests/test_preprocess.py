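"""Smoothing, visual-angle conversion, velocity, I-VT segmentation,
and the calibration gate."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from gazecue.preprocess import (
    ScreenGeometry,
    compute_velocity,
    label_samples,
    segment_events,
    smooth_gaze,
    to_degrees,
    validate_calibration,
)

from conftest import make_stream, step_stream


# ---------------------------------------------------------------------------
# visual angle

class TestToDegrees:
    def test_identical_points_zero(self, geometry):
        assert to_degrees((0.3, 0.7), (0.3, 0.7), geometry) == 0.0

    def test_known_chord(self, geometry):
        # 2.27 cm on screen at 65 cm: 2*atan(1.135/65) = 2.0 degrees
        dx_norm = 2.27 / geometry.width_cm
        deg = to_degrees((0.5, 0.5), (0.5 + dx_norm, 0.5), geometry)
        assert deg == pytest.approx(2.0, abs=0.01)

    def test_angle_decreases_with_distance(self, geometry):
        far = ScreenGeometry(viewing_distance_cm=2 * geometry.viewing_distance_cm)
        a = to_degrees((0.2, 0.2), (0.6, 0.6), geometry)
        b = to_degrees((0.2, 0.2), (0.6, 0.6), far)
        assert b < a

    def test_zero_viewing_distance_rejected(self):
        with pytest.raises(ValueError):
            ScreenGeometry(viewing_distance_cm=0.0)

    @given(
        x1=hst.floats(0, 1), y1=hst.floats(0, 1),
        x2=hst.floats(0, 1), y2=hst.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_metric_properties(self, x1, y1, x2, y2):
        geom = ScreenGeometry()
        d12 = to_degrees((x1, y1), (x2, y2), geom)
        d21 = to_degrees((x2, y2), (x1, y1), geom)
        assert d12 >= 0
        assert d12 == pytest.approx(d21, rel=1e-12, abs=1e-12)
        if (x1, y1) == (x2, y2):
            assert d12 == 0.0


# ---------------------------------------------------------------------------
# smoothing

class TestSmoothGaze:
    def test_polynomial_reproduced(self):
        # a Savitzky-Golay filter of order 9 reproduces any degree-<=9
        # polynomial exactly
        n = 120
        u = np.linspace(-1, 1, n)
        poly = 0.5 + 0.05 * u - 0.04 * u**3 + 0.02 * u**5 + 0.01 * u**9
        stream = make_stream(poly, poly[::-1].copy())
        out = smooth_gaze(stream)
        np.testing.assert_allclose(out["x_norm"], stream["x_norm"], atol=1e-9)
        np.testing.assert_allclose(out["y_norm"], stream["y_norm"], atol=1e-9)

    def test_constant_unchanged(self):
        stream = make_stream(np.full(80, 0.4), np.full(80, 0.6))
        out = smooth_gaze(stream)
        np.testing.assert_allclose(out["x_norm"], 0.4)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        t = np.arange(600) / 300.0
        sig = 0.5 + 0.1 * np.sin(2 * np.pi * 1.5 * t)
        noisy = sig + rng.normal(0, 0.01, t.size)
        out = smooth_gaze(make_stream(noisy, noisy))
        resid_in = noisy - sig
        resid_out = out["x_norm"].to_numpy() - sig
        assert resid_out.var() < resid_in.var()

    def test_invalid_samples_untouched(self):
        rng = np.random.default_rng(1)
        x = 0.5 + rng.normal(0, 0.01, 200)
        valid = np.ones(200, dtype=bool)
        valid[60:80] = False
        stream = make_stream(x, x.copy(), valid=valid)
        out = smooth_gaze(stream)
        np.testing.assert_array_equal(
            out.loc[~out["valid"], "x_norm"], stream.loc[~stream["valid"], "x_norm"])

    def test_short_run_passthrough_with_warning(self):
        stream = make_stream(np.full(10, 0.5), np.full(10, 0.5))
        with pytest.warns(UserWarning, match="shorter than the smoothing window"):
            out = smooth_gaze(stream, window=21, order=9)
        np.testing.assert_array_equal(out["x_norm"], stream["x_norm"])

    def test_window_validation(self):
        stream = make_stream(np.full(50, 0.5), np.full(50, 0.5))
        with pytest.raises(ValueError):
            smooth_gaze(stream, window=20)
        with pytest.raises(ValueError):
            smooth_gaze(stream, window=7, order=9)


# ---------------------------------------------------------------------------
# velocity

class TestComputeVelocity:
    def test_stationary_zero(self, geometry):
        stream = make_stream(np.full(100, 0.5), np.full(100, 0.5))
        vel = compute_velocity(stream, geometry)
        interior = vel[1:-1]
        np.testing.assert_allclose(interior, 0.0, atol=1e-9)
        assert np.isnan(vel[0]) and np.isnan(vel[-1])

    def test_linear_sweep_recovered(self, geometry):
        # gaze sweeping at a constant 10 deg/s angular speed
        fs = 300.0
        t = np.arange(300) / fs
        theta = np.radians(-5.0 + 10.0 * t)  # signed angle from screen center
        x_cm = 2 * geometry.viewing_distance_cm * np.tan(theta / 2)
        x = 0.5 + x_cm / geometry.width_cm
        vel = compute_velocity(make_stream(x, np.full_like(x, 0.5), fs=fs), geometry)
        assert np.nanmedian(vel) == pytest.approx(10.0, rel=0.02)

    def test_time_reversal_symmetry(self, geometry):
        rng = np.random.default_rng(2)
        x = 0.5 + np.cumsum(rng.normal(0, 0.002, 200))
        stream = make_stream(x, x[::-1].copy())
        rev = stream.iloc[::-1].reset_index(drop=True).copy()
        rev["time_s"] = stream["time_s"].to_numpy()
        v1 = compute_velocity(stream, geometry)
        v2 = compute_velocity(rev, geometry)
        np.testing.assert_allclose(v1, v2[::-1], equal_nan=True, rtol=1e-9)

    def test_nan_at_invalid(self, geometry):
        valid = np.ones(100, dtype=bool)
        valid[40:50] = False
        stream = make_stream(np.full(100, 0.5), np.full(100, 0.5), valid=valid)
        vel = compute_velocity(stream, geometry)
        assert np.isnan(vel[40:50]).all()


# ---------------------------------------------------------------------------
# segmentation

def oracle_segments(stream, geometry, threshold):
    """Brute-force reference: per-sample threshold labels, boundary samples
    inheriting their neighbor's label, then run-length grouping."""
    vel = compute_velocity(stream, geometry)
    valid = stream["valid"].to_numpy()
    out = []
    n = len(stream)
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        if j - i >= 3:
            lab = label_samples(vel[i:j], threshold)
            lab[0], lab[-1] = lab[1], lab[-2]
            runs = []
            for k, s in enumerate(lab):
                if runs and runs[-1][0] == s:
                    runs[-1][2] = i + k
                else:
                    runs.append([s, i + k, i + k])
            out.extend(("saccade" if s == 1 else "fixation", a, b) for s, a, b in runs)
        i = j
    return out


class TestSegmentEvents:
    def test_constant_stream_single_fixation(self, geometry):
        events = segment_events(
            make_stream(np.full(200, 0.5), np.full(200, 0.5)), geometry)
        assert [e.kind for e in events] == ["fixation"]

    def test_step_gives_fix_sacc_fix(self, geometry):
        stream = step_stream(geometry)
        events = segment_events(stream, geometry)
        assert [e.kind for e in events] == ["fixation", "saccade", "fixation"]
        sacc = events[1]
        assert sacc.peak_velocity_deg_s >= 120.0
        assert sacc.amplitude_deg > 5.0

    def test_empty_stream(self, geometry):
        assert segment_events(make_stream([], []), geometry) == []

    def test_matches_brute_force_oracle(self, geometry):
        rng = np.random.default_rng(3)
        for _ in range(5):
            # random walk of dwells and fast sweeps, no sub-minimum runs
            pieces = []
            pos = 0.4
            for _ in range(6):
                pieces.append(np.full(rng.integers(30, 90), pos))
                new = float(rng.uniform(0.2, 0.8))
                pieces.append(np.linspace(pos, new, 20))
                pos = new
            x = np.concatenate(pieces)
            stream = make_stream(x, np.full(x.size, 0.5))
            events = segment_events(stream, geometry, min_duration_s=0.0)
            expected = oracle_segments(stream, geometry, 30.0)
            assert [(e.kind) for e in events] == [k for k, _, _ in expected]
            t = stream["time_s"].to_numpy()
            for ev, (_, a, b) in zip(events, expected):
                assert ev.t_on == pytest.approx(t[a])
                assert ev.t_off == pytest.approx(t[b])

    def test_threshold_flip_at_30(self, geometry):
        # constant-speed sweeps just below / at-or-above the 30 deg/s threshold
        fs = 300.0
        for speed, expected in [(29.0, "fixation"), (31.0, "saccade")]:
            t = np.arange(200) / fs
            theta = np.radians(-2.0 + speed * t)
            x_cm = 2 * geometry.viewing_distance_cm * np.tan(theta / 2)
            stream = make_stream(0.5 + x_cm / geometry.width_cm,
                                 np.full(t.size, 0.5), fs=fs)
            events = segment_events(stream, geometry, min_duration_s=0.0)
            kinds = {e.kind for e in events}
            assert kinds == {expected}

    def test_boundary_velocity_is_saccade(self):
        lab = label_samples(np.array([10.0, 30.0, 50.0, np.nan]), 30.0)
        np.testing.assert_array_equal(lab, [0, 1, 1, -1])

    def test_long_invalid_gap_splits_events(self, geometry):
        valid = np.ones(400, dtype=bool)
        valid[150:200] = False  # ~167 ms: too long to bridge
        stream = make_stream(np.full(400, 0.5), np.full(400, 0.5), valid=valid)
        events = segment_events(stream, geometry)
        assert [e.kind for e in events] == ["fixation", "fixation"]
        assert events[0].t_off < events[1].t_on

    def test_blink_gap_bridged_when_gaze_stationary(self, geometry):
        valid = np.ones(300, dtype=bool)
        valid[140:155] = False  # 50 ms blink
        stream = make_stream(np.full(300, 0.5), np.full(300, 0.5), valid=valid)
        events = segment_events(stream, geometry)
        assert [e.kind for e in events] == ["fixation"]

    def test_short_gap_with_displacement_not_bridged(self, geometry):
        valid = np.ones(300, dtype=bool)
        valid[140:155] = False
        x = np.full(300, 0.4)
        x[155:] = 0.7  # gaze jumped during the gap
        stream = make_stream(x, np.full(300, 0.5), valid=valid)
        events = segment_events(stream, geometry)
        assert len(events) == 2
        assert events[0].t_off < events[1].t_on

    def test_events_tile_valid_stream(self, geometry):
        stream = step_stream(geometry)
        events = segment_events(stream, geometry)
        # ordered, non-overlapping, jointly covering all samples
        assert sum(e.n_samples for e in events) == len(stream)
        for a, b in zip(events, events[1:]):
            assert a.t_off < b.t_on

    def test_sub_minimum_run_merged(self, geometry):
        # single-sample velocity spikes (3.3 ms, below the 10 ms minimum)
        # must be absorbed into the surrounding fixation
        x = np.full(200, 0.5)
        x[100] += 0.02
        events = segment_events(make_stream(x, np.full(200, 0.5)), geometry)
        assert sum(e.kind == "saccade" for e in events) == 0


# ---------------------------------------------------------------------------
# calibration gate

class TestValidateCalibration:
    @pytest.mark.parametrize("errors,expected", [
        ([2.5, 1.0, 1.5], True),   # one failed point tolerated
        ([2.5, 2.5, 1.0], False),  # two failures exclude the recording
        ([2.0, 2.0, 2.0], True),   # the 2-degree limit is inclusive
        ([0.5, 0.5, 0.5], True),
        ([3.0, 3.0, 3.0], False),
    ])
    def test_gate(self, errors, expected):
        assert validate_calibration(errors) is expected

    def test_wrong_point_count(self):
        with pytest.raises(ValueError):
            validate_calibration([1.0, 1.0])
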