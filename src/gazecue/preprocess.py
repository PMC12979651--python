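"""Gaze preprocessing: smoothing, angular velocity, and I-VT event segmentation.

Raw gaze is a stream of (time, x, y, valid) samples in normalized screen
coordinates (origin top-left, x and y in [0, 1]).  The pipeline here is

1. Savitzky–Golay smoothing of x/y over contiguous valid runs,
2. per-sample angular velocity by central differences,
3. velocity-threshold (I-VT) segmentation into fixations and saccades,

plus the calibration-validation gate used to decide whether a recording is
usable at all.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

#: Angular velocity at or above this value classifies a sample as saccadic.
DEFAULT_VELOCITY_THRESHOLD_DEG_S = 30.0

#: Savitzky-Golay defaults (samples / polynomial degree).
DEFAULT_SMOOTH_WINDOW = 21
DEFAULT_SMOOTH_ORDER = 9

#: Events shorter than this are merged into their neighbor.
DEFAULT_MIN_EVENT_DURATION_S = 0.010

GAZE_COLUMNS = ["time_s", "x_norm", "y_norm", "valid"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display and recording geometry.

    Physical width/height are derived from the diagonal and the pixel grid
    assuming square pixels (only the diagonal and resolution are known).
    """

    width_px: int = 1920
    height_px: int = 1080
    diagonal_inches: float = 23.0
    viewing_distance_cm: float = 65.0
    sampling_rate_hz: float = 300.0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) <= 0:
            raise ValueError("pixel dimensions must be positive")
        if self.diagonal_inches <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("diagonal and sampling rate must be positive")
        if self.viewing_distance_cm <= 0:
            raise ValueError("viewing distance must be positive")

    @property
    def diagonal_cm(self) -> float:
        return self.diagonal_inches * 2.54

    @property
    def width_cm(self) -> float:
        diag_px = math.hypot(self.width_px, self.height_px)
        return self.diagonal_cm * self.width_px / diag_px

    @property
    def height_cm(self) -> float:
        diag_px = math.hypot(self.width_px, self.height_px)
        return self.diagonal_cm * self.height_px / diag_px


def to_degrees(p1, p2, geometry: ScreenGeometry) -> float:
    """Visual angle (degrees) subtended by the segment between two points.

    Points are normalized screen coordinates.  The normalized displacement is
    mapped to centimetres on the display surface and converted to visual angle
    with ``2 * atan(d / 2 / viewing_distance)``, i.e. the chord is assumed
    centred on the line of sight.  Symmetric in its arguments and zero iff the
    points coincide.
    """
    dx_cm = (float(p2[0]) - float(p1[0])) * geometry.width_cm
    dy_cm = (float(p2[1]) - float(p1[1])) * geometry.height_cm
    d_cm = math.hypot(dx_cm, dy_cm)
    return math.degrees(2.0 * math.atan2(d_cm / 2.0, geometry.viewing_distance_cm))


def axis_degrees(coord_norm: np.ndarray, axis_cm: float, geometry: ScreenGeometry) -> np.ndarray:
    """Signed visual angle of normalized coordinates measured from screen center."""
    d_cm = (np.asarray(coord_norm, dtype=float) - 0.5) * axis_cm
    return np.degrees(2.0 * np.arctan2(d_cm / 2.0, geometry.viewing_distance_cm))


def _valid_runs(valid: np.ndarray):
    """Yield (start, stop) half-open index ranges of contiguous valid samples."""
    v = np.asarray(valid, dtype=bool)
    if v.size == 0:
        return
    edges = np.flatnonzero(np.diff(v.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    stops = np.concatenate((edges + 1, [v.size]))
    for a, b in zip(starts, stops):
        if v[a]:
            yield int(a), int(b)


def smooth_gaze(
    stream: pd.DataFrame,
    window: int = DEFAULT_SMOOTH_WINDOW,
    order: int = DEFAULT_SMOOTH_ORDER,
) -> pd.DataFrame:
    """Savitzky–Golay smooth x/y independently over contiguous valid runs.

    Invalid samples are untouched and never enter a smoothing window.  Runs
    shorter than ``window`` are passed through unchanged with a warning.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= order:
        raise ValueError("window must exceed polynomial order")
    out = stream.copy()
    x = out["x_norm"].to_numpy(dtype=float, copy=True)
    y = out["y_norm"].to_numpy(dtype=float, copy=True)
    short_runs = 0
    for a, b in _valid_runs(out["valid"].to_numpy()):
        if b - a < window:
            short_runs += 1
            continue
        x[a:b] = savgol_filter(x[a:b], window, order)
        y[a:b] = savgol_filter(y[a:b], window, order)
    if short_runs:
        warnings.warn(
            f"{short_runs} valid run(s) shorter than the smoothing window "
            f"({window} samples); passed through unsmoothed",
            stacklevel=2,
        )
    out["x_norm"] = x
    out["y_norm"] = y
    return out


def compute_velocity(stream: pd.DataFrame, geometry: ScreenGeometry) -> np.ndarray:
    """Per-sample angular speed in degrees/s by central differences.

    NaN at invalid samples and at the boundary samples of each valid run,
    where a centred difference is unavailable.
    """
    t = stream["time_s"].to_numpy(dtype=float)
    x = stream["x_norm"].to_numpy(dtype=float)
    y = stream["y_norm"].to_numpy(dtype=float)
    vel = np.full(t.shape, np.nan)
    wcm, hcm = geometry.width_cm, geometry.height_cm
    for a, b in _valid_runs(stream["valid"].to_numpy()):
        if b - a < 3:
            continue
        sl = slice(a + 1, b - 1)
        dx = (x[a + 2 : b] - x[a : b - 2]) * wcm
        dy = (y[a + 2 : b] - y[a : b - 2]) * hcm
        d_cm = np.hypot(dx, dy)
        ang = np.degrees(2.0 * np.arctan2(d_cm / 2.0, geometry.viewing_distance_cm))
        dt = t[a + 2 : b] - t[a : b - 2]
        vel[sl] = ang / dt
    return vel


@dataclass
class GazeEvent:
    """One fixation or saccade, with summary kinematics."""

    kind: str  # "fixation" | "saccade"
    t_on: float
    t_off: float
    centroid_x: float
    centroid_y: float
    end_x: float
    end_y: float
    amplitude_deg: float
    peak_velocity_deg_s: float
    mean_velocity_deg_s: float
    n_samples: int


def _summarize_event(kind, idx, t, x, y, vel, geometry) -> GazeEvent:
    v = vel[idx]
    v = v[np.isfinite(v)]
    return GazeEvent(
        kind=kind,
        t_on=float(t[idx[0]]),
        t_off=float(t[idx[-1]]),
        centroid_x=float(np.mean(x[idx])),
        centroid_y=float(np.mean(y[idx])),
        end_x=float(x[idx[-1]]),
        end_y=float(y[idx[-1]]),
        amplitude_deg=to_degrees((x[idx[0]], y[idx[0]]), (x[idx[-1]], y[idx[-1]]), geometry),
        peak_velocity_deg_s=float(np.max(v)) if v.size else float("nan"),
        mean_velocity_deg_s=float(np.mean(v)) if v.size else float("nan"),
        n_samples=int(len(idx)),
    )


def label_samples(velocity: np.ndarray, threshold_deg_s: float) -> np.ndarray:
    """Naive per-sample I-VT labels: 1 = saccade (v >= threshold), 0 = fixation.

    Samples with undefined velocity inherit the nearest defined label within
    their run (handled by the caller); here they are marked -1.
    """
    lab = np.full(velocity.shape, -1, dtype=np.int8)
    ok = np.isfinite(velocity)
    lab[ok & (velocity >= threshold_deg_s)] = 1
    lab[ok & (velocity < threshold_deg_s)] = 0
    return lab


#: Invalid gaps up to this length (a blink or brief track loss) do not end
#: an ongoing fixation, mirroring the gap fill-in of production I-VT filters.
DEFAULT_MAX_BRIDGE_GAP_S = 0.075


def segment_events(
    stream: pd.DataFrame,
    geometry: ScreenGeometry,
    threshold_deg_s: float = DEFAULT_VELOCITY_THRESHOLD_DEG_S,
    min_duration_s: float = DEFAULT_MIN_EVENT_DURATION_S,
    velocity: np.ndarray | None = None,
    max_gap_s: float = DEFAULT_MAX_BRIDGE_GAP_S,
    bridge_dispersion_deg: float = 1.0,
) -> list[GazeEvent]:
    """I-VT segmentation into alternating fixation/saccade events.

    Within each contiguous valid run, samples at/above the threshold are
    saccadic and below it fixational; run-length grouping turns those labels
    into events.  Boundary samples with undefined velocity adopt the label of
    their nearest interior neighbor.  Events shorter than ``min_duration_s``
    are merged into the preceding event (or the following one at a run start).
    Invalid gaps split events, except that two fixations separated by a gap
    no longer than ``max_gap_s`` whose centroids lie within
    ``bridge_dispersion_deg`` are rejoined (blink bridging; disable with
    ``max_gap_s=0``).  An empty stream yields an empty list.
    """
    if len(stream) == 0:
        return []
    t = stream["time_s"].to_numpy(dtype=float)
    x = stream["x_norm"].to_numpy(dtype=float)
    y = stream["y_norm"].to_numpy(dtype=float)
    if velocity is None:
        velocity = compute_velocity(stream, geometry)
    labels = label_samples(velocity, threshold_deg_s)
    events: list[GazeEvent] = []
    for a, b in _valid_runs(stream["valid"].to_numpy()):
        lab = labels[a:b].copy()
        n = b - a
        if n < 3:
            continue
        # run-boundary samples have no centred velocity: inherit neighbor label
        lab[0] = lab[1]
        lab[-1] = lab[-2]
        # group consecutive equal labels
        edges = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate(([0], edges))
        stops = np.concatenate((edges, [n]))
        groups = [(lab[s], list(range(a + s, a + e))) for s, e in zip(starts, stops)]
        # a run of n samples spans n sample periods
        dt_est = float(np.median(np.diff(t[a:b])))

        def _dur(idx):
            return t[idx[-1]] - t[idx[0]] + dt_est

        # merge sub-minimum groups into the preceding group (first into next)
        merged: list[tuple[int, list[int]]] = []
        for kind, idx in groups:
            if _dur(idx) < min_duration_s and merged:
                merged[-1] = (merged[-1][0], merged[-1][1] + idx)
            elif _dur(idx) < min_duration_s and not merged:
                merged.append((kind, idx))  # provisional; may absorb into next
            else:
                if merged and _dur(merged[-1][1]) < min_duration_s:
                    prev = merged.pop()
                    idx = prev[1] + idx
                merged.append((kind, idx))
        # adjacent same-kind groups produced by merging are coalesced
        coalesced: list[tuple[int, list[int]]] = []
        for kind, idx in merged:
            if coalesced and coalesced[-1][0] == kind:
                coalesced[-1] = (kind, coalesced[-1][1] + idx)
            else:
                coalesced.append((kind, idx))
        for kind, idx in coalesced:
            name = "saccade" if kind == 1 else "fixation"
            events.append(_summarize_event(name, idx, t, x, y, velocity, geometry))
    if max_gap_s > 0:
        events = _bridge_fixations(events, geometry, max_gap_s, bridge_dispersion_deg)
    return events


def _bridge_fixations(
    events: list[GazeEvent], geometry: ScreenGeometry,
    max_gap_s: float, dispersion_deg: float,
) -> list[GazeEvent]:
    """Rejoin fixations split by short invalid gaps with stationary gaze."""
    out: list[GazeEvent] = []
    for ev in events:
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.kind == "fixation" and ev.kind == "fixation"
            and 0.0 < ev.t_on - prev.t_off <= max_gap_s + 1e-9
            and to_degrees((prev.centroid_x, prev.centroid_y),
                           (ev.centroid_x, ev.centroid_y), geometry) <= dispersion_deg
        ):
            n = prev.n_samples + ev.n_samples
            out[-1] = GazeEvent(
                kind="fixation", t_on=prev.t_on, t_off=ev.t_off,
                centroid_x=(prev.centroid_x * prev.n_samples + ev.centroid_x * ev.n_samples) / n,
                centroid_y=(prev.centroid_y * prev.n_samples + ev.centroid_y * ev.n_samples) / n,
                end_x=ev.end_x, end_y=ev.end_y,
                amplitude_deg=max(prev.amplitude_deg, ev.amplitude_deg),
                peak_velocity_deg_s=float(np.nanmax(
                    [prev.peak_velocity_deg_s, ev.peak_velocity_deg_s])),
                mean_velocity_deg_s=float(np.nansum(
                    [prev.mean_velocity_deg_s * prev.n_samples,
                     ev.mean_velocity_deg_s * ev.n_samples]) / n),
                n_samples=n,
            )
        else:
            out.append(ev)
    return out


def events_to_frame(events: list[GazeEvent]) -> pd.DataFrame:
    """Tabulate events; empty input yields an empty frame with all columns."""
    cols = [
        "kind", "t_on", "t_off", "centroid_x", "centroid_y", "end_x", "end_y",
        "amplitude_deg", "peak_velocity_deg_s", "mean_velocity_deg_s", "n_samples",
    ]
    if not events:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(e) for e in events], columns=cols)


def preprocess_stream(
    stream: pd.DataFrame,
    geometry: ScreenGeometry,
    window: int = DEFAULT_SMOOTH_WINDOW,
    order: int = DEFAULT_SMOOTH_ORDER,
    threshold_deg_s: float = DEFAULT_VELOCITY_THRESHOLD_DEG_S,
    min_duration_s: float = DEFAULT_MIN_EVENT_DURATION_S,
) -> tuple[pd.DataFrame, np.ndarray, list[GazeEvent]]:
    """Smooth, differentiate and segment one recording in a single call."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        smoothed = smooth_gaze(stream, window=window, order=order)
    vel = compute_velocity(smoothed, geometry)
    events = segment_events(
        smoothed, geometry, threshold_deg_s=threshold_deg_s,
        min_duration_s=min_duration_s, velocity=vel,
    )
    return smoothed, vel, events


def validate_calibration(
    errors_deg,
    limit_deg: float = 2.0,
    max_failures: int = 1,
    n_points: int = 3,
) -> bool:
    """Calibration-validation gate.

    Each of the ``n_points`` validation targets has a measured accuracy in
    degrees; a point fails when its error exceeds ``limit_deg`` (the limit is
    inclusive: an error of exactly 2 degrees passes).  The recording passes
    unless more than ``max_failures`` points fail.
    """
    errors = [float(e) for e in errors_deg]
    if len(errors) != n_points:
        raise ValueError(f"expected {n_points} validation points, got {len(errors)}")
    failures = sum(e > limit_deg for e in errors)
    return failures <= max_failures
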