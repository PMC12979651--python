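"""Per-trial behavioral and oculomotor features.

All oculomotor measures are computed inside the *target detection period*:
the interval from target onset to the key response (or to trial end when no
key was pressed).  Two bespoke binary measures are defined for social-cue
trials only:

* **RJA** (response to joint attention): the first fixation outside the
  central cue AOI lands in the quadrant the cue indicated, with no
  intermediate visit to another quadrant.
* **Peripheral vision**: gaze never leaves the cue AOI during the whole
  detection period, i.e. the target was handled without an overt gaze shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import GazeEvent, ScreenGeometry, axis_degrees

QUADRANTS = ("TL", "TR", "BL", "BR")


@dataclass(frozen=True)
class AOILayout:
    """Central cue AOI (circle in normalized units) plus screen quadrants.

    The quadrants are delimited by the screen midlines; the cue AOI radius
    defaults to 0.08 normalized units, which covers the 77 px cue stimulus
    on a 1920-wide display with margin.  Screen positions are normalized
    coordinates with origin top-left.
    """

    cue_center: tuple[float, float] = (0.5, 0.5)
    cue_radius: float = 0.08

    def __post_init__(self) -> None:
        if not (0.0 < self.cue_radius < 0.5):
            raise ValueError("cue radius must lie strictly inside the screen")

    def in_cue_aoi(self, x: float, y: float) -> bool:
        return math.hypot(x - self.cue_center[0], y - self.cue_center[1]) <= self.cue_radius

    def quadrant(self, x: float, y: float) -> str:
        if y < 0.5:
            return "TL" if x < 0.5 else "TR"
        return "BL" if x < 0.5 else "BR"


@dataclass(frozen=True)
class DetectionWindow:
    """Half-open interval [start, stop) plus degenerate-input flags."""

    start: float
    stop: float
    has_response: bool
    anticipatory: bool = False

    @property
    def empty(self) -> bool:
        return self.anticipatory or self.stop <= self.start


def detection_window(trial) -> DetectionWindow:
    """Target detection period of one trial.

    ``trial`` is any mapping with ``t_target_on``, ``t_response`` (NaN when no
    key was pressed) and ``t_trial_end``.  A response earlier than target
    onset is anticipatory: the window is empty and flagged.
    """
    t_on = float(trial["t_target_on"])
    t_resp = float(trial["t_response"])
    if not math.isnan(t_resp) and t_resp < t_on:
        return DetectionWindow(t_on, t_on, has_response=True, anticipatory=True)
    if math.isnan(t_resp):
        return DetectionWindow(t_on, float(trial["t_trial_end"]), has_response=False)
    return DetectionWindow(t_on, t_resp, has_response=True)


def _fixations_in(events: list[GazeEvent], window: DetectionWindow) -> list[GazeEvent]:
    return [e for e in events if e.kind == "fixation" and e.t_off > window.start and e.t_on < window.stop]


def _saccades_in(events: list[GazeEvent], window: DetectionWindow) -> list[GazeEvent]:
    # a saccade belongs to the window iff its onset lies inside it
    return [e for e in events if e.kind == "saccade" and window.start <= e.t_on < window.stop]


def _gaze_in_aoi_at_start(
    events: list[GazeEvent], window: DetectionWindow, aoi: AOILayout, grace_s: float = 0.100
) -> bool:
    """Was gaze inside the cue AOI at (or within ``grace_s`` before) window start?"""
    for e in events:
        if e.kind != "fixation":
            continue
        if e.t_on <= window.start <= e.t_off or window.start - grace_s <= e.t_off <= window.start:
            if aoi.in_cue_aoi(e.centroid_x, e.centroid_y):
                return True
    return False


def detect_rja(events: list[GazeEvent], trial, aoi: AOILayout) -> bool | None:
    """Response to joint attention on a social-cue trial; None on nonsocial.

    True iff gaze occupies the cue AOI at the start of the detection period
    and the first fixation outside the AOI lies in the cue-indicated quadrant.
    False when the first exit lands elsewhere or gaze never leaves the AOI.
    """
    if trial["cue_type"] != "social":
        return None
    window = detection_window(trial)
    if window.empty:
        return None
    if not _gaze_in_aoi_at_start(events, window, aoi):
        return False
    for e in _fixations_in(events, window):
        if not aoi.in_cue_aoi(e.centroid_x, e.centroid_y):
            return aoi.quadrant(e.centroid_x, e.centroid_y) == trial["cue_quadrant"]
    return False


def detect_peripheral(events: list[GazeEvent], trial, aoi: AOILayout) -> bool | None:
    """Peripheral-vision use on a social-cue trial; None on nonsocial.

    True iff every fixation in the detection window stays inside the cue AOI
    and no saccade in the window ends outside it.  Assessed regardless of
    button-press accuracy.  Undefined (None) when the window contains no
    events at all, in which case the trial drops out of the rate denominator.
    """
    if trial["cue_type"] != "social":
        return None
    window = detection_window(trial)
    if window.empty:
        return None
    fixations = _fixations_in(events, window)
    saccades = _saccades_in(events, window)
    if not fixations and not saccades:
        return None
    for e in fixations:
        if not aoi.in_cue_aoi(e.centroid_x, e.centroid_y):
            return False
    for e in saccades:
        if not aoi.in_cue_aoi(e.end_x, e.end_y):
            return False
    return True


def _overlap(e: GazeEvent, window: DetectionWindow) -> float:
    return max(0.0, min(e.t_off, window.stop) - max(e.t_on, window.start))


TRIAL_FEATURE_COLUMNS = [
    "rt", "correct", "n_saccades", "saccade_length_deg", "saccade_velocity_deg_s",
    "fix_dur_cue_soa", "sd_fix_locations_deg", "null_rate", "rja", "peripheral",
    "per_fixation_duration", "anticipatory",
]


def extract_trial_features(
    stream: pd.DataFrame,
    events: list[GazeEvent],
    trial,
    aoi: AOILayout,
    geometry: ScreenGeometry,
    saccade_length_stat: str = "mean",
    saccade_velocity_stat: str = "peak",
) -> dict:
    """All per-trial features as a flat dict (NaN/None marks undefined).

    ``saccade_length_stat`` chooses the per-trial summary of saccade
    amplitudes ("mean" or "sum"); ``saccade_velocity_stat`` chooses between
    the mean of per-saccade peak velocities ("peak") and of mean velocities
    ("mean").
    """
    window = detection_window(trial)
    out: dict = {"anticipatory": window.anticipatory}

    out["rt"] = (
        float(trial["t_response"]) - float(trial["t_target_on"])
        if window.has_response and not window.anticipatory
        else float("nan")
    )
    key = trial.get("key_pressed") if hasattr(trial, "get") else trial["key_pressed"]
    out["correct"] = (key == trial["target_quadrant"]) if isinstance(key, str) and key else float("nan")

    saccades = [] if window.empty else _saccades_in(events, window)
    fixations = [] if window.empty else _fixations_in(events, window)

    out["n_saccades"] = len(saccades)
    if saccades:
        amps = np.array([e.amplitude_deg for e in saccades])
        out["saccade_length_deg"] = float(amps.sum() if saccade_length_stat == "sum" else amps.mean())
        if saccade_velocity_stat == "peak":
            vels = np.array([e.peak_velocity_deg_s for e in saccades])
        else:
            vels = np.array([e.mean_velocity_deg_s for e in saccades])
        out["saccade_velocity_deg_s"] = float(np.nanmean(vels))
    else:
        out["saccade_length_deg"] = float("nan")
        out["saccade_velocity_deg_s"] = float("nan")

    # fixation time on the cue AOI between cue offset and target onset
    soa_win = DetectionWindow(float(trial["t_cue_off"]), float(trial["t_target_on"]), True)
    out["fix_dur_cue_soa"] = float(
        sum(
            _overlap(e, soa_win)
            for e in events
            if e.kind == "fixation" and aoi.in_cue_aoi(e.centroid_x, e.centroid_y)
        )
    )

    if len(fixations) >= 2:
        fx = axis_degrees(np.array([e.centroid_x for e in fixations]), geometry.width_cm, geometry)
        fy = axis_degrees(np.array([e.centroid_y for e in fixations]), geometry.height_cm, geometry)
        out["sd_fix_locations_deg"] = float(np.sqrt(np.var(fx, ddof=1) + np.var(fy, ddof=1)))
    else:
        out["sd_fix_locations_deg"] = float("nan")

    valid = stream["valid"].to_numpy(dtype=bool)
    out["null_rate"] = float(1.0 - valid.mean()) if valid.size else float("nan")

    out["rja"] = detect_rja(events, trial, aoi)
    out["peripheral"] = detect_peripheral(events, trial, aoi)

    if fixations:
        total = sum(_overlap(e, window) for e in fixations)
        out["per_fixation_duration"] = float(total / len(fixations))
    else:
        out["per_fixation_duration"] = float("nan")
    return out
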