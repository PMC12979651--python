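"""Synthetic gaze-cueing study generator.

The experimental task: a central cue (a face whose eyes shift, or an arrow)
points at one of the four screen corners for 500 ms; after an SOA of 250,
500 or 750 ms a red target dot appears in a corner, with a blue distractor
dot in another corner, and the child presses the key matching the target
corner.  Congruent trials place the target in the cued corner; incongruent
trials place the *distractor* there.  Four blocks of 36 trials alternate
social/nonsocial cues, with the starting cue type alternating between
participants.

The generator emits, per simulated participant, (a) the trial schedule with
phase timestamps and key responses, (b) a 300 Hz gaze stream in normalized
screen coordinates with validity flags, and (c) questionnaire covariates
drawn from group-conditioned distributions truncated to instrument ranges.
Gaze is built from alternating fixations (dispersion noise around an anchor)
and sigmoid-profile saccades whose peak velocity is tied to amplitude, so the
velocity-threshold segmenter can recover them.  Ground-truth columns
(``gen_*``) record what each trial was built to contain, which lets tests
close the loop between generator and measurement pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ScreenGeometry

QUADRANTS = ("TL", "TR", "BL", "BR")
CONGRUENCIES = ("cong", "incong")
CUE_TYPES = ("social", "nonsocial")


@dataclass(frozen=True)
class TaskConfig:
    """Gaze-cueing task schedule parameters."""

    n_blocks: int = 4
    trials_per_block: int = 36
    soa_levels_ms: tuple[int, ...] = (250, 500, 750)
    cue_phase_ms: float = 500.0
    sampling_rate_hz: float = 300.0
    corner_offset_units: float = 0.2
    stimulus_diameter_px: int = 77
    iti_s: float = 0.2

    def __post_init__(self) -> None:
        if self.n_blocks <= 0 or self.trials_per_block <= 0:
            raise ValueError("block structure must be positive")
        if not 0.0 < self.corner_offset_units < 0.5:
            raise ValueError("corner offset must lie in (0, 0.5)")
        if self.cue_phase_ms <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("durations and rates must be positive")
        if min(self.soa_levels_ms) <= 0:
            raise ValueError("SOA levels must be positive")
        cells = len(self.soa_levels_ms) * len(CONGRUENCIES)
        if self.trials_per_block % cells:
            raise ValueError(
                f"trials_per_block={self.trials_per_block} not divisible by "
                f"{cells} SOA x congruency cells"
            )

    def quadrant_center(self, quadrant: str) -> tuple[float, float]:
        off = self.corner_offset_units
        dx = -off if quadrant in ("TL", "BL") else off
        dy = -off if quadrant in ("TL", "TR") else off
        return (0.5 + dx, 0.5 + dy)


@dataclass(frozen=True)
class GroupParams:
    """Oculomotor, behavioral and questionnaire parameters for one group.

    Oculomotor timing parameters are seconds; ``*_between_sd`` values spread
    participant-level means around the group mean, ``*_within_sd`` values
    spread individual draws around the participant mean.  ``rja_probability``
    is conditional on an overt gaze shift occurring (i.e. on the trial not
    being handled by peripheral vision).  Questionnaire entries are
    (mean, sd) pairs on each instrument's native scale.
    """

    fix_dur_mean_s: float = 0.30
    fix_dur_between_sd_s: float = 0.08
    fix_dur_within_sd_s: float = 0.06
    orienting_latency_s: float = 0.20
    orienting_latency_sd_s: float = 0.05
    saccade_vel_scale: float = 1.0
    rja_probability: float = 0.73
    peripheral_probability: float = 0.56
    rate_between_sd: float = 0.08
    null_rate_mean: float = 0.05
    null_rate_between_sd: float = 0.04
    null_rate_within_sd: float = 0.10
    null_rate_within_spread: float = 0.06
    rt_shift_s: float = 0.25
    rt_scale_s: float = 0.70
    rt_sigma: float = 0.35
    gce_rt_cost_s: float = 0.03
    accuracy: float = 0.97
    goal_directedness: float = 0.7
    kars_inattention: tuple[float, float] = (3.5, 2.8)
    kars_hyperactivity: tuple[float, float] = (2.1, 2.1)
    cars: tuple[float, float] = (15.1, 0.4)
    cdi: tuple[float, float] = (7.7, 3.7)
    staic_state: tuple[float, float] = (30.6, 4.9)
    staic_trait: tuple[float, float] = (28.3, 5.2)
    age_years: tuple[float, float] = (7.9, 0.9)
    male_ratio: float = 0.444
    calib_error_mean_deg: float = 1.4
    calib_error_sd_deg: float = 0.4

    def __post_init__(self) -> None:
        for p in (self.rja_probability, self.peripheral_probability,
                  self.accuracy, self.male_ratio, self.goal_directedness):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for name in ("fix_dur_between_sd_s", "fix_dur_within_sd_s", "rate_between_sd",
                     "null_rate_between_sd", "null_rate_within_sd", "rt_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


#: Typically-developing defaults: faster re-fixation, little track loss,
#: stronger joint-attention response, small cueing cost.
TD_PARAMS = GroupParams()

#: ADHD defaults: longer per-fixation dwell, slower saccades, more track
#: loss, weaker joint-attention response, larger incongruency cost in RT,
#: and clinical-scale distributions shifted upward.
ADHD_PARAMS = GroupParams(
    fix_dur_mean_s=0.42,
    fix_dur_between_sd_s=0.10,
    fix_dur_within_sd_s=0.08,
    saccade_vel_scale=0.90,
    rja_probability=0.61,
    peripheral_probability=0.64,
    null_rate_mean=0.11,
    null_rate_between_sd=0.10,
    null_rate_within_sd=0.15,
    null_rate_within_spread=0.09,
    rt_shift_s=0.25,
    rt_scale_s=0.70,
    rt_sigma=0.55,
    gce_rt_cost_s=0.12,
    accuracy=0.85,
    kars_inattention=(13.7, 6.0),
    kars_hyperactivity=(8.7, 6.0),
    cars=(18.7, 5.3),
    cdi=(13.0, 6.5),
    staic_state=(33.3, 6.9),
    staic_trait=(30.3, 5.8),
    age_years=(7.7, 1.0),
    male_ratio=0.842,
    calib_error_mean_deg=1.3,
)

#: Legal score ranges used to truncate questionnaire draws.
INSTRUMENT_RANGES = {
    "kars_inattention": (0, 27),
    "kars_hyperactivity": (0, 27),
    "cars": (15, 60),
    "cdi": (0, 54),
    "staic_state": (20, 60),
    "staic_trait": (20, 60),
    "age": (6.0, 9.9),
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and per-group parameters."""

    n_adhd: int = 19
    n_td: int = 27
    adhd: GroupParams = field(default_factory=lambda: ADHD_PARAMS)
    td: GroupParams = field(default_factory=lambda: TD_PARAMS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adhd < 0 or self.n_td < 0:
            raise ValueError("group sizes must be nonnegative")


TRIAL_COLUMNS = [
    "block", "trial", "cue_type", "congruency", "soa_ms",
    "cue_quadrant", "target_quadrant", "distractor_quadrant",
    "t_cue_on", "t_cue_off", "t_target_on", "t_response", "t_trial_end",
    "key_pressed", "correct",
]


def generate_session_schedule(
    config: TaskConfig, seed: int, social_first: bool = True
) -> pd.DataFrame:
    """One participant's trial schedule (responses left unset).

    Each block holds an equal number of trials per SOA x congruency cell in
    random order; cue type is constant within a block and alternates between
    blocks.  Cue quadrants are balanced within block; congruent trials put
    the target in the cued quadrant, incongruent trials put the distractor
    there.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    per_cell = config.trials_per_block // (len(config.soa_levels_ms) * len(CONGRUENCIES))
    if config.trials_per_block % len(QUADRANTS):
        cue_pool_base = list(QUADRANTS) * math.ceil(config.trials_per_block / len(QUADRANTS))
        cue_pool_base = cue_pool_base[: config.trials_per_block]
    else:
        cue_pool_base = list(QUADRANTS) * (config.trials_per_block // len(QUADRANTS))

    rows = []
    t = 0.0
    for block in range(config.n_blocks):
        social = (block % 2 == 0) == social_first
        cells = [
            (soa, cong)
            for soa in config.soa_levels_ms
            for cong in CONGRUENCIES
            for _ in range(per_cell)
        ]
        rng.shuffle(cells)
        cues = list(cue_pool_base)
        rng.shuffle(cues)
        for trial, ((soa, cong), cue_q) in enumerate(zip(cells, cues)):
            others = [q for q in QUADRANTS if q != cue_q]
            if cong == "cong":
                target_q = cue_q
                distractor_q = others[rng.integers(len(others))]
            else:
                distractor_q = cue_q
                target_q = others[rng.integers(len(others))]
            t_cue_on = t
            t_cue_off = t_cue_on + config.cue_phase_ms / 1000.0
            t_target_on = t_cue_off + soa / 1000.0
            rows.append({
                "block": block, "trial": trial, "cue_type": "social" if social else "nonsocial",
                "congruency": cong, "soa_ms": int(soa),
                "cue_quadrant": cue_q, "target_quadrant": target_q,
                "distractor_quadrant": distractor_q,
                "t_cue_on": t_cue_on, "t_cue_off": t_cue_off, "t_target_on": t_target_on,
                "t_response": float("nan"), "t_trial_end": float("nan"),
                "key_pressed": "", "correct": float("nan"),
            })
            # provisional trial end; rewritten once the response is simulated
            t = t_target_on + 3.0
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


@dataclass(frozen=True)
class ParticipantTraits:
    """Participant-level realization of group parameters."""

    fix_dur_s: float
    fix_dur_within_sd_s: float
    orienting_latency_s: float
    saccade_vel_scale: float
    rja_probability: float
    peripheral_probability: float
    null_rate: float
    null_rate_within_sd: float
    rt_shift_s: float
    rt_scale_s: float
    rt_sigma: float
    gce_rt_cost_s: float
    accuracy: float
    goal_directedness: float


def realize_traits(params: GroupParams, rng: np.random.Generator) -> ParticipantTraits:
    """Draw one participant's oculomotor/behavioral traits from group ranges."""
    clip01 = lambda v: float(np.clip(v, 0.0, 1.0))
    return ParticipantTraits(
        fix_dur_s=float(np.clip(rng.normal(params.fix_dur_mean_s, params.fix_dur_between_sd_s), 0.10, 1.2)),
        fix_dur_within_sd_s=params.fix_dur_within_sd_s,
        orienting_latency_s=float(np.clip(
            rng.normal(params.orienting_latency_s, params.orienting_latency_sd_s), 0.08, 0.5)),
        saccade_vel_scale=float(np.clip(rng.normal(params.saccade_vel_scale, 0.05), 0.5, 2.0)),
        rja_probability=clip01(rng.normal(params.rja_probability, params.rate_between_sd)),
        peripheral_probability=clip01(rng.normal(params.peripheral_probability, params.rate_between_sd)),
        null_rate=float(np.clip(rng.normal(params.null_rate_mean, params.null_rate_between_sd), 0.0, 0.6)),
        null_rate_within_sd=(
            0.0 if params.null_rate_within_sd == 0.0
            else float(np.clip(
                rng.normal(params.null_rate_within_sd, params.null_rate_within_spread),
                0.01, 0.4))),
        rt_shift_s=params.rt_shift_s,
        rt_scale_s=float(np.clip(rng.normal(params.rt_scale_s, 0.08), 0.3, 2.0)),
        rt_sigma=float(np.clip(rng.normal(params.rt_sigma, 0.15), 0.10, 1.2)),
        gce_rt_cost_s=params.gce_rt_cost_s,
        accuracy=clip01(rng.normal(params.accuracy, 0.04)),
        goal_directedness=params.goal_directedness,
    )


def _saccade_duration(amplitude_deg: float, vel_scale: float) -> float:
    """Duration giving a main-sequence-like peak velocity for this amplitude.

    The sigmoid profile used below peaks at ``2.5 * amplitude / duration``
    deg/s; the target peak grows affinely with amplitude and is always at
    least twice the 30 deg/s classification threshold.
    """
    peak = max(2.0 * 30.0 * 1.4, vel_scale * (55.0 + 4.5 * amplitude_deg))
    return max(0.04, 2.5 * amplitude_deg / peak)


def _saccade_super_threshold_interval(
    t0: float, t1: float, p0, p1, geometry: ScreenGeometry,
    threshold_deg_s: float = 30.0,
) -> tuple[float, float]:
    """Time interval where the planned sigmoid saccade exceeds the threshold.

    The logistic profile with slope parameter ``s = duration/10`` has
    velocity ``peak * 4 f (1-f)`` with ``f`` the completed fraction, so the
    threshold crossings sit at ``f = (1 ± sqrt(1 - thr/peak)) / 2``.
    """
    amp = _norm_to_deg(p0, p1, geometry)
    dur = t1 - t0
    if amp <= 0.0 or dur <= 0.0:
        return (t1, t1)
    peak = 2.5 * amp / dur
    ratio = threshold_deg_s / peak
    if ratio >= 1.0:
        return (t1, t1)  # never crosses: no saccadic interval
    s = dur / 10.0
    mid = (t0 + t1) / 2.0
    f_hi = (1.0 + math.sqrt(1.0 - ratio)) / 2.0
    half = s * math.log(f_hi / (1.0 - f_hi))
    return (max(t0, mid - half), min(t1, mid + half))


def _norm_to_deg(p0, p1, geometry: ScreenGeometry) -> float:
    dx = (p1[0] - p0[0]) * geometry.width_cm
    dy = (p1[1] - p0[1]) * geometry.height_cm
    d = math.hypot(dx, dy)
    return math.degrees(2.0 * math.atan2(d / 2.0, geometry.viewing_distance_cm))


def _plan_trial(trial, traits: ParticipantTraits, config: TaskConfig,
                geometry: ScreenGeometry, rng: np.random.Generator) -> dict:
    """Plan one trial: event segments, response time/key, and ground truth.

    Returns a dict with ``segments`` (list of (kind, t0, t1, p0, p1)),
    response fields and ``gen_*`` ground-truth entries.  The response lands
    at the end of the fixation in progress when the planned RT elapses (or
    at the planned time during a peripheral trial), so the planned
    congruency-dependent RT is realized in expectation.  Holds at the screen
    center are rendered as chains of refixations inside the cue AOI
    separated by small saccades, as fixational drift produces in real
    recordings.
    """
    center = (0.5, 0.5)
    social = trial["cue_type"] == "social"
    t_target = trial["t_target_on"]

    rt_planned = traits.rt_shift_s + traits.rt_scale_s * math.exp(
        traits.rt_sigma * rng.standard_normal())
    if social and trial["congruency"] == "incong":
        rt_planned += traits.gce_rt_cost_s
    t_resp_planned = t_target + rt_planned

    peripheral = social and (rng.random() < traits.peripheral_probability)
    rja = (not peripheral) and (rng.random() < traits.rja_probability) if social else False

    def anchor(quadrant: str) -> tuple[float, float]:
        cx, cy = config.quadrant_center(quadrant)
        return (cx + rng.normal(0.0, 0.025), cy + rng.normal(0.0, 0.025))

    def fix_dur() -> float:
        return max(0.06, rng.normal(traits.fix_dur_s, traits.fix_dur_within_sd_s))

    def center_anchor() -> tuple[float, float]:
        # refixation anchors stay well inside the cue AOI (radius ~0.08)
        return (center[0] + float(np.clip(rng.normal(0.0, 0.015), -0.045, 0.045)),
                center[1] + float(np.clip(rng.normal(0.0, 0.015), -0.045, 0.045)))

    def refix_anchor(pos) -> tuple[float, float]:
        # next hold anchor: at least ~1 degree away so the shift is a real,
        # detectable saccade, still inside the cue AOI
        ang = rng.uniform(0.0, 2.0 * math.pi)
        r = rng.uniform(0.028, 0.055)
        return (float(np.clip(pos[0] + r * math.cos(ang), 0.455, 0.545)),
                float(np.clip(pos[1] + r * math.sin(ang), 0.455, 0.545)))

    def hold(segments, t0, t1, pos):
        """Fill [t0, t1) with within-AOI refixations; return final position."""
        t = t0
        while True:
            end = min(t + fix_dur(), t1)
            segments.append(("fixation", t, end, pos, pos))
            t = end
            if t >= t1 - 1e-9:
                return pos
            new = refix_anchor(pos)
            amp = _norm_to_deg(pos, new, geometry)
            for _ in range(5):  # clipping at the AOI box can shrink the hop
                if amp >= 0.5:
                    break
                new = refix_anchor(pos)
                amp = _norm_to_deg(pos, new, geometry)
            dur = _saccade_duration(amp, traits.saccade_vel_scale)
            if t + dur >= t1:
                segments[-1] = ("fixation", segments[-1][1], t1, pos, pos)
                return pos
            segments.append(("saccade", t, t + dur, pos, new))
            t += dur
            pos = new

    segments = []
    if peripheral:
        t_resp = t_resp_planned
        t_end = t_resp + 0.05
        hold(segments, trial["t_cue_on"], t_end, center_anchor())
    else:
        t_shift = t_target + max(0.08, rng.normal(traits.orienting_latency_s, 0.04))
        pos = hold(segments, trial["t_cue_on"], t_shift, center_anchor())
        pos_q = None
        if social:
            first_q = trial["cue_quadrant"] if rja else \
                str(rng.choice([q for q in QUADRANTS if q != trial["cue_quadrant"]]))
        else:
            first_q = trial["target_quadrant"] if rng.random() < traits.goal_directedness \
                else str(rng.choice([q for q in QUADRANTS if q != trial["target_quadrant"]]))
        # the key press follows the planned RT, rounded up to the end of the
        # fixation then in progress, so all window fixations are complete and
        # the planned (congruency-dependent) RT is realized in expectation
        t, dest_q = t_shift, first_q
        while True:
            dest = anchor(dest_q)
            amp = _norm_to_deg(pos, dest, geometry)
            dur = _saccade_duration(amp, traits.saccade_vel_scale)
            segments.append(("saccade", t, t + dur, pos, dest))
            t += dur
            pos, pos_q = dest, dest_q
            fdur = fix_dur()
            segments.append(("fixation", t, t + fdur, pos, pos))
            t += fdur
            if t >= t_resp_planned:
                t_resp = t  # respond as the current fixation completes
                break
            # keep scanning: hop toward the target (goal-biased) or elsewhere
            others = [q for q in QUADRANTS if q != pos_q]
            if pos_q != trial["target_quadrant"] and rng.random() < traits.goal_directedness:
                dest_q = trial["target_quadrant"]
            else:
                dest_q = str(rng.choice(others))
        t_end = t_resp + 0.05

    correct = rng.random() < traits.accuracy
    key = trial["target_quadrant"] if correct else \
        str(rng.choice([q for q in QUADRANTS if q != trial["target_quadrant"]]))

    # Ground truth for the detection window [t_target, t_resp], using I-VT
    # semantics: the sub-threshold ramp tails of each sigmoid saccade count
    # as fixation time, exactly as a velocity-threshold segmenter sees them.
    super_ivals = [
        _saccade_super_threshold_interval(t0, t1, p0, p1, geometry)
        for kind, t0, t1, p0, p1 in segments if kind == "saccade"
    ]
    window = t_resp - t_target
    sacc_time = sum(
        max(0.0, min(b, t_resp) - max(a, t_target)) for a, b in super_ivals if a < b
    )
    n_fix_win = sum(
        1 for kind, t0, t1, _, _ in segments
        if kind == "fixation" and min(t1, t_resp) - max(t0, t_target) > 0
    )
    gen_mean_fix = (window - sacc_time) / n_fix_win if n_fix_win else float("nan")
    gen_n_sacc = sum(
        1 for kind, t0, _, _, _ in segments
        if kind == "saccade" and t_target <= t0 < t_resp
    )

    return {
        "segments": segments, "t_response": t_resp, "t_trial_end": t_end,
        "key_pressed": key, "correct": bool(correct),
        "gen_rja": bool(rja) if social else None,
        "gen_peripheral": bool(peripheral) if social else None,
        "gen_n_saccades": gen_n_sacc,
        "gen_mean_fix_dur": gen_mean_fix,
    }


def render_segments(
    segments, t_start: float, t_end: float, sampling_rate_hz: float,
    rng: np.random.Generator, jitter_sd: float = 0.0015,
) -> pd.DataFrame:
    """Sample planned segments onto a regular time grid with fixation noise."""
    dt = 1.0 / sampling_rate_hz
    t = np.arange(t_start, t_end, dt)
    x = np.empty_like(t)
    y = np.empty_like(t)
    # fill from the last segment backwards so later segments win overlaps
    x[:] = segments[0][3][0]
    y[:] = segments[0][3][1]
    for kind, t0, t1, p0, p1 in segments:
        m = (t >= t0) & (t < t1)
        if not m.any():
            continue
        if kind == "fixation":
            x[m] = p0[0]
            y[m] = p0[1]
        else:
            # logistic displacement profile; peak velocity = 2.5*amp/duration
            s = (t1 - t0) / 10.0
            mid = (t0 + t1) / 2.0
            frac = 1.0 / (1.0 + np.exp(-(t[m] - mid) / s))
            x[m] = p0[0] + (p1[0] - p0[0]) * frac
            y[m] = p0[1] + (p1[1] - p0[1]) * frac
    # hold the final position after the last segment
    last_t1 = max(seg[2] for seg in segments)
    hold = t >= last_t1
    if hold.any():
        lx, ly = segments[-1][4]
        x[hold], y[hold] = lx, ly
    x = x + rng.normal(0.0, jitter_sd, t.size)
    y = y + rng.normal(0.0, jitter_sd, t.size)
    return pd.DataFrame({
        "time_s": t, "x_norm": np.clip(x, 0.0, 1.0),
        "y_norm": np.clip(y, 0.0, 1.0), "valid": np.ones(t.size, dtype=bool),
    })


def _draw_trial_null_rate(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Per-trial track-loss fraction: Beta with matched mean/SD on [0, 1].

    A Beta keeps the participant-level mean unbiased (a clipped normal at a
    small mean would inflate it) and yields the heavy right skew real
    dropout shows.  Degenerate requests (zero mean or zero spread) return
    the mean itself.
    """
    if mean <= 0.0:
        return 0.0
    if sd <= 0.0:
        return float(min(mean, 0.95))
    var = min(sd * sd, 0.99 * mean * (1.0 - mean))
    if var <= 1e-12:
        return float(min(mean, 0.95))
    k = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * k, (1.0 - mean) * k))


def apply_track_loss(
    stream: pd.DataFrame, null_rate: float, rng: np.random.Generator,
    mean_burst_samples: int = 15,
) -> pd.DataFrame:
    """Flag approximately ``null_rate`` of samples invalid, in short bursts.

    Track loss in recordings of young children is bursty (partial eyelid
    closure, head turns), not sample-wise independent; the default ~50 ms
    bursts match the micro-dropouts a gap-bridging I-VT filter is designed
    to ride over.  Invalid samples get NaN coordinates.
    """
    n = len(stream)
    target = int(round(float(np.clip(null_rate, 0.0, 0.95)) * n))
    if target <= 0:
        return stream
    valid = stream["valid"].to_numpy().copy()
    budget = target
    guard = 0
    while budget > 0 and guard < 10 * n:
        start = int(rng.integers(0, n))
        length = min(budget, 1 + int(rng.geometric(1.0 / mean_burst_samples)), n - start)
        newly = int(valid[start : start + length].sum())
        valid[start : start + length] = False
        budget -= newly
        guard += 1
    out = stream.copy()
    out["valid"] = valid
    out.loc[~valid, ["x_norm", "y_norm"]] = np.nan
    return out


def simulate_gaze_stream(
    trial, traits: ParticipantTraits, config: TaskConfig,
    geometry: ScreenGeometry, seed,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one trial's gaze segment plus response and ground truth.

    Returns ``(stream, info)`` where ``info`` carries the response fields and
    ``gen_*`` ground truth produced by the trial plan.  Deterministic given
    ``seed`` (an int or a ``SeedSequence``-compatible value).
    """
    rng = np.random.default_rng(seed)
    plan = _plan_trial(trial, traits, config, geometry, rng)
    q_trial = _draw_trial_null_rate(traits.null_rate, traits.null_rate_within_sd, rng)
    stream = render_segments(
        plan["segments"], trial["t_cue_on"], plan["t_trial_end"],
        config.sampling_rate_hz, rng)
    stream = apply_track_loss(stream, q_trial, rng)
    info = {k: v for k, v in plan.items() if k != "segments"}
    info["gen_null_rate"] = float(1.0 - stream["valid"].mean())
    info["gen_null_rate_target"] = q_trial
    return stream, info


PARTICIPANT_COLUMNS = [
    "id", "group", "age", "sex", "kars_inattention", "kars_hyperactivity",
    "kars_total", "cars", "cdi", "staic_state", "staic_trait",
    "calib_errors_deg", "calibration_pass", "social_first",
]


def draw_questionnaires(params: GroupParams, rng: np.random.Generator) -> dict:
    """Questionnaire and demographic draws respecting instrument ranges.

    Scores are drawn as ``floor + Gamma`` with the gamma moments matched to
    the requested mean and SD: the draw respects the scale floor without the
    mean bias a clipped normal would introduce, and gives symptom scores
    their typical right skew.  The instrument ceiling is enforced by
    clipping (negligible mass).
    """
    def trunc(key, pair):
        lo, hi = INSTRUMENT_RANGES[key]
        mean, sd = pair
        if mean <= lo or sd <= 0:
            return float(lo if mean <= lo else min(mean, hi))
        shape = ((mean - lo) / sd) ** 2
        scale = sd * sd / (mean - lo)
        return float(min(lo + rng.gamma(shape, scale), hi))

    inatt = trunc("kars_inattention", params.kars_inattention)
    hyper = trunc("kars_hyperactivity", params.kars_hyperactivity)
    return {
        "age": round(trunc("age", params.age_years), 1),
        "sex": "M" if rng.random() < params.male_ratio else "F",
        "kars_inattention": round(inatt),
        "kars_hyperactivity": round(hyper),
        "kars_total": round(inatt) + round(hyper),
        "cars": round(trunc("cars", params.cars), 1),
        "cdi": round(trunc("cdi", params.cdi)),
        "staic_state": round(trunc("staic_state", params.staic_state)),
        "staic_trait": round(trunc("staic_trait", params.staic_trait)),
    }


def simulate_participant(
    pid: str, group: str, params: GroupParams, config: TaskConfig,
    geometry: ScreenGeometry, seed_seq: np.random.SeedSequence,
    social_first: bool,
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Simulate one participant: metadata row, trial log, gaze stream."""
    child = seed_seq.spawn(3)
    rng_meta = np.random.default_rng(child[0])
    traits = realize_traits(params, rng_meta)
    meta = {"id": pid, "group": group, **draw_questionnaires(params, rng_meta)}
    errs = np.abs(rng_meta.normal(params.calib_error_mean_deg, params.calib_error_sd_deg, 3))
    meta["calib_errors_deg"] = ";".join(f"{e:.2f}" for e in errs)
    from .preprocess import validate_calibration
    meta["calibration_pass"] = validate_calibration(errs)
    meta["social_first"] = social_first

    schedule = generate_session_schedule(
        config, seed=int(child[1].generate_state(1)[0] % (2**31)), social_first=social_first)
    trial_seeds = child[2].spawn(len(schedule))
    streams = []
    extras = []
    t_offset = 0.0
    for i, row in schedule.iterrows():
        trial = row.to_dict()
        # re-base trial clock so trials are contiguous after variable RTs
        shift = t_offset - trial["t_cue_on"]
        for k in ("t_cue_on", "t_cue_off", "t_target_on"):
            trial[k] += shift
        stream, info = simulate_gaze_stream(trial, traits, config, geometry, trial_seeds[i])
        trial.update({
            "t_response": info["t_response"], "t_trial_end": info["t_trial_end"] + config.iti_s,
            "key_pressed": info["key_pressed"], "correct": info["correct"],
        })
        for k in ("gen_rja", "gen_peripheral", "gen_n_saccades",
                  "gen_mean_fix_dur", "gen_null_rate", "gen_null_rate_target"):
            trial[k] = info[k]
        t_offset = trial["t_trial_end"]
        streams.append(stream)
        extras.append(trial)
    trials = pd.DataFrame(extras)
    trials["participant"] = pid
    gaze = pd.concat(streams, ignore_index=True)
    return meta, trials, gaze


def simulate_cohort(
    spec: CohortSpec, config: TaskConfig | None = None,
    geometry: ScreenGeometry | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate the full cohort.

    Returns ``(participants, trials, gaze)``: the participant table, the
    concatenated trial log, and a dict of per-participant gaze streams.  The
    block-order (social-first vs nonsocial-first) alternates across
    participants.  A single master seed fans out to per-participant and
    per-trial substreams, so any participant's data is reproducible in
    isolation.
    """
    config = config or TaskConfig()
    geometry = geometry or ScreenGeometry(sampling_rate_hz=config.sampling_rate_hz)
    root = np.random.SeedSequence(spec.seed)
    n_total = spec.n_adhd + spec.n_td
    seqs = root.spawn(n_total)
    metas, trial_frames, gaze = [], [], {}
    labels = ["ADHD"] * spec.n_adhd + ["TD"] * spec.n_td
    for i, group in enumerate(labels):
        pid = f"{group.lower()}{i:03d}"
        params = spec.adhd if group == "ADHD" else spec.td
        meta, trials, stream = simulate_participant(
            pid, group, params, config, geometry, seqs[i], social_first=(i % 2 == 0))
        metas.append(meta)
        trial_frames.append(trials)
        gaze[pid] = stream
    participants = pd.DataFrame(metas, columns=PARTICIPANT_COLUMNS)
    all_trials = pd.concat(trial_frames, ignore_index=True)
    return participants, all_trials, gaze
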