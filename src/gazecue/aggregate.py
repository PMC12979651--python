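"""Participant-level aggregation of trial features.

Trial features collapse to one row per participant with a stable column
naming scheme ``feature.cue.soa.congruency`` (e.g. ``nsacc.social.0.25.cong``).
Continuous features take the *median* over a condition's trials (robust to
outliers); binary features (RJA, peripheral vision, accuracy) take the mean,
i.e. the rate of occurrence.  The gaze-cueing effect (GCE) of a feature at a
given SOA is its incongruent-cell value minus its congruent-cell value, on
social-cue trials.  Eligibility filters reproduce the study's inclusion
rules on the questionnaire covariates and the calibration gate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: trial-feature name -> (column in the trial feature table, kind)
CONDITION_FEATURES = {
    "rt": ("rt", "continuous"),
    "acc": ("correct", "binary"),
    "nsacc": ("n_saccades", "continuous"),
    "slen": ("saccade_length_deg", "continuous"),
    "svel": ("saccade_velocity_deg_s", "continuous"),
    "fixcue": ("fix_dur_cue_soa", "continuous"),
    "sdfix": ("sd_fix_locations_deg", "continuous"),
    "null": ("null_rate", "continuous"),
    "rja": ("rja", "binary"),
    "periph": ("peripheral", "binary"),
    "pfd": ("per_fixation_duration", "continuous"),
}

#: features restricted to social-cue blocks
SOCIAL_ONLY = {"rja", "periph"}

#: features whose GCE (incongruent - congruent per SOA, social cues) is kept
GCE_FEATURES = ("rt", "nsacc", "slen", "svel", "sdfix", "pfd")


def soa_label(soa_ms: int) -> str:
    return f"{soa_ms / 1000:g}"


def condition_column(feature: str, cue: str, soa_ms: int, congruency: str) -> str:
    return f"{feature}.{cue}.{soa_label(soa_ms)}.{congruency}"


def gce_column(feature: str, soa_ms: int) -> str:
    return f"gce_{feature}.{soa_label(soa_ms)}"


def _cell_value(values: pd.Series, kind: str) -> float:
    v = pd.to_numeric(values, errors="coerce").dropna()
    if v.empty:
        return float("nan")
    return float(v.mean() if kind == "binary" else v.median())


def aggregate_participant(trial_features: pd.DataFrame, participant_meta: dict) -> dict:
    """Collapse one participant's trial feature table to a single row.

    ``trial_features`` must carry the trial design columns (``cue_type``,
    ``soa_ms``, ``congruency``) alongside the per-trial features.  Cells with
    no usable trials are recorded as missing, never as zero.  RT cells are
    computed regardless of response accuracy; ``rt_correct`` pools correct
    trials only; ``rt_sd`` is the SD of RT over all trials.
    """
    row: dict = dict(participant_meta)
    tf = trial_features
    soas = sorted(tf["soa_ms"].unique())
    for feat, (col, kind) in CONDITION_FEATURES.items():
        cues = ("social",) if feat in SOCIAL_ONLY else ("social", "nonsocial")
        for cue in cues:
            for soa in soas:
                for cong in ("cong", "incong"):
                    cell = tf[(tf["cue_type"] == cue) & (tf["soa_ms"] == soa)
                              & (tf["congruency"] == cong)]
                    row[condition_column(feat, cue, soa, cong)] = _cell_value(cell[col], kind)
    for feat in GCE_FEATURES:
        for soa in soas:
            row[gce_column(feat, soa)] = compute_gce(row, feat, soa)

    rt_all = pd.to_numeric(tf["rt"], errors="coerce").dropna()
    row["rt_sd"] = float(rt_all.std(ddof=1)) if len(rt_all) >= 2 else float("nan")
    rt_corr = pd.to_numeric(tf.loc[tf["correct"] == True, "rt"], errors="coerce").dropna()  # noqa: E712
    row["rt_correct"] = float(rt_corr.median()) if len(rt_corr) else float("nan")

    nr = pd.to_numeric(tf["null_rate"], errors="coerce").dropna()
    row["null_rate"] = float(nr.mean()) if len(nr) else float("nan")
    row["sd_null_rate"] = float(nr.std(ddof=1)) if len(nr) >= 2 else float("nan")

    social = tf[tf["cue_type"] == "social"]
    pfd = pd.to_numeric(social["per_fixation_duration"], errors="coerce").dropna()
    row["pfd.social"] = float(pfd.median()) if len(pfd) else float("nan")
    rja = pd.to_numeric(social["rja"], errors="coerce").dropna()
    row["rja.social"] = float(rja.mean()) if len(rja) else float("nan")
    per = pd.to_numeric(social["peripheral"], errors="coerce").dropna()
    row["periph.social"] = float(per.mean()) if len(per) else float("nan")
    return row


def compute_gce(row, feature: str, soa_ms: int) -> float:
    """Gaze-cueing effect: incongruent minus congruent, social cues, one SOA.

    Missing in either cell propagates to a missing GCE.
    """
    inc = row.get(condition_column(feature, "social", soa_ms, "incong"), float("nan"))
    con = row.get(condition_column(feature, "social", soa_ms, "cong"), float("nan"))
    inc, con = float(inc), float(con)
    if np.isnan(inc) or np.isnan(con):
        return float("nan")
    return inc - con


def build_participant_matrix(
    trial_features: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate every participant and join the metadata table."""
    rows = []
    for _, meta in participants.iterrows():
        tf = trial_features[trial_features["participant"] == meta["id"]]
        rows.append(aggregate_participant(tf, meta.to_dict()))
    return pd.DataFrame(rows)


# Inclusion rules on the clinical scales (see apply_eligibility_filters).
ADHD_INATTENTION_MIN_EXCLUSIVE = 5   # ADHD rows with inattention <= 5 excluded
TD_INATTENTION_MAX_EXCLUSIVE = 10    # TD rows with inattention >= 10 excluded
TD_KARS_TOTAL_MAX_EXCLUSIVE = 18     # TD rows with KARS total >= 18 excluded
CARS_CUTOFF = 37                     # any row with CARS >= 37 excluded


def apply_eligibility_filters(
    participant_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort inclusion rules; return (retained, exclusion log).

    ADHD participants with a KARS inattention score at or below 5 are
    excluded (symptoms too mild for the clinical group); TD participants
    with inattention of 10 or more, or KARS total of 18 or more, are
    excluded (subclinical elevation); anyone with CARS of 37 or more (high
    autism risk) or a failed calibration gate is excluded.  Rows with a
    missing covariate are flagged in the log but retained.
    """
    reasons: list[dict] = []
    keep = np.ones(len(participant_table), dtype=bool)
    for i, (_, row) in enumerate(participant_table.iterrows()):
        pid = row["id"]
        needed = ["kars_inattention", "kars_total", "cars"]
        missing = [c for c in needed if pd.isna(row.get(c))]
        if missing:
            reasons.append({"id": pid, "reason": f"missing covariate: {','.join(missing)}",
                            "excluded": False})
            continue
        if row["group"] == "ADHD" and row["kars_inattention"] <= ADHD_INATTENTION_MIN_EXCLUSIVE:
            reasons.append({"id": pid, "reason": "ADHD inattention <= 5", "excluded": True})
            keep[i] = False
        elif row["group"] == "TD" and row["kars_inattention"] >= TD_INATTENTION_MAX_EXCLUSIVE:
            reasons.append({"id": pid, "reason": "TD inattention >= 10", "excluded": True})
            keep[i] = False
        elif row["group"] == "TD" and row["kars_total"] >= TD_KARS_TOTAL_MAX_EXCLUSIVE:
            reasons.append({"id": pid, "reason": "TD KARS total >= 18", "excluded": True})
            keep[i] = False
        elif row["cars"] >= CARS_CUTOFF:
            reasons.append({"id": pid, "reason": "CARS >= 37", "excluded": True})
            keep[i] = False
        elif "calibration_pass" in row.index and row["calibration_pass"] is False:
            reasons.append({"id": pid, "reason": "calibration validation failed",
                            "excluded": True})
            keep[i] = False
    log = pd.DataFrame(reasons, columns=["id", "reason", "excluded"])
    return participant_table[keep].reset_index(drop=True), log


def impute_for_modeling(
    matrix: pd.DataFrame, feature_cols: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-impute missing feature cells within group, for model fitting.

    Group-level statistics (Mann-Whitney screens) use complete cases; only
    the classification models see imputed values.  Returns the imputed
    matrix and a boolean missingness-flag frame of the same shape.
    """
    out = matrix.copy()
    flags = pd.DataFrame(False, index=matrix.index, columns=feature_cols)
    for col in feature_cols:
        vals = pd.to_numeric(out[col], errors="coerce")
        flags[col] = vals.isna()
        for group, idx in out.groupby("group").groups.items():
            med = vals.loc[idx].median()
            if np.isnan(med):
                med = vals.median()
            out.loc[idx, col] = vals.loc[idx].fillna(med)
    return out, flags
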