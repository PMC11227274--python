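"""End-to-end analysis: dataset -> stride and trial parameter tables.

Ties the modules together: segments every trial into strides, computes
stride parameters, classifies footfall patterns, detects aerial phases and
attaches the half-cosine peak-force estimate, producing tidy DataFrames
that mirror the derived stride-parameter CSV schema.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .events import Dataset, LimbId, TrialRecord
from .gaits import classify, detect_aerial, support_timeline
from .kinematics import (
    StrideParams,
    TrialSummary,
    segment_strides,
    stride_params,
    trial_means,
)
from .loading import DEFAULT_FORELIMB_SHARE, peak_vertical_grf

__all__ = [
    "analyze_trial",
    "stride_table",
    "trial_table",
    "write_stride_csv",
]

STRIDE_COLUMNS = [
    "trial_id",
    "stride_index",
    "phase_LF",
    "phase_RH",
    "phase_RF",
    "df_LH",
    "df_LF",
    "df_RH",
    "df_RF",
    "df_mean",
    "sf_hz",
    "stance_s",
    "swing_s",
    "class8",
    "class4",
    "locomotion",
    "symmetry",
    "has_aerial",
    "aerial_fraction",
    "predicted_aerial",
]


def analyze_trial(trial: TrialRecord) -> tuple[list[StrideParams], TrialSummary | None]:
    """Per-stride parameters and the trial summary (None if no complete stride)."""
    strides = [stride_params(s) for s in segment_strides(trial)]
    return strides, (trial_means(strides) if strides else None)


def _classification_row(params: StrideParams | TrialSummary) -> dict:
    gait = classify(params)
    aerial = detect_aerial(support_timeline(params), params)
    return {
        "class8": gait.class8,
        "class4": gait.class4,
        "locomotion": gait.locomotion,
        "symmetry": gait.symmetry,
        "has_aerial": aerial.has_aerial,
        "aerial_fraction": aerial.aerial_fraction,
        "predicted_aerial": aerial.predicted_simplified,
    }


def stride_table(data: Dataset) -> pd.DataFrame:
    """One row per complete stride, with kinematics and classification."""
    rows = []
    for trial in data:
        strides, _ = analyze_trial(trial)
        for i, p in enumerate(strides):
            row = {
                "trial_id": trial.trial_id,
                "stride_index": i,
                "phase_LF": p.phases[LimbId.LF],
                "phase_RH": p.phases[LimbId.RH],
                "phase_RF": p.phases[LimbId.RF],
                "df_LH": p.duty_factors[LimbId.LH],
                "df_LF": p.duty_factors[LimbId.LF],
                "df_RH": p.duty_factors[LimbId.RH],
                "df_RF": p.duty_factors[LimbId.RF],
                "df_mean": p.df_mean,
                "sf_hz": p.stride_frequency,
                "stance_s": sum(p.stance.values()) / 4.0,
                "swing_s": sum(p.swing.values()) / 4.0,
            }
            row.update(_classification_row(p))
            rows.append(row)
    return pd.DataFrame(rows, columns=STRIDE_COLUMNS)


def trial_table(
    data: Dataset, limb_share: float = DEFAULT_FORELIMB_SHARE
) -> pd.DataFrame:
    """One row per analyzable trial: mean stride parameters, classification
    of the trial-mean gait, and the forelimb peak-force estimate
    (``peak_vgrf_bw``, half-cosine model at the trial's forelimb DF)."""
    rows = []
    for trial in data:
        _, summary = analyze_trial(trial)
        if summary is None:
            continue
        row = {
            "trial_id": trial.trial_id,
            "individual_id": trial.individual_id,
            "source": trial.source,
            "n_strides": summary.n_strides,
            "phase_LF": summary.phases[LimbId.LF],
            "phase_RH": summary.phases[LimbId.RH],
            "phase_RF": summary.phases[LimbId.RF],
            "df_mean": summary.df_mean,
            "df_fore": summary.df_fore,
            "df_hind": summary.df_hind,
            "sf_hz": summary.stride_frequency,
            "stance_s": summary.stance,
            "swing_s": summary.swing,
            "peak_vgrf_bw": peak_vertical_grf(
                min(summary.df_fore, 1.0), limb_share
            ),
        }
        row.update(_classification_row(summary))
        rows.append(row)
    return pd.DataFrame(rows)


def write_stride_csv(data: Dataset, path: str | Path) -> pd.DataFrame:
    """Write the derived stride-parameter CSV and return the table."""
    table = stride_table(data)
    table.to_csv(path, index=False, float_format="%.6f")
    return table
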