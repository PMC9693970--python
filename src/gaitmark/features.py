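"""Per-subject feature extraction.

Kinematic block: for each accepted stride the segmentation module provides
left/right swing and stance and the double-support duration, each in
seconds and as % of stride; here they are collapsed per subject into four
indices — average, median, SD and IQR — plus the gait-speed and
timed-up-and-go covariates copied from metadata (insoles carry no spatial
information, so these are dataset-provided, not computed).

Dynamic block: mean / median / SD / IQR of each foot's total-force channel
over the whole trial, swing samples included.

Conventions (configurable): SD is the sample SD (n-1); quantiles use
linear interpolation, IQR = Q3 - Q1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .core import InsoleRecording, SubjectMeta, Units, ValidationError
from .segmentation import CycleSet, cycle_parameters

# canonical variable labels, kinematic block (report row order)
GAIT_SPEED = "Gait Speed (m/s)"
TUG = "Time Up and Go (s)"

_KIN_PARAMS = [
    ("left SWING", "left_swing_s"),
    ("right SWING", "right_swing_s"),
    ("left SWING %", "left_swing_pct"),
    ("right SWING %", "right_swing_pct"),
    ("left STANCE", "left_stance_s"),
    ("right STANCE", "right_stance_s"),
    ("left STANCE %", "left_stance_pct"),
    ("right STANCE %", "right_stance_pct"),
    ("DOUBLE SUPPORT", "double_support_s"),
    ("DOUBLE SUPPORT %", "double_support_pct"),
]
_INDICES = ["Ave", "Med", "SD", "IQR"]

KINEMATIC_VARIABLES: List[str] = [GAIT_SPEED, TUG] + [
    f"{idx} {label}" for idx in _INDICES for label, _ in _KIN_PARAMS
]
DYNAMIC_VARIABLES: List[str] = [
    f"{idx} Force {side}" for idx in _INDICES for side in ("left", "right")
]
ALL_VARIABLES: List[str] = KINEMATIC_VARIABLES + DYNAMIC_VARIABLES


class NoCyclesError(RuntimeError):
    """Subject has zero accepted cycles and must be excluded."""


@dataclass
class SubjectFeatures:
    """Flat per-subject variable -> value mapping."""

    subject_id: str
    values: Dict[str, float] = field(default_factory=dict)

    def merged_with(self, other: "SubjectFeatures") -> "SubjectFeatures":
        if other.subject_id != self.subject_id:
            raise ValueError("cannot merge features of different subjects")
        merged = dict(self.values)
        merged.update(other.values)
        return SubjectFeatures(self.subject_id, merged)


def _indices(values: np.ndarray, quantile_method: str) -> Dict[str, float]:
    q1, q3 = np.percentile(values, [25, 75], method=quantile_method)
    return {
        "Ave": float(np.mean(values)),
        "Med": float(np.percentile(values, 50, method=quantile_method)),
        "SD": float(np.std(values, ddof=1)) if values.size >= 2 else None,
        "IQR": float(q3 - q1) if values.size >= 2 else None,
    }


def kinematic_features(
    cycleset: CycleSet,
    meta: Optional[SubjectMeta] = None,
    quantile_method: str = "linear",
) -> SubjectFeatures:
    """Ave/Med/SD/IQR over accepted cycles for every kinematic parameter.

    Dispersion indices require >= 2 accepted cycles and are omitted (with a
    warning) otherwise; zero accepted cycles raises :class:`NoCyclesError`.
    """
    if not cycleset.accepted:
        raise NoCyclesError(
            f"subject {cycleset.subject_id!r}: zero accepted cycles"
        )
    per_cycle = [cycle_parameters(c) for c in cycleset.accepted]
    feats = SubjectFeatures(cycleset.subject_id)
    if len(per_cycle) < 2:
        warnings.warn(
            f"subject {cycleset.subject_id!r}: single accepted cycle, "
            "dispersion indices omitted",
            stacklevel=2,
        )
    for label, key in _KIN_PARAMS:
        vals = np.array([p[key] for p in per_cycle])
        for idx, v in _indices(vals, quantile_method).items():
            if v is not None:
                feats.values[f"{idx} {label}"] = v
    if meta is not None:
        if meta.gait_speed is not None:
            feats.values[GAIT_SPEED] = meta.gait_speed
        if meta.tug is not None:
            feats.values[TUG] = meta.tug
    return feats


def normalize_voltage(
    recording: InsoleRecording, max_output: float
) -> InsoleRecording:
    """Express a raw-volt recording as % of the maximal detectable force.

    Every channel is divided by ``max_output`` (the device full-scale
    output) and scaled to percent.  Values above full scale are clipped at
    100% with a saturation warning.
    """
    if max_output <= 0:
        raise ValidationError("max_output must be positive")
    if recording.units != Units.VOLT:
        raise ValidationError("normalize_voltage expects a volt recording")

    n_sat = int(
        (recording.left_sensors > max_output).sum()
        + (recording.right_sensors > max_output).sum()
    )
    if n_sat:
        warnings.warn(
            f"{n_sat} samples above full scale {max_output:g}; clipped at 100%",
            stacklevel=2,
        )

    def conv(x):
        return np.minimum(x / max_output * 100.0, 100.0)

    left = conv(recording.left_sensors)
    right = conv(recording.right_sensors)
    return InsoleRecording(
        subject_id=recording.subject_id,
        time=recording.time.copy(),
        left_sensors=left,
        right_sensors=right,
        left_total=left.sum(axis=1),
        right_total=right.sum(axis=1),
        sampling_rate=recording.sampling_rate,
        units=Units.PERCENT_MAX,
    )


def dynamic_features(
    recording: InsoleRecording, quantile_method: str = "linear"
) -> SubjectFeatures:
    """Whole-trial mean/median/SD/IQR of each foot's total force.

    Requires calibrated (newton) or normalized (percent-of-max) input —
    raw volts must go through :func:`normalize_voltage` first.
    """
    if recording.units == Units.VOLT:
        raise ValidationError(
            "dynamic features need calibrated or normalized data; "
            "apply normalize_voltage first"
        )
    feats = SubjectFeatures(recording.subject_id)
    for side, channel in (("left", recording.left_total), ("right", recording.right_total)):
        for idx, v in _indices(np.asarray(channel), quantile_method).items():
            feats.values[f"{idx} Force {side}"] = v
    return feats
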