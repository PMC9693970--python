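"""Core domain types shared across the package.

An :class:`InsoleRecording` holds the two-foot, 8-sensor vertical
ground-reaction-force time series of one walking trial, together with the
per-foot total-force channels.  A :class:`SubjectMeta` row carries the
clinical / demographic covariates of one subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

N_SENSORS = 8


class Units(str, Enum):
    """Physical units of the force channels."""

    NEWTON = "newton"
    VOLT = "volt"
    PERCENT_MAX = "percent_max"


class ValidationError(ValueError):
    """A recording or metadata table violates a structural invariant."""


@dataclass
class InsoleRecording:
    """Two-foot insole VGRF trial.

    Channels: ``time`` (seconds), ``left_sensors``/``right_sensors`` with
    shape ``(n, 8)`` (heel-to-toe order), and the per-foot totals
    ``left_total``/``right_total``.  Totals are the per-sample sum of the
    corresponding sensor channels unless the source file declared its own
    total columns.
    """

    subject_id: str
    time: np.ndarray
    left_sensors: np.ndarray
    right_sensors: np.ndarray
    left_total: np.ndarray
    right_total: np.ndarray
    sampling_rate: float
    units: Units = Units.NEWTON

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.left_sensors = np.atleast_2d(np.asarray(self.left_sensors, dtype=float))
        self.right_sensors = np.atleast_2d(np.asarray(self.right_sensors, dtype=float))
        self.left_total = np.asarray(self.left_total, dtype=float)
        self.right_total = np.asarray(self.right_total, dtype=float)
        self.units = Units(self.units)

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    def validate(self) -> "InsoleRecording":
        """Check structural invariants, returning ``self`` on success."""
        n = self.n_samples
        if n < 2:
            raise ValidationError("recording needs at least 2 samples")
        for name in ("left_sensors", "right_sensors"):
            arr = getattr(self, name)
            if arr.shape != (n, N_SENSORS):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected ({n}, {N_SENSORS})"
                )
        for name in ("left_total", "right_total"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValidationError(f"{name} has shape {arr.shape}, expected ({n},)")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        med_dt = float(np.median(dt))
        if abs(med_dt - 1.0 / self.sampling_rate) > 0.01 / self.sampling_rate:
            raise ValidationError(
                f"median sampling interval {med_dt:.6g} s inconsistent with "
                f"declared rate {self.sampling_rate:g} Hz"
            )
        if self.units in (Units.NEWTON, Units.PERCENT_MAX):
            for name in ("left_sensors", "right_sensors", "left_total", "right_total"):
                if np.any(getattr(self, name) < 0):
                    raise ValidationError(f"negative forces in {name}")
        return self

    def swapped_feet(self) -> "InsoleRecording":
        """Mirror the recording (left channels become right and vice versa)."""
        return replace(
            self,
            left_sensors=self.right_sensors.copy(),
            right_sensors=self.left_sensors.copy(),
            left_total=self.right_total.copy(),
            right_total=self.left_total.copy(),
        )


@dataclass
class SubjectMeta:
    """Per-subject covariates. Optional clinical fields default to ``None``."""

    subject_id: str
    group: str  # "PD" or "HS"
    cohort: Optional[int] = None
    age: Optional[float] = None
    gender: Optional[str] = None
    gait_speed: Optional[float] = None  # m/s
    tug: Optional[float] = None  # seconds
    hoehn_yahr: Optional[float] = None
    updrs: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in ("PD", "HS"):
            raise ValidationError(f"group must be 'PD' or 'HS', got {self.group!r}")
        if self.gait_speed is not None and not self.gait_speed > 0:
            raise ValidationError("gait_speed must be > 0 when present")
        if self.tug is not None and not self.tug > 0:
            raise ValidationError("tug must be > 0 when present")
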