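"""Synthetic two-foot insole VGRF generator with ground-truth events.

Each stride is the phase sequence DLS -> SLS-R -> DLS -> SLS-L.  Per-cycle
timing is drawn from a :class:`GaitProfile`: stride time (mean + CV), the
per-foot stance fraction, and the per-episode double-support fraction.  For
a symmetric gait these are linked (``ds = stance - 0.5``); independent
draws produce mild left/right asymmetry, which is kept as long as all four
phases stay positive.

During a foot's stance the total force follows a smooth two-peak curve
(piecewise raised-cosine through knots at 0%, 25%, 50%, 75%, 100% of
stance, peaks above body weight and a mid-stance valley below it) and is
distributed over the 8 sensors by a heel-to-toe Gaussian activation
schedule.  Swing force is exactly zero before noise.  Sensor noise is
additive Gaussian truncated at zero.

The waveform takes a configurable non-zero value at the stance edges
(``contact_ramp_fraction`` of body weight, default 8%) standing in for the
sharp loading transient of heel strike; this keeps threshold crossings
within one sample of the true contact event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import N_SENSORS, InsoleRecording, SubjectMeta, Units, ValidationError


@dataclass
class GaitProfile:
    """Programmable gait timing, force scale, variability and covariates.

    ``*_sd`` fields are within-subject (cycle-to-cycle) SDs;
    ``*_between_sd`` fields are between-subject SDs used by
    :func:`simulate_cohort` when drawing per-subject profiles.
    """

    stride_time_mean: float = 1.06  # s
    stride_time_cv: float = 0.025
    stance_fraction_mean: float = 0.583  # per foot, fraction of stride
    stance_fraction_sd: float = 0.013
    double_support_fraction_mean: float = 0.083  # per DLS episode
    double_support_fraction_sd: float = 0.005
    body_weight: float = 700.0  # N
    peak_ratio: float = 1.1  # stance peaks, multiple of body weight
    valley_ratio: float = 0.75  # mid-stance valley, multiple of body weight
    contact_ramp_fraction: float = 0.12  # force at stance edges, x body weight
    sensor_noise_sd: float = 0.0  # N per sensor
    gait_speed_mean: float = 1.26  # m/s
    gait_speed_sd: float = 0.166
    tug_mean: float = 9.3  # s
    tug_sd: float = 1.6
    # between-subject heterogeneity (cohort level)
    stride_time_between_sd: float = 0.07
    stance_fraction_between_sd: float = 0.035
    double_support_between_sd: float = 0.03
    body_weight_between_sd: float = 120.0

    def validate(self) -> "GaitProfile":
        if not 0.0 < self.stance_fraction_mean < 1.0:
            raise ValidationError("stance_fraction_mean must be in (0, 1)")
        if not 2.0 * self.double_support_fraction_mean < self.stance_fraction_mean:
            raise ValidationError(
                "each stance contains two DLS episodes: need "
                "2*double_support_fraction_mean < stance_fraction_mean"
            )
        if self.double_support_fraction_mean <= 0:
            raise ValidationError("double_support_fraction_mean must be > 0")
        sds = (
            self.stride_time_cv,
            self.stance_fraction_sd,
            self.double_support_fraction_sd,
            self.sensor_noise_sd,
            self.gait_speed_sd,
            self.tug_sd,
        )
        if any(s < 0 for s in sds):
            raise ValidationError("SDs and CVs must be >= 0")
        if not self.peak_ratio > self.valley_ratio > 0:
            raise ValidationError("need peak_ratio > valley_ratio > 0")
        return self


def default_hs_profile() -> GaitProfile:
    """Healthy-like defaults (group contrasts follow published magnitudes)."""
    return GaitProfile()


def default_pd_profile() -> GaitProfile:
    """PD-like defaults: slower, higher TUG, larger stride-to-stride
    variability; same force scale as the healthy profile."""
    return GaitProfile(
        stride_time_mean=1.07,
        stride_time_cv=0.040,
        stance_fraction_mean=0.585,
        stance_fraction_sd=0.020,
        double_support_fraction_mean=0.086,
        double_support_fraction_sd=0.009,
        gait_speed_mean=1.019,
        gait_speed_sd=0.227,
        tug_mean=12.056,
        tug_sd=3.962,
        stride_time_between_sd=0.10,
    )


@dataclass
class CycleTruth:
    """Ground-truth timing of one simulated stride (seconds, trial clock)."""

    start: float
    end: float
    dls1: Tuple[float, float]
    sls_r: Tuple[float, float]
    dls2: Tuple[float, float]
    sls_l: Tuple[float, float]
    left_stance: List[Tuple[float, float]]  # within-cycle contact intervals
    right_stance: List[Tuple[float, float]]

    def phase_bounds(self) -> List[float]:
        """The five boundary times: cycle start, three internal phase
        transitions, cycle end."""
        return [self.dls1[0], self.sls_r[0], self.dls2[0], self.sls_l[0], self.sls_l[1]]

    def to_dict(self) -> Dict:
        return asdict(self)


def _two_peak_curve(s: np.ndarray, profile: GaitProfile) -> np.ndarray:
    """Stance-phase total force vs normalized stance progress ``s in [0,1)``.

    Piecewise cosine-eased interpolation through
    (0, edge), (0.25, peak), (0.5, valley), (0.75, peak), (1, edge).
    """
    bw = profile.body_weight
    xs = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    ys = bw * np.array(
        [
            profile.contact_ramp_fraction,
            profile.peak_ratio,
            profile.valley_ratio,
            profile.peak_ratio,
            profile.contact_ramp_fraction,
        ]
    )
    s = np.clip(s, 0.0, 1.0)
    idx = np.clip(np.searchsorted(xs, s, side="right") - 1, 0, len(xs) - 2)
    u = (s - xs[idx]) / (xs[idx + 1] - xs[idx])
    ease = 0.5 * (1.0 - np.cos(np.pi * u))
    return ys[idx] + (ys[idx + 1] - ys[idx]) * ease


_SENSOR_CENTERS = (np.arange(N_SENSORS) + 0.5) / N_SENSORS  # heel -> toe
_SENSOR_WIDTH = 0.25


def _sensor_weights(s: np.ndarray) -> np.ndarray:
    """Heel-to-toe Gaussian activation; rows sum to 1. Shape (len(s), 8)."""
    w = np.exp(-(((s[:, None] - _SENSOR_CENTERS[None, :]) / _SENSOR_WIDTH) ** 2))
    return w / w.sum(axis=1, keepdims=True)


def _draw_cycles(profile: GaitProfile, n_cycles: int, rng: np.random.Generator):
    """Per-cycle (stride_time, dls1, sls_r, dls2, sls_l) durations."""
    t = profile.stride_time_mean * (
        1.0 + profile.stride_time_cv * rng.standard_normal(n_cycles)
    )
    t = np.clip(t, 0.3 * profile.stride_time_mean, None)
    f_st = rng.normal(profile.stance_fraction_mean, profile.stance_fraction_sd, n_cycles)
    f_st = np.clip(f_st, 0.52, 0.95)
    f_ds = rng.normal(
        profile.double_support_fraction_mean,
        profile.double_support_fraction_sd,
        n_cycles,
    )
    # keep phase order valid: DLS episodes and both SLS positive
    f_ds = np.clip(f_ds, 0.01, (f_st - 0.02) / 2.0)
    dls = f_ds * t
    sls_l = (f_st - 2.0 * f_ds) * t
    sls_r = (1.0 - f_st) * t
    return t, dls, sls_r, dls.copy(), sls_l


def simulate_subject(
    profile: GaitProfile,
    duration: float,
    sampling_rate: float = 100.0,
    seed=0,
    subject_id: str = "S00",
    group: str = "HS",
    cohort: int = 1,
) -> Tuple[InsoleRecording, List[CycleTruth], SubjectMeta]:
    """Simulate one walking trial.

    Deterministic for a fixed seed.  One lead-in and one tail cycle are
    rendered beyond the recorded window so edge stances carry complete
    force curves; the ground truth lists only cycles fully inside the
    recording.
    """
    profile.validate()
    if duration < 3.0 * profile.stride_time_mean:
        raise ValidationError("duration must cover at least 3 stride times")
    rng = np.random.default_rng(seed)

    n_cycles = int(np.ceil(duration / (0.3 * profile.stride_time_mean))) + 3
    t, d1, sr, d2, sl = _draw_cycles(profile, n_cycles, rng)
    starts = np.concatenate(([0.0], np.cumsum(t)))

    # recording window starts at the onset of cycle 1 (cycle 0 is lead-in)
    offset = starts[1]
    n_samples = int(round(duration * sampling_rate))
    time = np.arange(n_samples) / sampling_rate
    abs_time = time + offset

    # per-foot stance intervals in absolute trial time
    right_iv = [
        (starts[i], starts[i] + d1[i] + sr[i] + d2[i]) for i in range(n_cycles)
    ]
    left_iv = [(starts[0], starts[0] + d1[0])]  # partial: lead-in DLS1
    for i in range(n_cycles - 1):
        left_iv.append((starts[i] + d1[i] + sr[i], starts[i + 1] + d1[i + 1]))

    left_sensors = np.zeros((n_samples, N_SENSORS))
    right_sensors = np.zeros((n_samples, N_SENSORS))
    for ivs, sensors in ((left_iv, left_sensors), (right_iv, right_sensors)):
        for (u0, u1) in ivs:
            lo = int(np.searchsorted(abs_time, u0, side="left"))
            hi = int(np.searchsorted(abs_time, u1, side="left"))
            if hi <= lo:
                continue
            s = (abs_time[lo:hi] - u0) / (u1 - u0)
            total = _two_peak_curve(s, profile)
            sensors[lo:hi] = total[:, None] * _sensor_weights(s)

    if profile.sensor_noise_sd > 0:
        left_sensors = np.maximum(
            left_sensors + rng.normal(0, profile.sensor_noise_sd, left_sensors.shape), 0.0
        )
        right_sensors = np.maximum(
            right_sensors + rng.normal(0, profile.sensor_noise_sd, right_sensors.shape), 0.0
        )

    recording = InsoleRecording(
        subject_id=subject_id,
        time=time,
        left_sensors=left_sensors,
        right_sensors=right_sensors,
        left_total=left_sensors.sum(axis=1),
        right_total=right_sensors.sum(axis=1),
        sampling_rate=sampling_rate,
        units=Units.NEWTON,
    ).validate()

    truths: List[CycleTruth] = []
    # the closing boundary sample must exist inside the recorded window
    t_end = (n_samples - 1) / sampling_rate
    for i in range(1, n_cycles):
        a = starts[i] - offset
        b = starts[i + 1] - offset
        if a < -1e-12 or b > t_end + 1e-12:
            continue
        b0 = a
        b1 = a + d1[i]
        b2 = b1 + sr[i]
        b3 = b2 + d2[i]
        truths.append(
            CycleTruth(
                start=a,
                end=b,
                dls1=(b0, b1),
                sls_r=(b1, b2),
                dls2=(b2, b3),
                sls_l=(b3, b),
                left_stance=[(b0, b1), (b2, b)],
                right_stance=[(b0, b3)],
            )
        )

    gait_speed = max(0.1, rng.normal(profile.gait_speed_mean, profile.gait_speed_sd))
    tug = max(1.0, rng.normal(profile.tug_mean, profile.tug_sd))
    meta = SubjectMeta(
        subject_id=subject_id,
        group=group,
        cohort=cohort,
        age=float(np.round(rng.uniform(55, 80), 1)),
        gender=("M" if rng.random() < 0.5 else "F"),
        gait_speed=float(gait_speed),
        tug=float(tug),
    )
    return recording, truths, meta


def _subject_profile(base: GaitProfile, rng: np.random.Generator) -> GaitProfile:
    """Draw a subject-level profile around the group-level means."""
    stride = max(0.4, rng.normal(base.stride_time_mean, base.stride_time_between_sd))
    f_st = float(np.clip(
        rng.normal(base.stance_fraction_mean, base.stance_fraction_between_sd),
        0.53, 0.80,
    ))
    f_ds = float(np.clip(
        rng.normal(base.double_support_fraction_mean, base.double_support_between_sd),
        0.02, (f_st - 0.04) / 2.0,
    ))
    bw = max(300.0, rng.normal(base.body_weight, base.body_weight_between_sd))
    return replace(
        base,
        stride_time_mean=stride,
        stance_fraction_mean=f_st,
        double_support_fraction_mean=f_ds,
        body_weight=bw,
    )


def simulate_cohort(
    hs_profile: GaitProfile,
    pd_profile: GaitProfile,
    n_hs: int,
    n_pd: int,
    duration: float,
    sampling_rate: float = 100.0,
    seed=0,
) -> Tuple[List[InsoleRecording], List[List[CycleTruth]], List[SubjectMeta]]:
    """Simulate ``n_hs`` healthy-like then ``n_pd`` PD-like subjects.

    Per-subject generators are spawned from the master seed with the
    subject index as spawn key, so subjects are independent and the cohort
    reproducible.
    """
    if n_hs < 1 or n_pd < 1:
        raise ValidationError("need at least one subject per group")
    recordings, truths, metas = [], [], []
    specs = [("HS", hs_profile)] * n_hs + [("PD", pd_profile)] * n_pd
    for i, (group, base) in enumerate(specs):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        prof = _subject_profile(base.validate(), rng)
        rec, tr, meta = simulate_subject(
            prof,
            duration=duration,
            sampling_rate=sampling_rate,
            seed=ss.spawn(1)[0],
            subject_id=f"{group}{i:03d}",
            group=group,
        )
        recordings.append(rec)
        truths.append(tr)
        metas.append(meta)
    return recordings, truths, metas


VOLT_FULL_SCALE = 3.3  # device output span in volts


def degrade_to_voltage(
    recording: InsoleRecording, max_output: float
) -> Tuple[InsoleRecording, int]:
    """Map a calibrated recording to raw volts.

    ``max_output`` is the full-scale force (N) that maps to
    :data:`VOLT_FULL_SCALE` volts.  Forces above full scale are clipped
    with a warning; the clipped-sample count is returned alongside the
    recording.  Inverse (up to scale) of
    :func:`gaitmark.features.normalize_voltage`.
    """
    import warnings

    if recording.units != Units.NEWTON:
        raise ValidationError("degrade_to_voltage expects a newton recording")
    if max_output <= 0:
        raise ValidationError("max_output must be positive")

    def conv(x):
        return np.minimum(x, max_output) / max_output * VOLT_FULL_SCALE

    n_clipped = int(
        (recording.left_sensors > max_output).sum()
        + (recording.right_sensors > max_output).sum()
    )
    if n_clipped:
        warnings.warn(
            f"{n_clipped} sensor samples exceed full scale {max_output:g} N; clipped",
            stacklevel=2,
        )
    left = conv(recording.left_sensors)
    right = conv(recording.right_sensors)
    out = InsoleRecording(
        subject_id=recording.subject_id,
        time=recording.time.copy(),
        left_sensors=left,
        right_sensors=right,
        left_total=left.sum(axis=1),
        right_total=right.sum(axis=1),
        sampling_rate=recording.sampling_rate,
        units=Units.VOLT,
    )
    return out, n_clipped


def write_ground_truth(truths: Sequence[CycleTruth], path) -> Path:
    """JSON sidecar with the ground-truth cycle events."""
    path = Path(path)
    path.write_text(json.dumps([t.to_dict() for t in truths], indent=1))
    return path


def read_ground_truth(path) -> List[CycleTruth]:
    raw = json.loads(Path(path).read_text())
    out = []
    for d in raw:
        out.append(
            CycleTruth(
                start=d["start"],
                end=d["end"],
                dls1=tuple(d["dls1"]),
                sls_r=tuple(d["sls_r"]),
                dls2=tuple(d["dls2"]),
                sls_l=tuple(d["sls_l"]),
                left_stance=[tuple(p) for p in d["left_stance"]],
                right_stance=[tuple(p) for p in d["right_stance"]],
            )
        )
    return out
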