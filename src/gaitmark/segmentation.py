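"""Gait-cycle segmentation from two-foot total vertical force.

The differential GRF ``delta = right_total - left_total`` is computed and
exposed for QC, but phase labelling itself uses the two per-foot contact
series: delta alone cannot distinguish double support from an airborne gap.
A stride is anchored at the onset of a double-limb-support episode that is
immediately followed by right single support, and runs to the end of the
subsequent left single support — i.e. the phase pattern within one cycle is
``DLS -> SLS-R -> DLS -> SLS-L``.  A mirrored (left-anchored) definition is
available via ``anchor="left"``.

Overlong cycles are discarded with a one-sided rule: a cycle is rejected
when its duration exceeds ``mean + 2*SD`` of all segmented cycle durations,
with the mean and SD computed once over all cycles (no iteration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import InsoleRecording, Units

DEFAULT_CONTACT_THRESHOLD_N = 20.0  # newtons, calibrated data
DEFAULT_CONTACT_FRACTION = 0.03  # fraction of per-subject max, uncalibrated data
DEFAULT_MIN_PHASE_DURATION = 0.05  # seconds


class NoGaitError(RuntimeError):
    """The force signal never crosses the contact threshold."""


class InsufficientGaitError(RuntimeError):
    """Fewer than one complete gait cycle in the recording."""


class Phase(IntEnum):
    DLS = 0  # both feet loaded
    SLS_L = 1  # left foot only
    SLS_R = 2  # right foot only
    AIRBORNE = 3  # neither foot loaded


@dataclass
class DifferentialGRF:
    """Right-minus-left total force, same sample grid as the recording."""

    time: np.ndarray
    delta: np.ndarray


def differential_grf(recording: InsoleRecording) -> DifferentialGRF:
    """delta = right_total - left_total, elementwise."""
    return DifferentialGRF(
        time=recording.time.copy(),
        delta=recording.right_total - recording.left_total,
    )


@dataclass
class ContactSeries:
    """Debounced per-foot boolean contact series."""

    left: np.ndarray
    right: np.ndarray
    contact_threshold: float
    min_phase_duration: float
    sampling_rate: float


def _rle(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode a 1-D array -> (starts, lengths, values)."""
    n = x.shape[0]
    if n == 0:
        return np.array([], int), np.array([], int), np.array([])
    change = np.flatnonzero(x[1:] != x[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [n])))
    return starts, lengths, x[starts]


def _flip_short(x: np.ndarray, state: bool, min_len: int) -> np.ndarray:
    """Iteratively flip runs of ``state`` shorter than ``min_len``
    (shortest first, re-encoding after each flip so neighbours coalesce)."""
    while True:
        starts, lengths, values = _rle(x)
        if len(lengths) <= 1:
            return x
        short = np.flatnonzero((lengths < min_len) & (values == state))
        if short.size == 0:
            return x
        i = short[np.argmin(lengths[short])]
        x[starts[i] : starts[i] + lengths[i]] = not state


def _merge_short_runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Debounce: drop sub-threshold contact chatter, then fill short gaps.

    Spikes (short True runs) are removed before gaps (short False runs) so
    an isolated noise spike near a phase boundary cannot get bridged into
    the adjacent stance run.
    """
    x = mask.astype(bool).copy()
    if min_len <= 1:
        return x
    x = _flip_short(x, True, min_len)
    x = _flip_short(x, False, min_len)
    return x


def resolve_threshold(recording: InsoleRecording, contact_threshold=None) -> float:
    """Default contact threshold: 20 N for newton data, 3% of the
    per-subject maximum total force otherwise (volts / percent-of-max)."""
    if contact_threshold is not None:
        return float(contact_threshold)
    if recording.units == Units.NEWTON:
        return DEFAULT_CONTACT_THRESHOLD_N
    peak = float(max(recording.left_total.max(), recording.right_total.max()))
    return DEFAULT_CONTACT_FRACTION * peak


def detect_contact(
    recording: InsoleRecording,
    contact_threshold: Optional[float] = None,
    min_phase_duration: float = DEFAULT_MIN_PHASE_DURATION,
) -> ContactSeries:
    """Threshold the per-foot totals and debounce short runs.

    Raises :class:`NoGaitError` if either foot never crosses the threshold.
    """
    thr = resolve_threshold(recording, contact_threshold)
    if thr <= 0:
        raise ValueError("contact threshold must be positive")
    min_len = int(round(min_phase_duration * recording.sampling_rate))
    left = recording.left_total > thr
    right = recording.right_total > thr
    if not left.any() or not right.any():
        raise NoGaitError(
            f"no gait detected: a foot never exceeds threshold {thr:g}"
        )
    return ContactSeries(
        left=_merge_short_runs(left, min_len),
        right=_merge_short_runs(right, min_len),
        contact_threshold=thr,
        min_phase_duration=min_phase_duration,
        sampling_rate=recording.sampling_rate,
    )


def label_phases(contact: ContactSeries) -> np.ndarray:
    """Per-sample phase labels from the two contact series."""
    labels = np.full(contact.left.shape[0], Phase.AIRBORNE, dtype=np.int8)
    labels[contact.left & contact.right] = Phase.DLS
    labels[contact.left & ~contact.right] = Phase.SLS_L
    labels[~contact.left & contact.right] = Phase.SLS_R
    return labels


@dataclass
class GaitCycle:
    """One segmented stride: half-open sample interval and its four phases.

    ``phases`` holds ``(phase, start, end)`` triples in temporal order; for
    the right-anchored definition the order is DLS, SLS-R, DLS, SLS-L.
    """

    start: int
    end: int
    phases: List[Tuple[Phase, int, int]]
    sampling_rate: float
    anchor: str = "right"

    @property
    def stride_duration(self) -> float:
        return (self.end - self.start) / self.sampling_rate

    def phase_duration(self, phase: Phase) -> float:
        return sum(
            (e - s) for p, s, e in self.phases if p == phase
        ) / self.sampling_rate


@dataclass
class RejectedCycle:
    start: int
    end: int
    reason: str
    cycle: Optional[GaitCycle] = None


@dataclass
class CycleSet:
    """Accepted and rejected cycles of one subject, with the outlier bound."""

    subject_id: str
    accepted: List[GaitCycle]
    rejected: List[RejectedCycle]
    sl_mean: Optional[float] = None  # mean stride duration, pre-rejection
    sl_sd: Optional[float] = None  # SD of stride duration, pre-rejection

    @property
    def n_segmented(self) -> int:
        return len(self.accepted) + sum(1 for r in self.rejected if r.cycle is not None)


_PATTERNS = {
    "right": [Phase.DLS, Phase.SLS_R, Phase.DLS, Phase.SLS_L],
    "left": [Phase.DLS, Phase.SLS_L, Phase.DLS, Phase.SLS_R],
}


def segment_cycles(
    labels: np.ndarray,
    sampling_rate: float,
    anchor: str = "right",
) -> Tuple[List[GaitCycle], List[RejectedCycle]]:
    """Cut the labelled series into strides.

    Returns accepted cycles plus spans discarded for containing airborne
    samples or an irregular phase pattern.  Leading/trailing fragments are
    silently dropped.  Raises :class:`InsufficientGaitError` when no
    complete cycle exists.
    """
    if anchor not in _PATTERNS:
        raise ValueError(f"anchor must be 'right' or 'left', got {anchor!r}")
    pattern = _PATTERNS[anchor]
    first_sls, last_sls = pattern[1], pattern[3]

    starts, lengths, values = _rle(np.asarray(labels))
    ends = starts + lengths
    nruns = len(starts)
    cycles: List[GaitCycle] = []
    dropped: List[RejectedCycle] = []

    i = 0
    while i < nruns:
        if (
            values[i] == Phase.DLS
            and i + 1 < nruns
            and values[i + 1] == first_sls
        ):
            # close at the next DLS onset preceded by the terminal SLS
            j = i + 1
            while j < nruns and not (
                values[j] == Phase.DLS and values[j - 1] == last_sls
            ):
                j += 1
            if j == nruns:
                break  # trailing fragment
            span = [(Phase(values[k]), int(starts[k]), int(ends[k])) for k in range(i, j)]
            seq = [p for p, _, _ in span]
            if Phase.AIRBORNE in seq:
                dropped.append(
                    RejectedCycle(int(starts[i]), int(starts[j]), "airborne gap")
                )
            elif seq != pattern:
                dropped.append(
                    RejectedCycle(int(starts[i]), int(starts[j]), "irregular phase pattern")
                )
            else:
                cycles.append(
                    GaitCycle(
                        start=int(starts[i]),
                        end=int(starts[j]),
                        phases=span,
                        sampling_rate=sampling_rate,
                        anchor=anchor,
                    )
                )
            i = j
        else:
            i += 1

    if not cycles:
        raise InsufficientGaitError("fewer than one complete gait cycle")
    return cycles, dropped


_LEFT_CONTACT = {Phase.DLS: True, Phase.SLS_L: True, Phase.SLS_R: False}
_RIGHT_CONTACT = {Phase.DLS: True, Phase.SLS_R: True, Phase.SLS_L: False}


def cycle_parameters(cycle: GaitCycle) -> Dict[str, float]:
    """Kinematic parameters of one stride, in seconds and % of stride.

    Stance per foot is the in-cycle time that foot is loaded; swing is its
    complement, so ``stance% + swing% == 100`` exactly.  Step durations run
    from one foot's initial contact to the other's.
    """
    fs = cycle.sampling_rate
    sl = cycle.stride_duration
    left_stance = sum(
        (e - s) for p, s, e in cycle.phases if _LEFT_CONTACT[p]
    ) / fs
    right_stance = sum(
        (e - s) for p, s, e in cycle.phases if _RIGHT_CONTACT[p]
    ) / fs
    dls = cycle.phase_duration(Phase.DLS)
    sls_l = cycle.phase_duration(Phase.SLS_L)
    sls_r = cycle.phase_duration(Phase.SLS_R)

    # initial contact per foot: start of the first phase where the foot is
    # loaded but was not loaded in the (cyclically) previous phase
    def initial_contact(table) -> int:
        nph = len(cycle.phases)
        for k in range(nph):
            p = cycle.phases[k][0]
            prev = cycle.phases[(k - 1) % nph][0]
            if table[p] and not table[prev]:
                return cycle.phases[k][1]
        return cycle.start  # foot loaded throughout (degenerate)

    ic_left = initial_contact(_LEFT_CONTACT)
    ic_right = initial_contact(_RIGHT_CONTACT)
    n = cycle.end - cycle.start
    left_step = ((ic_left - ic_right) % n) / fs  # right IC -> left IC
    right_step = ((ic_right - ic_left) % n) / fs  # left IC -> right IC

    params = {
        "left_stance_s": left_stance,
        "right_stance_s": right_stance,
        "left_swing_s": sl - left_stance,
        "right_swing_s": sl - right_stance,
        "double_support_s": dls,
        "sls_l_s": sls_l,
        "sls_r_s": sls_r,
        "left_step_s": left_step,
        "right_step_s": right_step,
        "stride_s": sl,
    }
    for key in list(params):
        if key != "stride_s":
            params[key[: -len("_s")] + "_pct"] = 100.0 * params[key] / sl
    return params


def reject_outlier_cycles(
    cycles: Sequence[GaitCycle],
    subject_id: str = "",
    enabled: bool = True,
) -> CycleSet:
    """One-sided rejection of overlong strides.

    The bound ``mean + 2*SD`` is computed once over all segmented cycles
    (sample SD, n-1).  With a single cycle (SD undefined) everything passes
    through unmarked.
    """
    cycles = list(cycles)
    durations = np.array([c.stride_duration for c in cycles])
    if not enabled or len(cycles) < 2:
        return CycleSet(subject_id, accepted=cycles, rejected=[])
    sl_mean = float(np.mean(durations))
    sl_sd = float(np.std(durations, ddof=1))
    bound = sl_mean + 2.0 * sl_sd
    accepted, rejected = [], []
    for c, d in zip(cycles, durations):
        if d > bound:
            rejected.append(
                RejectedCycle(c.start, c.end, "outlier duration", cycle=c)
            )
        else:
            accepted.append(c)
    return CycleSet(subject_id, accepted=accepted, rejected=rejected,
                    sl_mean=sl_mean, sl_sd=sl_sd)


def extract_cycles(
    recording: InsoleRecording,
    contact_threshold: Optional[float] = None,
    min_phase_duration: float = DEFAULT_MIN_PHASE_DURATION,
    anchor: str = "right",
    outlier_rejection: bool = True,
) -> CycleSet:
    """Convenience: contact detection -> labels -> cycles -> outlier rule."""
    contact = detect_contact(recording, contact_threshold, min_phase_duration)
    labels = label_phases(contact)
    cycles, dropped = segment_cycles(labels, recording.sampling_rate, anchor=anchor)
    cycleset = reject_outlier_cycles(
        cycles, subject_id=recording.subject_id, enabled=outlier_rejection
    )
    cycleset.rejected = dropped + cycleset.rejected
    return cycleset
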