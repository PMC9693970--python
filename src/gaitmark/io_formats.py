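"""Readers and writers for insole recordings, metadata, and feature tables.

The default on-disk recording layout follows the public force-sensitive
insole gait databases: whitespace/tab-delimited numeric text with one row
per sample and columns ``time, L1..L8, R1..R8 [, Ltotal, Rtotal]`` at a
nominal 100 Hz.  A :class:`Dialect` makes the layout configurable because
different acquisitions ship with or without total columns and with
different units (newtons for calibrated hardware, volts for raw output).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import N_SENSORS, InsoleRecording, SubjectMeta, Units, ValidationError

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed numeric text in a recording file."""


@dataclass
class Dialect:
    """Column layout and units of a recording file.

    ``has_totals=None`` auto-detects from the column count (19 columns with
    totals, 17 without).
    """

    units: Units = Units.NEWTON
    has_totals: Optional[bool] = None
    sampling_rate: Optional[float] = None  # None -> estimated from median dt
    totals_mismatch_tol: float = 0.01  # relative, warn above this


DEFAULT_DIALECT = Dialect()


def _load_numeric(path: PathLike) -> np.ndarray:
    rows: List[List[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric cell at line {lineno}") from exc
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise ParseError(
                    f"{path}: line {lineno} has {len(vals)} columns, expected {ncols}"
                )
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: empty file")
    return np.asarray(rows, dtype=float)


def read_insole_file(
    path: PathLike,
    dialect: Dialect = DEFAULT_DIALECT,
    subject_id: Optional[str] = None,
) -> InsoleRecording:
    """Read one recording from delimited numeric text.

    Missing total columns are recomputed as the per-foot sensor sums.  When
    total columns are present but disagree with the sensor sums by more than
    ``dialect.totals_mismatch_tol`` (relative to the max total), a warning is
    emitted and the file totals are kept (they are what downstream analysis
    of the source datasets used).
    """
    data = _load_numeric(path)
    ncols = data.shape[1]
    has_totals = dialect.has_totals
    if has_totals is None:
        if ncols == 1 + 2 * N_SENSORS + 2:
            has_totals = True
        elif ncols == 1 + 2 * N_SENSORS:
            has_totals = False
        else:
            raise ParseError(
                f"{path}: {ncols} columns; expected {1 + 2 * N_SENSORS} or "
                f"{1 + 2 * N_SENSORS + 2}"
            )
    expected = 1 + 2 * N_SENSORS + (2 if has_totals else 0)
    if ncols != expected:
        raise ParseError(f"{path}: {ncols} columns, dialect expects {expected}")

    time = data[:, 0]
    left = data[:, 1 : 1 + N_SENSORS]
    right = data[:, 1 + N_SENSORS : 1 + 2 * N_SENSORS]
    left_sum = left.sum(axis=1)
    right_sum = right.sum(axis=1)
    if has_totals:
        left_total = data[:, 1 + 2 * N_SENSORS]
        right_total = data[:, 2 + 2 * N_SENSORS]
        scale = max(
            float(np.max(np.abs(left_total))),
            float(np.max(np.abs(right_total))),
            1e-12,
        )
        mismatch = max(
            float(np.max(np.abs(left_total - left_sum))),
            float(np.max(np.abs(right_total - right_sum))),
        )
        if mismatch > dialect.totals_mismatch_tol * scale:
            warnings.warn(
                f"{path}: file totals disagree with sensor sums by up to "
                f"{mismatch:.3g} (keeping file totals)",
                stacklevel=2,
            )
    else:
        left_total = left_sum
        right_total = right_sum

    if np.any(np.diff(time) <= 0):
        raise ValidationError(f"{path}: time column not strictly increasing")
    rate = dialect.sampling_rate
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(time)))
    rec = InsoleRecording(
        subject_id=subject_id or Path(path).stem,
        time=time,
        left_sensors=left,
        right_sensors=right,
        left_total=left_total,
        right_total=right_total,
        sampling_rate=rate,
        units=dialect.units,
    )
    return rec.validate()


def write_insole_file(
    recording: InsoleRecording, path: PathLike, include_totals: bool = True
) -> Path:
    """Write a recording in the default tab-delimited layout."""
    cols = [recording.time, *recording.left_sensors.T, *recording.right_sensors.T]
    if include_totals:
        cols += [recording.left_total, recording.right_total]
    mat = np.column_stack(cols)
    np.savetxt(path, mat, fmt="%.10g", delimiter="\t")
    return Path(path)


_META_OPTIONAL = ("cohort", "age", "gender", "gait_speed", "tug", "hoehn_yahr", "updrs")


def read_metadata(path: PathLike) -> List[SubjectMeta]:
    """Read the per-subject metadata table (CSV with header)."""
    df = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if df["subject_id"].isna().any() or df["group"].isna().any():
        raise ValidationError(f"{path}: empty subject_id or group cell")
    ids = df["subject_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValidationError(f"{path}: duplicated subject_id(s): {dupes}")

    out: List[SubjectMeta] = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _META_OPTIONAL:
            if col in df.columns and pd.notna(row[col]):
                val = row[col]
                if col == "cohort":
                    val = int(val)
                elif col != "gender":
                    val = float(val)
                else:
                    val = str(val)
                kwargs[col] = val
        out.append(SubjectMeta(subject_id=str(row["subject_id"]), group=str(row["group"]), **kwargs))
    return out


def write_metadata(meta: Sequence[SubjectMeta], path: PathLike) -> Path:
    df = pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "group": m.group,
                **{c: getattr(m, c) for c in _META_OPTIONAL},
            }
            for m in meta
        ],
        columns=["subject_id", "group", *_META_OPTIONAL],
    )
    df.to_csv(path, index=False)
    return Path(path)


def write_feature_table(features, path: PathLike) -> Path:
    """Write per-subject features in long format (subject_id, variable, value).

    ``features`` is a sequence of objects with ``subject_id`` and a
    ``values`` mapping (see :class:`gaitmark.features.SubjectFeatures`), or
    an already-long :class:`pandas.DataFrame`.
    """
    if isinstance(features, pd.DataFrame):
        df = features.loc[:, ["subject_id", "variable", "value"]]
    else:
        rows = [
            {"subject_id": f.subject_id, "variable": var, "value": val}
            for f in features
            for var, val in f.values.items()
        ]
        df = pd.DataFrame(rows, columns=["subject_id", "variable", "value"])
    df.to_csv(path, index=False, float_format="%.12g")
    return Path(path)


def read_feature_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"subject_id", "variable", "value"}
    if not expected.issubset(df.columns):
        raise ValidationError(f"{path}: feature table needs columns {sorted(expected)}")
    df["subject_id"] = df["subject_id"].astype(str)
    return df
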