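"""End-to-end orchestration: simulate/ingest -> segment -> features ->
compare -> report, with a serialized config and a structured run log."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import io_formats as iof
from . import segmentation as seg
from . import stats as st
from . import synthetic_gait as syn
from .core import InsoleRecording, SubjectMeta, Units, ValidationError


@dataclass
class PipelineConfig:
    """All tunables of a run; every downstream module reads from here."""

    mode: str = "simulate"  # "simulate" | "files"
    out_dir: str = "gaitmark_out"
    seed: int = 0
    # simulate mode
    n_hs: int = 8
    n_pd: int = 8
    duration: float = 60.0
    sampling_rate: float = 100.0
    hs_profile: Dict = field(default_factory=dict)  # GaitProfile overrides
    pd_profile: Dict = field(default_factory=dict)
    # files mode
    data_dir: Optional[str] = None
    metadata: Optional[str] = None
    units: str = "newton"
    voltage_max_output: Optional[float] = None  # required for volt data
    # segmentation
    contact_threshold: Optional[float] = None
    min_phase_duration: float = seg.DEFAULT_MIN_PHASE_DURATION
    anchor: str = "right"
    outlier_rejection: bool = True
    # features / stats
    quantile_method: str = "linear"
    alpha: float = 0.05
    m_tests: int = 50
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(
    config: PipelineConfig,
) -> Tuple[List[InsoleRecording], List[SubjectMeta]]:
    if config.mode == "simulate":
        hs = dataclasses.replace(syn.default_hs_profile(), **config.hs_profile)
        pd_prof = dataclasses.replace(syn.default_pd_profile(), **config.pd_profile)
        recordings, _, metas = syn.simulate_cohort(
            hs, pd_prof, config.n_hs, config.n_pd,
            duration=config.duration,
            sampling_rate=config.sampling_rate,
            seed=config.seed,
        )
        return recordings, metas
    if config.mode != "files":
        raise ValidationError(f"unknown mode {config.mode!r}")
    if not config.data_dir or not config.metadata:
        raise ValidationError("files mode needs data_dir and metadata")
    metas = iof.read_metadata(config.metadata)
    dialect = iof.Dialect(units=Units(config.units))
    recordings = []
    for m in metas:
        path = Path(config.data_dir) / f"{m.subject_id}.txt"
        if not path.exists():
            raise ValidationError(f"missing recording for subject {m.subject_id}: {path}")
        recordings.append(iof.read_insole_file(path, dialect, subject_id=m.subject_id))
    return recordings, metas


def average_cycle_profile(
    recordings: Sequence[InsoleRecording],
    cyclesets: Sequence[seg.CycleSet],
    groups: Optional[Sequence[str]] = None,
    n_points: int = 101,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Group-mean total force vs % of gait cycle, per foot.

    Each accepted cycle is linearly resampled to a common 0-100% axis,
    averaged within subject, then across subjects, so long trials do not
    dominate the group mean.  Returns
    ``{group: {"pct": grid, "left": mean, "right": mean, "n_subjects": k}}``.
    """
    if groups is None:
        groups = ["all"] * len(recordings)
    grid = np.linspace(0.0, 100.0, n_points)
    per_group: Dict[str, Dict[str, list]] = {}
    for rec, cs, grp in zip(recordings, cyclesets, groups):
        if not cs.accepted:
            continue
        left_curves, right_curves = [], []
        for c in cs.accepted:
            idx = np.linspace(c.start, c.end - 1, n_points)
            base = np.arange(c.start, c.end)
            left_curves.append(np.interp(idx, base, rec.left_total[c.start : c.end]))
            right_curves.append(np.interp(idx, base, rec.right_total[c.start : c.end]))
        bucket = per_group.setdefault(grp, {"left": [], "right": []})
        bucket["left"].append(np.mean(left_curves, axis=0))
        bucket["right"].append(np.mean(right_curves, axis=0))
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for grp, bucket in per_group.items():
        out[grp] = {
            "pct": grid,
            "left": np.mean(bucket["left"], axis=0),
            "right": np.mean(bucket["right"], axis=0),
            "n_subjects": len(bucket["left"]),
        }
    return out


def _cycles_frame(cyclesets: Sequence[seg.CycleSet]) -> pd.DataFrame:
    rows = []
    for cs in cyclesets:
        for c in cs.accepted:
            rows.append(
                {
                    "subject_id": cs.subject_id, "start": c.start, "end": c.end,
                    "status": "accepted", "reason": "",
                    **seg.cycle_parameters(c),
                }
            )
        for r in cs.rejected:
            row = {
                "subject_id": cs.subject_id, "start": r.start, "end": r.end,
                "status": "rejected", "reason": r.reason,
            }
            if r.cycle is not None:
                row.update(seg.cycle_parameters(r.cycle))
            rows.append(row)
    return pd.DataFrame(rows)


def _qc_plots(out_dir, recordings, cyclesets, metas):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = Path(out_dir) / "figures"
    figdir.mkdir(parents=True, exist_ok=True)

    # differential-GRF trace with cycle boundaries, first subject
    rec, cs = recordings[0], cyclesets[0]
    delta = seg.differential_grf(rec)
    fig, ax = plt.subplots(figsize=(10, 3))
    n_show = min(rec.n_samples, int(10 * rec.sampling_rate))
    ax.plot(delta.time[:n_show], delta.delta[:n_show], lw=0.8)
    for c in cs.accepted:
        if c.start < n_show:
            ax.axvline(rec.time[c.start], color="k", lw=0.5, alpha=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("differential GRF")
    ax.set_title(f"subject {rec.subject_id}")
    fig.tight_layout()
    fig.savefig(figdir / "differential_grf.png", dpi=120)
    plt.close(fig)

    # average-cycle force profiles per group
    groups = [m.group for m in metas]
    profiles = average_cycle_profile(recordings, cyclesets, groups)
    fig, axes = plt.subplots(1, len(profiles), figsize=(5 * len(profiles), 3.2),
                             squeeze=False)
    for ax, (grp, prof) in zip(axes[0], sorted(profiles.items())):
        ax.plot(prof["pct"], prof["right"], color="tab:red", label="R tot")
        ax.plot(prof["pct"], prof["left"], color="tab:green", label="L tot")
        ax.set_title(f"{grp} (n={prof['n_subjects']})")
        ax.set_xlabel("% gait cycle")
        ax.set_ylabel("total force")
        ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "average_cycle.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Run the full analysis; returns paths of the emitted artifacts.

    Deterministic for a fixed config (CSV outputs are byte-stable across
    reruns; only the figures and log timestamps may differ at pixel level).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings, metas = _load_inputs(config)

    if config.units == "volt":
        if config.voltage_max_output is None:
            raise ValidationError("volt data needs voltage_max_output")
        recordings = [
            feat.normalize_voltage(r, config.voltage_max_output) for r in recordings
        ]
    unit_set = {r.units for r in recordings}
    if len(unit_set) > 1:
        raise ValidationError(f"mixed units across cohort: {sorted(u.value for u in unit_set)}")

    cyclesets: List[seg.CycleSet] = []
    subject_features: List[feat.SubjectFeatures] = []
    log: Dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "subjects": {},
    }
    kept_idx = []
    for i, (rec, meta) in enumerate(zip(recordings, metas)):
        entry: Dict = {}
        try:
            cs = seg.extract_cycles(
                rec,
                contact_threshold=config.contact_threshold,
                min_phase_duration=config.min_phase_duration,
                anchor=config.anchor,
                outlier_rejection=config.outlier_rejection,
            )
            kin = feat.kinematic_features(cs, meta, config.quantile_method)
            dyn = feat.dynamic_features(rec, config.quantile_method)
            subject_features.append(kin.merged_with(dyn))
            cyclesets.append(cs)
            kept_idx.append(i)
            entry["n_accepted"] = len(cs.accepted)
            entry["n_rejected"] = len(cs.rejected)
            entry["rejections"] = sorted({r.reason for r in cs.rejected})
        except (seg.NoGaitError, seg.InsufficientGaitError, feat.NoCyclesError) as exc:
            entry["excluded"] = str(exc)
            warnings.warn(f"subject {rec.subject_id} excluded: {exc}", stacklevel=2)
        log["subjects"][rec.subject_id] = entry

    if not subject_features:
        raise ValidationError("no subject produced features")

    paths: Dict[str, Path] = {}
    paths["cycles"] = out_dir / "cycles.csv"
    _cycles_frame(cyclesets).to_csv(paths["cycles"], index=False, float_format="%.10g")
    paths["features"] = iof.write_feature_table(subject_features, out_dir / "features.csv")
    iof.write_metadata(metas, out_dir / "metadata.csv")
    paths["metadata"] = out_dir / "metadata.csv"

    features_df = iof.read_feature_table(paths["features"])
    report = st.run_comparison_suite(
        features_df, metas, alpha=config.alpha, m=config.m_tests
    )
    for name, df in (
        ("ttest_kinematic", report.kinematic),
        ("ttest_dynamic", report.dynamic),
        ("roc", report.roc),
    ):
        paths[name] = out_dir / f"{name}.csv"
        df.to_csv(paths[name], index=False, float_format="%.10g")

    if config.make_plots and cyclesets:
        _qc_plots(out_dir, [recordings[i] for i in kept_idx],
                  cyclesets, [metas[i] for i in kept_idx])

    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    paths["run_log"] = out_dir / "run_log.json"
    paths["run_log"].write_text(json.dumps(log, indent=1, sort_keys=True))
    return paths
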