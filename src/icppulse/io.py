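"""CSV readers/writers, pipeline configuration, run log, and the
end-to-end pipeline.

Dialects are fixed (comma separator, dot decimal, one header line) so
reruns are byte-identical:

* signal:      ``time_s,icp_mmHg``
* annotations: ``onset_time_s,class_label,amplitude_mmHg``
* pulses:      ``onset_time_s,duration_s,label,amp_mmHg,p1,p2,p3``
* windows:     ``window_start_s,psi,p1,p2,p3,p4,n_valid,n_artifact``
* summaries:   ``patient_id,mean_icp,amp_icp,mean_psi,hours_analyzed``
* cohort CT:   ``patient_id,midline_shift_mm,lesion_volume_cm3,marshall,rotterdam``
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierConfig, classify_recording
from .ct import validate_cohort
from .metrics import compute_psi_windows, summarize_patient
from .stats import AssociationReport, run_association_study
from .types import (
    ClassifiedPulse,
    CTAssessment,
    ICPRecording,
    MIN_FS_HZ,
    PatientSummary,
    PulseClass,
    WindowMetrics,
)

__all__ = [
    "read_signal",
    "write_signal",
    "write_annotations",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_pulses_csv",
    "read_pulses_csv",
    "write_windows_csv",
    "write_summaries_csv",
    "PipelineConfig",
    "RunLog",
    "run_pipeline",
]

_FLOAT_FMT = "%.6f"


def write_signal(path: str | Path, recording: ICPRecording) -> None:
    """Two-column signal CSV with a one-line header."""
    t = recording.time_s
    arr = np.column_stack([t, recording.samples])
    np.savetxt(path, arr, fmt=_FLOAT_FMT, delimiter=",", header="time_s,icp_mmHg", comments="")


def read_signal(path: str | Path, patient_id: str | None = None) -> ICPRecording:
    """Read the signal dialect; verifies uniform sampling (inter-sample
    interval deviating < 1% from its median) and the 50 Hz floor.

    Also accepts a single-column variant whose first line is
    ``# fs=<Hz>`` followed by an ``icp_mmHg`` header.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        try:
            fs = float(first.lstrip("#").split("=")[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"unparseable fs header in {path}: {first!r}") from exc
        df = pd.read_csv(path, skiprows=1)
        samples = df.iloc[:, 0].to_numpy(dtype=float)
    else:
        df = pd.read_csv(path)
        if "time_s" not in df.columns or "icp_mmHg" not in df.columns:
            raise ValueError(f"{path}: expected columns time_s,icp_mmHg")
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0:
            raise ValueError(f"{path}: empty signal")
        med = float(np.median(dt))
        if med <= 0 or np.max(np.abs(dt - med)) > 0.01 * med:
            raise ValueError(f"{path}: non-uniform sampling")
        fs = 1.0 / med
        samples = df["icp_mmHg"].to_numpy(dtype=float)
    if fs < MIN_FS_HZ:
        raise ValueError(
            f"{path}: sampling rate {fs:g} Hz below the {MIN_FS_HZ:.0f} Hz minimum"
        )
    return ICPRecording(samples, round(fs, 6), patient_id=patient_id or path.stem)


def write_annotations(path: str | Path, truth) -> None:
    """Ground-truth annotation CSV (onset_time_s, class_label, amplitude_mmHg)."""
    with open(path, "w") as fh:
        fh.write("onset_time_s,class_label,amplitude_mmHg\n")
        for t, c, a in zip(truth.onset_times_s, truth.pulse_classes, truth.amplitudes_mmHg):
            fh.write(f"{t:.6f},{int(c)},{a:.6f}\n")


def write_cohort_csv(path: str | Path, cts: list[CTAssessment]) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id,midline_shift_mm,lesion_volume_cm3,marshall,rotterdam\n")
        for c in cts:
            fh.write(
                f"{c.patient_id},{c.midline_shift_mm:.6f},{c.lesion_volume_cm3:.6f},"
                f"{c.marshall},{c.rotterdam}\n"
            )


def read_cohort_csv(path: str | Path) -> list[dict]:
    """Raw cohort rows as dicts; pass through :func:`icppulse.ct.validate_cohort`."""
    df = pd.read_csv(path)
    return df.to_dict("records")


def write_pulses_csv(path: str | Path, pulses: list[ClassifiedPulse]) -> None:
    with open(path, "w") as fh:
        fh.write("onset_time_s,duration_s,label,amp_mmHg,p1,p2,p3\n")
        for p in pulses:
            h = list(p.subpeaks.heights) + [float("nan")] * (3 - p.subpeaks.n_visible)
            fh.write(
                f"{p.onset_time_s:.6f},{p.segment.duration_s:.6f},{int(p.label)},"
                f"{p.amp_mmHg:.6f},{h[0]:.6f},{h[1]:.6f},{h[2]:.6f}\n"
            )


def read_pulses_csv(path: str | Path, fs: float = 100.0) -> list[ClassifiedPulse]:
    """Rehydrate classified pulses from the pulses dialect (for the PSI
    stage, which needs only onset time, duration and label)."""
    from .types import PulseSegment, SubPeakSet

    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        i0 = int(round(row["onset_time_s"] * fs))
        i1 = i0 + max(1, int(round(row["duration_s"] * fs)))
        amp = float(row["amp_mmHg"])
        seg = PulseSegment(i0, i1, np.array([0.0, amp]), fs)
        out.append(ClassifiedPulse(seg, SubPeakSet([]), PulseClass(int(row["label"])), amp))
    return out


def write_windows_csv(path: str | Path, windows: list[WindowMetrics]) -> None:
    with open(path, "w") as fh:
        fh.write("window_start_s,psi,p1,p2,p3,p4,n_valid,n_artifact\n")
        for w in windows:
            p = w.class_fractions
            fh.write(
                f"{w.window_start_s:.6f},{w.psi:.6f},{p[0]:.6f},{p[1]:.6f},"
                f"{p[2]:.6f},{p[3]:.6f},{w.n_valid},{w.n_artifact}\n"
            )


def write_summaries_csv(path: str | Path, summaries: list[PatientSummary]) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id,mean_icp,amp_icp,mean_psi,hours_analyzed\n")
        for s in summaries:
            fh.write(
                f"{s.patient_id},{s.mean_icp_mmHg:.6f},{s.amp_icp_mmHg:.6f},"
                f"{s.mean_psi:.6f},{s.hours_analyzed:.6f}\n"
            )


def read_summaries_csv(path: str | Path) -> list[PatientSummary]:
    df = pd.read_csv(path)
    return [
        PatientSummary(
            str(r["patient_id"]),
            float(r["mean_icp"]),
            float(r["amp_icp"]),
            float(r["mean_psi"]),
            float(r.get("hours_analyzed", 24.0)),
        )
        for _, r in df.iterrows()
    ]


@dataclass
class PipelineConfig:
    """Flat, serializable configuration of the end-to-end pipeline."""

    window_len_s: float = 300.0
    shift_s: float = 10.0
    horizon_h: float = 24.0
    min_valid_fraction: float = 0.6
    psi_aggregate: str = "mean"
    tie_tol_frac: float = 0.02
    rel_prominence: float = 0.05
    amp_gate_lo_mmHg: float = 0.5
    amp_gate_hi_mmHg: float = 50.0
    class4_min_width_frac: float = 0.40
    ci_method: str = "delong"
    bootstrap_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_len_s <= 0 or self.shift_s <= 0 or self.horizon_h <= 0:
            raise ValueError("durations must be positive")
        if self.shift_s > self.window_len_s:
            raise ValueError("shift_s must not exceed window_len_s")

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            tie_tol_frac=self.tie_tol_frac,
            rel_prominence=self.rel_prominence,
            amp_gate_mmHg=(self.amp_gate_lo_mmHg, self.amp_gate_hi_mmHg),
            class4_min_width_frac=self.class4_min_width_frac,
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class RunLog:
    """Timestamped per-stage record of counts and reasoned exclusions."""

    config_hash: str = ""
    seed: int | None = None
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, exclusions: list[dict] | None = None) -> None:
        for e in exclusions or []:
            if not e.get("reason"):
                raise ValueError("every exclusion needs a reason")
        self.stages.append(
            {
                "stage": stage,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "n_in": n_in,
                "n_out": n_out,
                "exclusions": exclusions or [],
            }
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"config_hash": self.config_hash, "seed": self.seed, "stages": self.stages},
                indent=2,
            )
        )


def run_pipeline(
    signal_paths: list[str | Path],
    ct_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "icppulse_out",
    seed: int | None = None,
) -> AssociationReport:
    """detect -> classify -> PSI -> summarize -> cohort stats, with a run log.

    One signal file per patient (patient id = file stem). Patients whose
    signal fails any stage are excluded with a logged reason; every
    patient appears exactly once in either the summary table or the
    exclusion log.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(config_hash=config.config_hash(), seed=seed)
    ccfg = config.classifier_config()

    summaries: list[PatientSummary] = []
    excl: list[dict] = []
    for path in signal_paths:
        pid = Path(path).stem
        try:
            rec = read_signal(path, patient_id=pid)
            pulses = classify_recording(rec, ccfg)
            windows = compute_psi_windows(
                pulses, config.window_len_s, config.shift_s,
                min_valid_fraction=config.min_valid_fraction,
            )
            write_pulses_csv(out / f"{pid}_pulses.csv", pulses)
            write_windows_csv(out / f"{pid}_windows.csv", windows)
            summaries.append(
                summarize_patient(
                    rec, pulses, config.horizon_h, config.window_len_s, config.shift_s,
                    config.psi_aggregate, config.min_valid_fraction,
                )
            )
        except ValueError as exc:
            excl.append({"patient_id": pid, "reason": str(exc)})
    log.record("signal_analysis", len(signal_paths), len(summaries), excl)
    if len(summaries) < 2:
        log.write(out / "runlog.json")
        raise ValueError("fewer than 2 patients survived signal analysis")

    rows = read_cohort_csv(ct_path)
    cts, ct_report = validate_cohort(rows)
    log.record(
        "ct_validation",
        ct_report.n_input,
        ct_report.n_retained,
        [{"patient_id": p, "reason": r} for p, r in ct_report.exclusions],
    )

    ids = {s.patient_id for s in summaries} & {c.patient_id for c in cts}
    dropped = [
        {"patient_id": s.patient_id, "reason": "no matching CT row"}
        for s in summaries
        if s.patient_id not in ids
    ] + [
        {"patient_id": c.patient_id, "reason": "no analyzable signal"}
        for c in cts
        if c.patient_id not in ids
    ]
    summaries = [s for s in summaries if s.patient_id in ids]
    cts = [c for c in cts if c.patient_id in ids]
    log.record("join", len(ids) + len(dropped), len(ids), dropped)

    report = run_association_study(
        summaries, cts, ci_method=config.ci_method, seed=config.bootstrap_seed
    )
    write_summaries_csv(out / "summaries.csv", summaries)
    report.comparison_table().to_csv(out / "group_comparisons.csv", index=False)
    report.correlation_table().to_csv(out / "correlations.csv", index=False)
    report.roc_table().to_csv(out / "roc.csv", index=False)
    with open(out / "stats_summary.json", "w") as fh:
        json.dump(
            {
                "n_patients": report.n_patients,
                "auc": {f"{m}|{f}": r.auc for (m, f), r in report.rocs.items()},
                "auc_paired_delong_extension": {
                    f"{a}-vs-{b}|{f}": {"delta": d, "z": z, "p": p}
                    for ((a, b), f), (d, z, p) in report.auc_comparisons.items()
                },
            },
            fh,
            indent=2,
        )
    log.write(out / "runlog.json")
    return report
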