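"""Pulse Shape Index in moving windows and per-patient summary metrics.

PSI for a window is the weighted sum of class numbers i = 1..4 with
weights p_i, the fraction of valid (non-artifact) pulses in the window
assigned to class i: ``psi = 1*p1 + 2*p2 + 3*p3 + 4*p4``. It equals the
mean class number in the window, runs on a continuous scale from 1
(only normal class-1 waveforms) to 4 (only class-4 waveforms), and is
computed in 5-min windows shifted every 10 s. Per-patient metrics (mean
ICP, AmpICP, mean PSI) are taken over the first 24 h of recording.
"""

from __future__ import annotations

import math

import numpy as np

from .types import ClassifiedPulse, ICPRecording, PatientSummary, WindowMetrics

__all__ = ["compute_psi_windows", "compute_amp_icp", "summarize_patient", "psi_from_fractions"]

DEFAULT_WINDOW_S = 300.0
DEFAULT_SHIFT_S = 10.0
MIN_VALID_FRACTION = 0.6  #: validity floor, fraction of expected beat count


def psi_from_fractions(fractions) -> float:
    """Weighted sum of class numbers: ``sum(i * p_i for i in 1..4)``."""
    p = np.asarray(fractions, dtype=float)
    if p.size != 4 or np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must be a length-4 probability vector")
    return float(np.dot(np.arange(1, 5), p))


def _min_valid_count(
    pulses: list[ClassifiedPulse], window_len_s: float, fraction: float = MIN_VALID_FRACTION
) -> int:
    """Validity floor: a fraction (default 60%) of the beat count
    expected at the cohort's typical beat duration (median over pulses)."""
    if not pulses:
        return 1
    med_dur = float(np.median([p.segment.duration_s for p in pulses]))
    med_dur = max(med_dur, 1e-6)
    return max(1, int(math.ceil(fraction * window_len_s / med_dur)))


def compute_psi_windows(
    pulses: list[ClassifiedPulse],
    window_len_s: float = DEFAULT_WINDOW_S,
    shift_s: float = DEFAULT_SHIFT_S,
    min_valid_count: int | None = None,
    min_valid_fraction: float = MIN_VALID_FRACTION,
) -> list[WindowMetrics]:
    """PSI and class fractions in left-aligned half-open moving windows.

    Windows start at the first pulse onset and step by ``shift_s``;
    artifacts are excluded from the fractions but counted. Windows with
    fewer valid pulses than the floor get ``psi = nan`` and are excluded
    from any downstream aggregation.
    """
    if not pulses:
        return []
    times = np.array([p.onset_time_s for p in pulses])
    if np.any(np.diff(times) < 0):
        raise ValueError("pulses must be time-ordered")
    labels = np.array([int(p.label) for p in pulses])
    if min_valid_count is None:
        min_valid_count = _min_valid_count(pulses, window_len_s, min_valid_fraction)

    t0, t_end = float(times[0]), float(times[-1])
    span = t_end - t0
    n_windows = max(1, int(math.floor((span - window_len_s) / shift_s)) + 1) if span >= window_len_s else 1
    starts = t0 + shift_s * np.arange(n_windows)

    # cumulative per-class counts -> O(1) per window
    onehot = labels[:, None] == np.arange(5)[None, :]
    cum = np.vstack([np.zeros(5, dtype=int), np.cumsum(onehot, axis=0)])
    lo = np.searchsorted(times, starts, side="left")
    hi = np.searchsorted(times, starts + window_len_s, side="left")
    counts = cum[hi] - cum[lo]

    out: list[WindowMetrics] = []
    for k in range(n_windows):
        n_art = int(counts[k, 0])
        valid = counts[k, 1:]
        n_valid = int(valid.sum())
        fr = tuple(valid / n_valid) if n_valid > 0 else (0.0, 0.0, 0.0, 0.0)
        psi = psi_from_fractions(fr) if n_valid >= min_valid_count else float("nan")
        out.append(WindowMetrics(float(starts[k]), window_len_s, fr, psi, n_valid, n_art))
    return out


def compute_amp_icp(pulses: list[ClassifiedPulse]) -> float:
    """Mean peak-to-peak amplitude (mm Hg) over valid pulses."""
    amps = [p.amp_mmHg for p in pulses if p.is_valid]
    if not amps:
        raise ValueError("no valid pulses to average")
    return float(np.mean(amps))


def summarize_patient(
    recording: ICPRecording,
    pulses: list[ClassifiedPulse],
    horizon_h: float = 24.0,
    window_len_s: float = DEFAULT_WINDOW_S,
    shift_s: float = DEFAULT_SHIFT_S,
    psi_aggregate: str = "mean",
    min_valid_fraction: float = MIN_VALID_FRACTION,
) -> PatientSummary:
    """First-``horizon_h`` summary: mean ICP, AmpICP and mean PSI.

    Mean ICP is the arithmetic mean of raw samples outside
    artifact-flagged segments; mean PSI aggregates the defined window
    PSI values (arithmetic mean by default, median as option).
    """
    horizon_s = horizon_h * 3600.0
    if recording.duration_s < window_len_s:
        raise ValueError("recording shorter than one analysis window")
    n_h = min(recording.n_samples, int(round(horizon_s * recording.fs)))
    pulses_h = [p for p in pulses if p.onset_time_s < horizon_s]

    keep = np.ones(n_h, dtype=bool)
    for p in pulses_h:
        if not p.is_valid:
            keep[p.segment.onset_index : min(p.segment.end_index, n_h)] = False
    samples = recording.samples[:n_h]
    mean_icp = float(samples[keep].mean()) if keep.any() else float(samples.mean())

    amp_icp = compute_amp_icp(pulses_h)
    windows = compute_psi_windows(
        pulses_h, window_len_s, shift_s, min_valid_fraction=min_valid_fraction
    )
    psis = np.array([w.psi for w in windows])
    psis = psis[np.isfinite(psis)]
    if psis.size == 0:
        raise ValueError("no window reached the validity floor")
    agg = np.median if psi_aggregate == "median" else np.mean
    return PatientSummary(
        patient_id=recording.patient_id,
        mean_icp_mmHg=mean_icp,
        amp_icp_mmHg=amp_icp,
        mean_psi=float(agg(psis)),
        hours_analyzed=min(horizon_h, recording.duration_s / 3600.0),
    )
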