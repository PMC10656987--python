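"""Rule-based morphology classification of single ICP pulses.

Each cardiac-cycle segment is reduced to at most three sub-peaks
(P1, P2, P3 in temporal order: percussion, tidal, dicrotic) and labelled
by a deterministic cascade that encodes the published class semantics:

1. normal — dominant P1;
2. potentially pathological — P2 prominent, but P1 still higher than P3;
3. likely pathological — both P2 and P3 at or above P1;
4. pathological — rounded or triangular pulse with one visible maximum;

plus an artifact class for distorted waveforms (duration-gate
violations, non-physiological amplitudes, flat or spike-dominated
shapes). The cascade is exhaustive and exclusive: every finite segment
receives exactly one label. All shape rules compare heights relative to
the pulse amplitude, so labels are invariant under affine transforms of
the pressure scale; only the absolute-amplitude artifact gate uses
physical units by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig

from .detect import detect_onsets, segment_pulses
from .types import (
    ClassifiedPulse,
    ICPRecording,
    PulseClass,
    PulseSegment,
    SubPeak,
    SubPeakSet,
)

__all__ = ["ClassifierConfig", "find_subpeaks", "classify_pulse", "classify_recording"]


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunables of the rule cascade (defaults documented in the docs).

    ``tie_tol_frac`` — relative tolerance (fraction of pulse amplitude)
    at rule boundaries; ties resolve toward the lower (less pathological)
    class. ``amp_gate_mmHg`` — physical peak-to-peak amplitude range of a
    plausible pulse; outside it the segment is an artifact.
    """

    smooth_window_frac: float = 0.11
    smooth_polyorder: int = 3
    rel_prominence: float = 0.05
    shoulder_curvature_frac: float = 0.12
    tie_tol_frac: float = 0.02
    amp_gate_mmHg: tuple[float, float] = (0.5, 50.0)
    class4_min_width_frac: float = 0.40
    flat_fraction_max: float = 0.30
    spike_width_frac: float = 0.03


DEFAULT_CONFIG = ClassifierConfig()


def _smooth(x: np.ndarray, cfg: ClassifierConfig) -> np.ndarray:
    n = x.size
    win = max(cfg.smooth_polyorder + 2, int(round(cfg.smooth_window_frac * n)))
    win = min(win | 1, n if n % 2 else n - 1)
    if win <= cfg.smooth_polyorder:
        return x.astype(float)
    return sig.savgol_filter(x, win, cfg.smooth_polyorder)


def find_subpeaks(
    segment: PulseSegment, config: ClassifierConfig = DEFAULT_CONFIG
) -> SubPeakSet:
    """Reduce a segment to <= 3 sub-peaks assigned P1/P2/P3 by latency.

    Local maxima of the smoothed waveform with prominence above a
    fraction of the pulse amplitude are kept; shoulder candidates (a
    sub-peak visible only as an inflection) are recovered from local
    maxima of negative second-derivative (curvature) away from existing
    peaks. If more than three candidates survive, the three most
    prominent are kept, then reordered temporally.
    """
    x = np.asarray(segment.samples, dtype=float)
    n = x.size
    if n < 5:
        return SubPeakSet([])
    y = _smooth(x, config)
    amp = float(y.max() - y.min())
    if amp <= 0:
        return SubPeakSet([])

    prom_thr = config.rel_prominence * amp
    idx, props = sig.find_peaks(y, prominence=prom_thr)
    cands = [(int(i), float(p)) for i, p in zip(idx, props["prominences"])]

    # shoulder recovery: a sub-peak visible only as an inflection shows
    # as a curvature (negative-d2) maximum away from the found maxima.
    # A wide second-derivative Savitzky-Golay on the smoothed waveform
    # keeps noise curvature below that of a genuine shoulder; the
    # threshold is relative to the curvature of an amplitude-sized
    # feature 10% of the beat wide. A maximum's own curvature ridge can
    # drift off-apex under noise, so each found maximum shields its
    # half-prominence width; shoulders must also carry real height.
    if n >= 15:
        win2 = max(7, int(round(1.5 * config.smooth_window_frac * n)) | 1)
        win2 = min(win2, n if n % 2 else n - 1)
        d2 = sig.savgol_filter(y, win2, config.smooth_polyorder, deriv=2)
        curv_scale = amp / (0.1 * n) ** 2
        sh_idx, sh_props = sig.find_peaks(
            -d2, prominence=config.shoulder_curvature_frac * curv_scale
        )
        if idx.size:
            half_widths = sig.peak_widths(y, idx, rel_height=0.5)[0] / 2.0
        else:
            half_widths = np.array([])
        min_guard = max(2.0, 0.05 * n)
        y_min = float(y.min())
        for i, p in zip(sh_idx, sh_props["prominences"]):
            clear = all(
                abs(i - j) > max(min_guard, w) for j, w in zip(idx, half_widths)
            )
            if d2[i] < 0 and clear and (y[i] - y_min) >= 0.2 * amp:
                cands.append((int(i), float(p * (0.05 * n) ** 2)))

    # keep interior candidates only, cap at three by prominence
    lo, hi = int(0.02 * n), int(0.97 * n)
    cands = [(i, p) for i, p in cands if lo <= i <= hi]
    cands = sorted(sorted(cands, key=lambda c: -c[1])[:3])

    base = float(y.min())
    peaks = [
        SubPeak(latency_fraction=i / n, height_mmHg=float(y[i] - base), prominence_mmHg=p)
        for i, p in cands
    ]
    return SubPeakSet(peaks)


def _flat_fraction(x: np.ndarray, amp: float) -> float:
    if x.size < 2 or amp <= 0:
        return 1.0
    return float(np.mean(np.abs(np.diff(x)) <= 1e-9 * amp))


def _dominant_width_frac(segment: PulseSegment, cfg: ClassifierConfig) -> float:
    """Width at half prominence of the tallest smoothed peak, as a
    fraction of the beat duration; 0 when no interior peak exists."""
    y = _smooth(np.asarray(segment.samples, dtype=float), cfg)
    idx, props = sig.find_peaks(y, prominence=cfg.rel_prominence * (y.max() - y.min()))
    if idx.size == 0:
        return 0.0
    top = int(np.argmax(props["prominences"]))
    widths = sig.peak_widths(y, idx[top : top + 1], rel_height=0.5)[0]
    return float(widths[0] / y.size)


def classify_pulse(
    segment: PulseSegment, config: ClassifierConfig = DEFAULT_CONFIG
) -> ClassifiedPulse:
    """Label one segment via the artifact screen and the shape cascade."""
    x = np.asarray(segment.samples, dtype=float)
    amp = segment.amp_mmHg
    lo_amp, hi_amp = config.amp_gate_mmHg

    def artifact(subpeaks: SubPeakSet | None = None) -> ClassifiedPulse:
        return ClassifiedPulse(segment, subpeaks or SubPeakSet([]), PulseClass.ARTIFACT, amp)

    # (a) artifact screens: duration, physical amplitude, flat/spike shape
    if not segment.in_duration_gate or x.size < 5:
        return artifact()
    if not np.all(np.isfinite(x)) or amp < lo_amp or amp > hi_amp:
        return artifact()
    if _flat_fraction(x, amp) > config.flat_fraction_max:
        return artifact()

    subpeaks = find_subpeaks(segment, config)
    width_frac = _dominant_width_frac(segment, config)
    if subpeaks.n_visible == 0:
        return artifact(subpeaks)
    if subpeaks.n_visible == 1 and width_frac < config.spike_width_frac:
        return artifact(subpeaks)  # spike-dominated

    # (b) single rounded/triangular maximum
    if subpeaks.n_visible == 1:
        if width_frac >= config.class4_min_width_frac:
            return ClassifiedPulse(segment, subpeaks, PulseClass.C4, amp)
        label = PulseClass.C1  # lone narrow maximum: P1 trivially highest
        return ClassifiedPulse(segment, subpeaks, label, amp)

    h = list(subpeaks.heights) + [-np.inf] * (3 - subpeaks.n_visible)
    h1, h2, h3 = h[:3]
    tol = config.tie_tol_frac * amp
    # (c) dominant P1 (ties resolve toward the lower class)
    if h1 >= max(h2, h3) - tol:
        label = PulseClass.C1
    # (e) both P2 and P3 at or above P1
    elif h3 > h1 + tol:
        label = PulseClass.C3
    # (d) prominent P2 with P1 still above P3
    else:
        label = PulseClass.C2
    return ClassifiedPulse(segment, subpeaks, label, amp)


def classify_recording(
    recording: ICPRecording, config: ClassifierConfig = DEFAULT_CONFIG
) -> list[ClassifiedPulse]:
    """Detect onsets, segment, and classify every complete beat in order."""
    onsets = detect_onsets(recording)
    segments = segment_pulses(recording, onsets)
    return [classify_pulse(s, config) for s in segments]
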