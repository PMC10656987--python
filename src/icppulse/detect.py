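"""Cardiac-cycle segmentation of a continuous ICP recording.

The beat onset is defined as the diastolic trough preceding the systolic
upstroke. Detection is trough-anchored: the dominant cardiac period is
estimated spectrally (0.67-3.0 Hz band) in 30-s blocks to track rate
drift, and local minima of a detrended, median-filtered copy of the
signal are located with a minimum spacing derived from the block's
period. Raw samples are preserved for classification.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sig
from scipy.ndimage import uniform_filter1d

from .types import ICPRecording, MIN_ANALYSIS_S, PulseSegment

__all__ = ["estimate_heart_period", "detect_onsets", "segment_pulses"]

CARDIAC_BAND_HZ = (0.67, 3.0)  # 40-180 bpm
BLOCK_S = 30.0


class UnanalyzableWindowError(ValueError):
    """No cardiac component found in the analysis band."""


def estimate_heart_period(recording: ICPRecording, window_s: float | None = None) -> float:
    """Dominant cardiac period (s) from the strongest spectral peak in
    the 0.67-3.0 Hz band of the (first ``window_s`` seconds of the)
    signal. Raises :class:`UnanalyzableWindowError` if the band carries
    no distinct peak (e.g. a flat line)."""
    x = recording.samples
    fs = recording.fs
    if window_s is not None:
        x = x[: int(round(window_s * fs))]
    if x.size < MIN_ANALYSIS_S * fs:
        raise ValueError(f"need at least {MIN_ANALYSIS_S:.0f} s of signal")
    return _period_from_samples(x, fs)


def _period_from_samples(x: np.ndarray, fs: float) -> float:
    x = x - x.mean()
    nper = min(x.size, int(8 * fs))
    freqs, pxx = sig.welch(x, fs=fs, nperseg=nper)
    band = (freqs >= CARDIAC_BAND_HZ[0]) & (freqs <= CARDIAC_BAND_HZ[1])
    if not np.any(band) or np.all(pxx[band] <= 0):
        raise UnanalyzableWindowError("no spectral peak in the cardiac band")
    in_band = pxx[band]
    # require the cardiac peak to stand clear of the broadband floor
    if in_band.max() < 10.0 * np.median(pxx[freqs > 0.1]) or in_band.max() == 0:
        raise UnanalyzableWindowError("no distinct cardiac component")
    f0 = freqs[band][int(np.argmax(in_band))]
    return float(1.0 / f0)


def _detrend(x: np.ndarray, fs: float, period_s: float) -> np.ndarray:
    """Remove slow-wave/respiratory baseline with a moving-average filter
    about two beats long; offset- and scale-commuting, so detection stays
    invariant to affine transforms of the pressure scale."""
    win = max(3, int(round(2.0 * period_s * fs)) | 1)
    baseline = uniform_filter1d(x.astype(float), win, mode="nearest")
    return x - baseline


def _refine_to_foot(x: np.ndarray, trough: int, fs: float, period_s: float) -> int:
    """Snap a coarse trough to the foot of the next systolic upstroke:
    the point where the slope first exceeds 10% of the upstroke maximum,
    walking back from the steepest rise within ~0.8 period."""
    hi = min(x.size, trough + max(2, int(round(0.8 * period_s * fs))))
    if hi - trough < 3:
        return trough
    win = max(3, int(round(0.02 * fs)) | 1)
    d = np.gradient(uniform_filter1d(x[trough:hi].astype(float), win, mode="nearest"))
    d_max = d.max()
    if d_max <= 0:
        return trough
    # first substantial rise, not the global steepest: in multi-peaked
    # beats the tidal (P2) upstroke can out-slope the percussion (P1) one
    above = np.nonzero(d >= 0.5 * d_max)[0]
    u = int(above[0])
    thr = 0.1 * d[u]
    i = u
    while i > 0 and d[i] > thr:
        i -= 1
    return trough + i


def detect_onsets(recording: ICPRecording) -> np.ndarray:
    """Ordered onset indices for the whole recording.

    The beat onset is the diastolic trough at the foot of the systolic
    upstroke: coarse troughs are located block-wise with a spacing
    derived from the block's spectral heart period, then snapped to the
    upstroke foot. Blocks whose spectrum shows no cardiac component
    (flat or artifact-dominated stretches) contribute no onsets.
    """
    x = recording.samples
    fs = recording.fs
    if x.size < MIN_ANALYSIS_S * fs:
        raise ValueError(f"recording shorter than {MIN_ANALYSIS_S:.0f} s")
    xf = sig.medfilt(x, kernel_size=3)

    block = int(BLOCK_S * fs)
    onsets: list[int] = []
    for start in range(0, x.size, block):
        stop = min(start + block, x.size)
        if stop - start < MIN_ANALYSIS_S * fs:
            start = max(0, x.size - int(MIN_ANALYSIS_S * fs) - 1)
        try:
            period = _period_from_samples(x[start:stop], fs)
        except UnanalyzableWindowError:
            continue
        margin = int(round(period * fs))
        lo = max(0, start - margin)
        hi = min(x.size, stop + margin)
        seg = _detrend(xf[lo:hi], fs, period)
        dist = max(1, int(round(0.6 * period * fs)))
        prom = 0.15 * (np.percentile(seg, 95) - np.percentile(seg, 5))
        troughs, _ = sig.find_peaks(-seg, distance=dist, prominence=prom)
        for t in troughs + lo:
            if start <= t < stop:
                onsets.append(_refine_to_foot(xf, int(t), fs, period))

    out = np.array(sorted(set(onsets)), dtype=int)
    if out.size > 1:  # drop troughs closer than the shortest credible beat
        keep = [0]
        for i in range(1, out.size):
            if out[i] - out[keep[-1]] >= int(0.25 * fs):
                keep.append(i)
        out = out[keep]
    return out


def segment_pulses(recording: ICPRecording, onsets: np.ndarray) -> list[PulseSegment]:
    """Half-open ``[onset, next_onset)`` slices, one per consecutive pair.

    Segments outside the 0.25-2.5 s duration gate are retained; the
    classifier screens them into the artifact class.
    """
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size and np.any(np.diff(onsets) <= 0):
        raise ValueError("onsets must be strictly increasing")
    return [
        PulseSegment(int(a), int(b), recording.samples[a:b], recording.fs)
        for a, b in zip(onsets[:-1], onsets[1:])
    ]
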