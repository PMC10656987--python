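import numpy as np
import pytest

from icppulse.types import ClassifiedPulse, PulseClass, PulseSegment, SubPeakSet


def make_classified(t_onset: float, label: int, dur: float = 1.0, amp: float = 8.0,
                    fs: float = 100.0) -> ClassifiedPulse:
    """A minimal classified pulse for window/summary tests (the segment
    carries only the endpoints needed for its amplitude)."""
    i0 = int(round(t_onset * fs))
    seg = PulseSegment(i0, i0 + max(1, int(round(dur * fs))), np.array([0.0, amp]), fs)
    return ClassifiedPulse(seg, SubPeakSet([]), PulseClass(label), amp)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def match_onsets(detected_s: np.ndarray, truth_s: np.ndarray, tol_s: float = 0.1):
    """Greedy one-to-one matching; returns (recall, precision)."""
    used: set[int] = set()
    tp = 0
    for t in truth_s:
        if detected_s.size == 0:
            break
        d = np.abs(detected_s - t)
        j = int(np.argmin(d))
        if d[j] <= tol_s and j not in used:
            tp += 1
            used.add(j)
    recall = tp / len(truth_s) if len(truth_s) else 0.0
    precision = tp / len(detected_s) if len(detected_s) else 0.0
    return recall, precision
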