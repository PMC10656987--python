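"""Core domain containers for ICP pulse-waveform analysis.

Pressure is always in mm Hg, time in seconds, sampling rate in Hz.
A morphology label is one of the four compliance classes (1 = normal
triphasic pulse with dominant P1 ... 4 = rounded/triangular single-maximum
pulse) or ``ARTIFACT`` for distorted waveforms and detection errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

MIN_FS_HZ = 50.0  #: minimum viable sampling frequency for pulse morphology
MIN_ANALYSIS_S = 10.0  #: shortest signal span any analysis call accepts

#: candidate-beat duration gate (s); segments outside are artifact candidates
MIN_BEAT_S = 0.25
MAX_BEAT_S = 2.5


class PulseClass(IntEnum):
    """Morphology label. Integer values 1-4 are the class numbers the
    Pulse Shape Index averages; ``ARTIFACT`` (0) is excluded from PSI."""

    ARTIFACT = 0
    C1 = 1
    C2 = 2
    C3 = 3
    C4 = 4

    @property
    def is_valid(self) -> bool:
        return self != PulseClass.ARTIFACT


VALID_CLASSES = (PulseClass.C1, PulseClass.C2, PulseClass.C3, PulseClass.C4)


@dataclass
class ICPRecording:
    """Uniformly sampled intracranial pressure trace.

    Parameters
    ----------
    samples : ndarray
        Pressure samples, mm Hg.
    fs : float
        Sampling rate, Hz (>= 50).
    patient_id : str
        Opaque patient identifier.
    t0_offset_h : float, optional
        Hours between the CT scan and recording start (informational).
    """

    samples: np.ndarray
    fs: float
    patient_id: str = "anon"
    t0_offset_h: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs < MIN_FS_HZ:
            raise ValueError(
                f"sampling rate {self.fs} Hz is below the {MIN_FS_HZ:.0f} Hz "
                "minimum viable for pulse-morphology analysis"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class PulseSegment:
    """One candidate cardiac-cycle slice, half-open ``[onset, end)``."""

    onset_index: int
    end_index: int
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.end_index <= self.onset_index:
            raise ValueError("end_index must exceed onset_index")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return (self.end_index - self.onset_index) / self.fs

    @property
    def onset_time_s(self) -> float:
        return self.onset_index / self.fs

    @property
    def amp_mmHg(self) -> float:
        """Peak-to-peak amplitude of the slice."""
        return float(np.max(self.samples) - np.min(self.samples))

    @property
    def in_duration_gate(self) -> bool:
        return MIN_BEAT_S <= self.duration_s <= MAX_BEAT_S


@dataclass
class SubPeak:
    """A single detected sub-peak (P1, P2 or P3)."""

    latency_fraction: float  #: position within the beat, fraction of duration
    height_mmHg: float  #: height above the segment onset level
    prominence_mmHg: float


@dataclass
class SubPeakSet:
    """Up to three sub-peaks in temporal order (P1, P2, P3)."""

    peaks: list[SubPeak] = field(default_factory=list)

    def __post_init__(self) -> None:
        lats = [p.latency_fraction for p in self.peaks]
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise ValueError("sub-peak latencies must be strictly increasing")

    @property
    def n_visible(self) -> int:
        return len(self.peaks)

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(p.height_mmHg for p in self.peaks)


@dataclass
class ClassifiedPulse:
    """A pulse segment with its sub-peak descriptors and morphology label."""

    segment: PulseSegment
    subpeaks: SubPeakSet
    label: PulseClass
    amp_mmHg: float

    @property
    def onset_time_s(self) -> float:
        return self.segment.onset_time_s

    @property
    def is_valid(self) -> bool:
        return self.label.is_valid


@dataclass
class WindowMetrics:
    """Per-window class fractions and Pulse Shape Index.

    ``psi`` is the weighted sum of class numbers ``i`` with weights equal
    to the fraction ``p_i`` of valid pulses in the window assigned to each
    class (artifacts excluded); ``nan`` when the window holds fewer valid
    pulses than the validity floor.
    """

    window_start_s: float
    window_len_s: float
    class_fractions: tuple[float, float, float, float]
    psi: float
    n_valid: int
    n_artifact: int

    @property
    def psi_defined(self) -> bool:
        return bool(np.isfinite(self.psi))


@dataclass
class PatientSummary:
    """First-24-h summary metrics for one patient."""

    patient_id: str
    mean_icp_mmHg: float
    amp_icp_mmHg: float
    mean_psi: float
    hours_analyzed: float = 24.0


# thresholds for the binary CT flags (strict inequalities)
MLS_THRESHOLD_MM = 5.0
LESION_THRESHOLD_CM3 = 25.0


@dataclass
class CTAssessment:
    """Per-patient CT assessment with derived binary flags.

    Midline shift is *present* iff it exceeds 5 mm; a mass lesion is
    *present* iff the total lesion volume exceeds 25 cm^3 (both strict).
    Marshall categories I-VI are stored as integers 1-6.
    """

    patient_id: str
    midline_shift_mm: float
    lesion_volume_cm3: float
    marshall: int
    rotterdam: int

    def __post_init__(self) -> None:
        if self.midline_shift_mm < 0:
            raise ValueError("midline shift must be non-negative")
        if self.lesion_volume_cm3 < 0:
            raise ValueError("lesion volume must be non-negative")
        if not 1 <= int(self.marshall) <= 6:
            raise ValueError("Marshall category must be in 1..6")
        if not 1 <= int(self.rotterdam) <= 6:
            raise ValueError("Rotterdam score must be in 1..6")

    @property
    def mls_present(self) -> bool:
        return self.midline_shift_mm > MLS_THRESHOLD_MM

    @property
    def lesion_present(self) -> bool:
        return self.lesion_volume_cm3 > LESION_THRESHOLD_CM3
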