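"""Synthetic ICP pulses, recordings and cohorts with ground truth.

The generator renders single-beat archetypes of the four morphology
classes as sums of Gaussian sub-waves (P1, P2, P3), composes them into
long recordings with heart-rate jitter, slow-wave and respiratory
modulation, additive noise and injected artifacts, and samples whole
cohorts in which a latent injury-severity variable couples pulse
morphology to CT covariates (midline shift, lesion volume, Marshall and
Rotterdam scores) while leaving mean ICP nearly uncoupled — the regime
in which pulse-shape information is expected to outperform mean ICP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .types import (
    CTAssessment,
    ICPRecording,
    MIN_FS_HZ,
    PatientSummary,
    PulseClass,
)

__all__ = [
    "PulseArchetypeParams",
    "RecordingSpec",
    "CohortSpec",
    "GroundTruth",
    "ARCHETYPES",
    "generate_pulse",
    "generate_recording",
    "generate_cohort",
    "CohortResult",
]


@dataclass(frozen=True)
class PulseArchetypeParams:
    """Geometry of a single-beat archetype.

    Sub-peak amplitudes are relative heights of the P1/P2/P3 Gaussian
    components; latencies and widths (Gaussian sigma) are fractions of
    the beat duration. ``baseline`` and ``pulse_pressure`` set the
    physical scale in mm Hg.
    """

    class_label: int
    sub_peak_amplitudes: tuple[float, float, float]
    sub_peak_latencies: tuple[float, float, float]
    sub_peak_widths: tuple[float, float, float]
    baseline: float = 0.0
    pulse_pressure: float = 8.0

    def __post_init__(self) -> None:
        if self.class_label not in (1, 2, 3, 4):
            raise ValueError(f"invalid class label {self.class_label}")
        lats = self.sub_peak_latencies
        if not (0 < lats[0] < lats[1] < lats[2] < 1):
            raise ValueError("latencies must be strictly increasing in (0,1)")
        if any(a < 0 for a in self.sub_peak_amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if self.pulse_pressure < 0:
            raise ValueError("pulse_pressure must be >= 0")


# Default archetype geometry. The published class definitions are purely
# ordinal (relative heights of P1/P2/P3); latencies and widths here are
# chosen for visual plausibility of a triphasic pressure pulse.
ARCHETYPES: dict[int, PulseArchetypeParams] = {
    1: PulseArchetypeParams(1, (1.00, 0.74, 0.50), (0.14, 0.38, 0.62), (0.045, 0.050, 0.050)),
    2: PulseArchetypeParams(2, (0.80, 1.00, 0.55), (0.14, 0.38, 0.62), (0.045, 0.050, 0.050)),
    3: PulseArchetypeParams(3, (0.62, 1.00, 0.85), (0.14, 0.38, 0.62), (0.045, 0.050, 0.050)),
    # class 4: one broad rounded component, "only one visible maximum"
    4: PulseArchetypeParams(4, (0.0, 1.00, 0.0), (0.10, 0.40, 0.90), (0.05, 0.19, 0.05)),
}


def generate_pulse(
    params: PulseArchetypeParams,
    beat_duration: float,
    fs: float,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Render one beat of ``round(beat_duration * fs)`` samples.

    The waveform is a sum of Gaussian sub-waves, linearly detrended so
    both endpoints sit at the minimum, then scaled so that
    ``min == baseline`` and ``max - min == pulse_pressure`` exactly.
    Optional white noise (``noise_sd`` mm Hg) is added after scaling.
    """
    if not 0.3 <= beat_duration <= 2.0:
        raise ValueError("beat_duration must be within [0.3, 2.0] s")
    if fs < MIN_FS_HZ:
        raise ValueError(f"fs must be >= {MIN_FS_HZ:.0f} Hz")
    n = int(round(beat_duration * fs))
    t = np.arange(n) / n  # beat-fraction time base
    shape = np.zeros(n)
    for a, mu, sig in zip(
        params.sub_peak_amplitudes, params.sub_peak_latencies, params.sub_peak_widths
    ):
        if a > 0:
            shape += a * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    # pin both endpoints to the same level so beats concatenate smoothly
    shape -= shape[0] + (shape[-1] - shape[0]) * t
    shape -= shape.min()
    peak = shape.max()
    if params.pulse_pressure == 0 or peak == 0:
        out = np.full(n, params.baseline)
    else:
        out = params.baseline + params.pulse_pressure * shape / peak
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, n)
    return out


@dataclass(frozen=True)
class RecordingSpec:
    """Recipe for a synthetic continuous ICP recording.

    ``class_schedule`` is a list of ``((t_start_s, t_end_s), (p1,p2,p3,p4))``
    entries; the mixture in force at each beat's onset decides its class.
    Artifacts replace a fraction ``artifact_rate`` of beats with one of
    three non-physiological shapes (spike, flatline, truncated beat).
    """

    duration_s: float = 300.0
    fs: float = 100.0
    heart_rate_bpm: float = 60.0
    heart_rate_jitter_bpm: float = 2.0
    class_schedule: tuple = (((0.0, np.inf), (1.0, 0.0, 0.0, 0.0)),)
    mean_icp_mmHg: float = 12.0
    pulse_pressure_mmHg: float = 8.0
    slow_wave_amp_mmHg: float = 1.5
    slow_wave_period_s: float = 60.0
    respiratory_amp_mmHg: float = 0.5
    respiratory_freq_hz: float = 0.25
    noise_sd: float = 0.1
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < MIN_FS_HZ:
            raise ValueError(f"fs must be >= {MIN_FS_HZ:.0f} Hz")
        if not 0 <= self.artifact_rate < 1:
            raise ValueError("artifact_rate must be in [0, 1)")
        if not 40 <= self.heart_rate_bpm <= 180:
            raise ValueError("heart rate must be in the 40-180 bpm cardiac band")
        for (_t0, _t1), mix in self.class_schedule:
            m = np.asarray(mix, dtype=float)
            if m.size != 4 or np.any(m < 0) or not np.isclose(m.sum(), 1.0):
                raise ValueError("each class mixture must be a length-4 probability vector")

    def mixture_at(self, t: float) -> np.ndarray:
        for (t0, t1), mix in self.class_schedule:
            if t0 <= t < t1:
                return np.asarray(mix, dtype=float)
        # fall back to the last scheduled mixture
        return np.asarray(self.class_schedule[-1][1], dtype=float)


@dataclass
class GroundTruth:
    """Per-beat truth for a synthetic recording."""

    onset_times_s: np.ndarray
    pulse_classes: list[PulseClass]
    amplitudes_mmHg: np.ndarray

    def __post_init__(self) -> None:
        self.onset_times_s = np.asarray(self.onset_times_s, dtype=float)
        if np.any(np.diff(self.onset_times_s) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if len(self.pulse_classes) != self.onset_times_s.size:
            raise ValueError("one class per onset required")


_ARTIFACT_KINDS = ("spike", "flatline", "truncated")


def generate_recording(spec: RecordingSpec) -> tuple[ICPRecording, GroundTruth]:
    """Compose a recording beat-by-beat and return it with its ground truth.

    Artifact beats are injected after composition by overwriting the
    final signal: flatlines hold the value at the beat onset, spikes add
    a short high-pressure transient on a flattened beat, truncated beats
    keep the first half of the waveform and hold the last value.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = int(round(spec.duration_s * spec.fs))

    onsets, classes, amps, pieces = [], [], [], []
    t_cursor = 0.0
    while t_cursor < spec.duration_s:
        bpm = np.clip(
            rng.normal(spec.heart_rate_bpm, spec.heart_rate_jitter_bpm), 40.0, 180.0
        )
        beat_dur = float(np.clip(60.0 / bpm, 0.34, 1.5))
        mix = spec.mixture_at(t_cursor)
        label = PulseClass(int(rng.choice([1, 2, 3, 4], p=mix)))
        is_artifact = rng.random() < spec.artifact_rate
        pp = spec.pulse_pressure_mmHg * float(rng.lognormal(0.0, 0.05))
        params = replace(ARCHETYPES[int(label)], pulse_pressure=pp)
        beat = generate_pulse(params, beat_dur, spec.fs)
        onsets.append(t_cursor)
        classes.append(PulseClass.ARTIFACT if is_artifact else label)
        amps.append(float(beat.max() - beat.min()))
        pieces.append((beat, is_artifact))
        t_cursor += beat.size / spec.fs

    signal = np.concatenate([b for b, _ in pieces])[:n_total]
    if signal.size < n_total:  # pad with baseline if rounding left a gap
        signal = np.pad(signal, (0, n_total - signal.size))

    t = np.arange(n_total) / spec.fs
    signal = (
        signal
        + spec.mean_icp_mmHg
        + spec.slow_wave_amp_mmHg * np.sin(2 * np.pi * t / spec.slow_wave_period_s)
        + spec.respiratory_amp_mmHg * np.sin(2 * np.pi * spec.respiratory_freq_hz * t)
        + rng.normal(0.0, spec.noise_sd, n_total)
    )

    # overwrite artifact beats on the composed signal
    start = 0
    for (beat, is_artifact), onset in zip(pieces, onsets):
        stop = min(start + beat.size, n_total)
        if is_artifact and stop > start:
            kind = _ARTIFACT_KINDS[int(rng.integers(len(_ARTIFACT_KINDS)))]
            seg = signal[start:stop]
            if kind == "flatline":
                seg[:] = seg[0]
            elif kind == "spike":
                seg[:] = seg[0]
                k = max(1, int(0.01 * spec.fs))
                mid = seg.size // 2
                seg[mid : mid + k] += rng.uniform(55.0, 80.0)
            else:  # truncated: keep first half, hold the last value
                half = seg.size // 2
                seg[half:] = seg[half - 1] if half > 0 else seg[0]
        start += beat.size

    recording = ICPRecording(signal, spec.fs)
    truth = GroundTruth(np.asarray(onsets), classes, np.asarray(amps))
    return recording, truth


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic patient cohort.

    A standard-normal latent severity per patient drives, with strength
    ``severity_effect``, the pulse-class mixture and all CT covariates;
    ``icp_effect`` couples severity to baseline mean ICP and is kept
    small by default so that group differences in mean ICP stay modest —
    mirroring cohorts where morphology separates groups that mean
    pressure does not. With ``severity_effect = 0`` every coupling
    vanishes and all associations are null.
    """

    n_patients: int = 130
    prevalence_mls: float = 27 / 130
    prevalence_lesion: float = 40 / 130
    severity_effect: float = 1.0
    icp_effect: float = 0.8
    mean_icp_level_mmHg: float = 12.5
    icp_sd_mmHg: float = 3.5
    amp_level_mmHg: float = 8.6
    amp_sd_mmHg: float = 2.8
    psi_noise_sd: float = 0.60
    mixture_center_base: float = 2.0
    mixture_center_slope: float = 0.7
    mixture_spread: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        for p in (self.prevalence_mls, self.prevalence_lesion):
            if not 0 <= p <= 1:
                raise ValueError("prevalences must be in [0, 1]")


# marginal category probabilities used to bin the ordinal-score latents
_MARSHALL_PROBS = np.array([0.025, 0.53, 0.13, 0.025, 0.0, 0.29])
_ROTTERDAM_PROBS = np.array([0.01, 0.14, 0.49, 0.16, 0.17, 0.03])


def _ordinal_from_latent(z: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Bin standard-normal latents into ordinal scores 1..6 by quantile."""
    edges = sps.norm.ppf(np.clip(np.cumsum(probs)[:-1], 1e-12, 1 - 1e-12))
    return np.digitize(z, edges) + 1


def class_mixture_for_severity(spec: CohortSpec, severity: float) -> np.ndarray:
    """Class mixture implied by a severity value: a discretized Gaussian
    kernel over class numbers 1..4 centred at a severity-shifted mean."""
    c = np.clip(
        spec.mixture_center_base + spec.mixture_center_slope * spec.severity_effect * severity,
        1.0,
        4.0,
    )
    i = np.arange(1, 5)
    w = np.exp(-0.5 * ((i - c) / spec.mixture_spread) ** 2)
    return w / w.sum()


@dataclass
class CohortResult:
    """Cohort draw: per-patient summaries, CT table, and generator truth."""

    summaries: list[PatientSummary]
    cts: list[CTAssessment]
    severity: np.ndarray
    mixtures: np.ndarray  # (n_patients, 4) scheduled class mixtures
    mean_psi_true: np.ndarray


def generate_cohort(spec: CohortSpec) -> CohortResult:
    """Sample a cohort of per-patient summary metrics and CT covariates.

    Latent construction: severity ``s ~ N(0,1)``; each CT covariate mixes
    severity with an independent standard-normal error, scaled so the
    combined latent is standard normal, and is then mapped through a
    monotone transform whose cut point is placed at the quantile that
    yields the requested prevalence. Mean PSI is the mixture-implied mean
    class number plus measurement noise; mean ICP and AmpICP are normal
    around cohort-typical levels with weak severity coupling.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    s = rng.normal(size=n)
    se = spec.severity_effect
    norm = np.sqrt(se**2 + 1.0)

    def latent() -> np.ndarray:
        return (se * s + rng.normal(size=n)) / norm

    # midline shift: piecewise-linear monotone map, cut at 5 mm
    z_mls = latent()
    q_mls = sps.norm.ppf(1.0 - spec.prevalence_mls)
    mls = np.clip(5.0 + 2.5 * (z_mls - q_mls), 0.0, None)

    # lesion volume: log-normal, cut at 25 cm^3
    z_les = latent()
    q_les = sps.norm.ppf(1.0 - spec.prevalence_lesion)
    vol = 25.0 * np.exp(z_les - q_les)

    marshall = _ordinal_from_latent(latent(), _MARSHALL_PROBS)
    rotterdam = _ordinal_from_latent(latent(), _ROTTERDAM_PROBS)

    mixtures = np.vstack([class_mixture_for_severity(spec, si) for si in s])
    psi_true = mixtures @ np.arange(1, 5)
    mean_psi = np.clip(psi_true + rng.normal(0.0, spec.psi_noise_sd, n), 1.0, 4.0)

    mean_icp = np.clip(
        spec.mean_icp_level_mmHg + spec.icp_effect * s + rng.normal(0.0, spec.icp_sd_mmHg, n),
        2.0,
        None,
    )
    amp = np.clip(
        spec.amp_level_mmHg + 0.25 * se * s + rng.normal(0.0, spec.amp_sd_mmHg, n),
        1.0,
        None,
    )

    summaries, cts = [], []
    for i in range(n):
        pid = f"P{i:03d}"
        summaries.append(
            PatientSummary(pid, float(mean_icp[i]), float(amp[i]), float(mean_psi[i]))
        )
        cts.append(
            CTAssessment(pid, float(mls[i]), float(vol[i]), int(marshall[i]), int(rotterdam[i]))
        )
    return CohortResult(summaries, cts, s, mixtures, psi_true)


def recording_spec_for_severity(
    spec: CohortSpec, severity: float, duration_s: float = 300.0, seed: int = 0
) -> RecordingSpec:
    """Full-signal mode: a RecordingSpec whose class mixture and mean ICP
    follow the same severity couplings as the summary-mode cohort."""
    mix = tuple(class_mixture_for_severity(spec, severity))
    return RecordingSpec(
        duration_s=duration_s,
        class_schedule=(((0.0, np.inf), mix),),
        mean_icp_mmHg=float(spec.mean_icp_level_mmHg + spec.icp_effect * severity),
        seed=seed,
    )
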