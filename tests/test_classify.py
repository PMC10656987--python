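"""Morphology rule cascade: sub-peaks, labels, artifact screens, invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icppulse.classify import classify_pulse, classify_recording, find_subpeaks
from icppulse.synth import (
    ARCHETYPES,
    PulseArchetypeParams,
    RecordingSpec,
    generate_pulse,
    generate_recording,
)
from icppulse.types import PulseClass, PulseSegment


def segment_of(samples: np.ndarray, fs: float = 100.0) -> PulseSegment:
    return PulseSegment(0, samples.size, samples, fs)


def two_gaussian_pulse(a1: float, a2: float, fs: float = 100.0) -> np.ndarray:
    """Hand-built two-peak beat, independent of the package generator."""
    t = np.arange(int(fs)) / fs
    y = a1 * np.exp(-0.5 * ((t - 0.15) / 0.05) ** 2)
    y += a2 * np.exp(-0.5 * ((t - 0.40) / 0.05) ** 2)
    return 10.0 + 8.0 * y


class TestFindSubpeaks:
    def test_class1_three_decreasing_peaks(self):
        sp = find_subpeaks(segment_of(generate_pulse(ARCHETYPES[1], 1.0, 100.0)))
        assert sp.n_visible == 3
        assert np.all(np.diff(sp.heights) < 0)

    def test_class4_single_visible_maximum(self):
        sp = find_subpeaks(segment_of(generate_pulse(ARCHETYPES[4], 1.0, 100.0)))
        assert sp.n_visible == 1

    def test_monotone_ramp_has_no_interior_structure(self):
        sp = find_subpeaks(segment_of(np.linspace(10, 20, 100)))
        assert sp.n_visible <= 1

    def test_shoulder_recovered_from_curvature(self):
        # P1 present only as an inflection on the rise toward P2
        params = PulseArchetypeParams(
            2, (0.45, 1.0, 0.5), (0.22, 0.36, 0.62), (0.05, 0.06, 0.05)
        )
        sp = find_subpeaks(segment_of(generate_pulse(params, 1.0, 100.0)))
        assert sp.n_visible == 3
        assert sp.peaks[0].latency_fraction < 0.3


class TestClassifyPulse:
    @pytest.mark.parametrize("label", [1, 2, 3, 4])
    def test_clean_archetype_recovery(self, label):
        rng = np.random.default_rng(label)
        hits = 0
        for _ in range(100):
            x = generate_pulse(ARCHETYPES[label], rng.uniform(0.6, 1.2), 100.0)
            hits += int(classify_pulse(segment_of(x)).label) == label
        assert hits >= 95

    def test_class2_robust_to_noise(self):
        hits = sum(
            int(classify_pulse(segment_of(
                generate_pulse(ARCHETYPES[2], 1.0, 100.0, seed=s, noise_sd=0.2)
            )).label) == 2
            for s in range(100)
        )
        assert hits >= 90

    def test_tie_between_p1_p2_resolves_to_class1(self):
        x = two_gaussian_pulse(1.0, 1.0)
        assert classify_pulse(segment_of(x)).label == PulseClass.C1

    def test_clearly_higher_p2_is_class2(self):
        x = two_gaussian_pulse(1.0, 1.15)
        assert classify_pulse(segment_of(x)).label == PulseClass.C2

    @pytest.mark.parametrize(
        "samples",
        [
            np.full(100, 12.0),  # flatline
            np.full(100, 12.0) + 0.1 * np.sin(np.arange(100) / 8),  # sub-gate amp
        ],
        ids=["flat", "tiny-amplitude"],
    )
    def test_artifact_amplitude_screens(self, samples):
        assert classify_pulse(segment_of(samples)).label == PulseClass.ARTIFACT

    def test_spike_and_duration_screens(self):
        spike = np.full(100, 12.0)
        spike[50] = 90.0  # amp 78 mm Hg, above physiological gate
        assert classify_pulse(segment_of(spike)).label == PulseClass.ARTIFACT
        short = generate_pulse(ARCHETYPES[1], 1.0, 100.0)[:15]  # 0.15 s
        assert classify_pulse(segment_of(short)).label == PulseClass.ARTIFACT

    def test_affine_invariance_of_labels(self):
        for label in (1, 2, 3, 4):
            x = generate_pulse(ARCHETYPES[label], 1.0, 100.0)
            base = classify_pulse(segment_of(x)).label
            trans = classify_pulse(segment_of(2.0 * x + 7.0)).label
            assert base == trans == PulseClass(label)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_every_finite_segment_gets_exactly_one_label(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 260))
        x = rng.normal(12.0, rng.uniform(0.01, 20.0), n)
        label = classify_pulse(segment_of(x)).label
        assert label in set(PulseClass)


@pytest.fixture(scope="module")
def mixed_recording():
    spec = RecordingSpec(
        duration_s=300, class_schedule=(((0, np.inf), (0.5, 0.5, 0, 0)),), seed=3
    )
    return generate_recording(spec)


class TestClassifyRecording:
    def test_mixture_fractions_recovered(self, mixed_recording):
        rec, _ = mixed_recording
        labels = np.array([int(p.label) for p in classify_recording(rec)])
        n = labels.size
        se = np.sqrt(0.25 / n)
        assert abs(np.mean(labels == 1) - 0.5) <= 3 * se
        assert abs(np.mean(labels == 2) - 0.5) <= 3 * se

    def test_artifact_fraction_recovered(self):
        rec, _ = generate_recording(RecordingSpec(duration_s=300, artifact_rate=0.1, seed=5))
        labels = np.array([int(p.label) for p in classify_recording(rec)])
        se = np.sqrt(0.1 * 0.9 / labels.size)
        assert abs(np.mean(labels == 0) - 0.1) <= 3 * se + 0.01

    def test_clean_class1_recording_has_no_pathological_labels(self):
        rec, _ = generate_recording(RecordingSpec(duration_s=120, seed=6))
        labels = [int(p.label) for p in classify_recording(rec)]
        assert all(l not in (3, 4) for l in labels)

    def test_order_preserving(self, mixed_recording):
        rec, _ = mixed_recording
        pulses = classify_recording(rec)
        times = [p.onset_time_s for p in pulses]
        assert times == sorted(times)
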