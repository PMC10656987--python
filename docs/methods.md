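# Methods

## The measurement problem

Cerebrospinal compliance — the capacity of the intracranial space to buffer
volume changes — cannot be monitored directly without invasive volume
manipulation. The shape of the per-heartbeat ICP pulse is an indirect
window on it: with falling compliance the tidal peak (P2) and dicrotic peak
(P3) gain prominence over the percussion peak (P1), and the pulse finally
rounds into a single-maximum wave. `icppulse` operationalizes this
progression as a four-class ordinal scale plus an artifact class, and
averages class numbers over time as the Pulse Shape Index (PSI).

Class semantics, in shape terms:

1. dominant P1 (normal triphasic pulse);
2. P2 at or above P1, P1 still higher than P3;
3. both P2 and P3 at or above P1;
4. rounded or triangular wave with only one visible maximum;
0. artifact: distorted waveform or detection error, excluded from PSI.

## Pipeline stages and their assumptions

### Beat detection (`icppulse.detect`)

The onset of a beat is the diastolic trough at the foot of the systolic
upstroke. Detection is trough-anchored and period-guided:

* the dominant cardiac period is the strongest Welch-spectrum component in
  the 0.67–3.0 Hz band (40–180 bpm), re-estimated in 30-s blocks so that
  heart-rate drift over 24-h recordings is tracked;
* slow waves and respiration are removed for trough search by subtracting a
  moving-average baseline about two beats long (edge-replicated, so no
  boundary artifacts); the raw samples are preserved for classification;
* coarse troughs (minimum spacing 0.6 periods, prominence 15% of the
  block's robust range) are snapped to the foot of the **first** upstroke
  whose slope reaches 50% of the window maximum — using the global steepest
  slope instead would lock onto the P2 upstroke in class-2/3 beats. The
  foot is where the slope falls below 10% of that upstroke's peak slope.
* a 3-sample median filter suppresses single-sample spikes before trough
  search.

Every operation commutes with affine transforms of the pressure scale, so
detection is invariant to sensor offset and gain. Blocks with no distinct
cardiac spectral component (flat or artifact-dominated stretches)
contribute no onsets; the surrounding segments then fail the duration gate
and fall into the artifact class downstream.

Assumption: input is uniformly sampled at ≥ 50 Hz. Below 50 Hz the pulse
shape is too poorly resolved for morphology analysis, and such inputs are
rejected everywhere (generator, reader, detector).

### Morphology classification (`icppulse.classify`)

Each segment is reduced to at most three sub-peaks (P1/P2/P3 by temporal
order) and labelled by a deterministic cascade. Numerical choices:

* smoothing: Savitzky–Golay, window 11% of the beat (odd, ≥ polyorder+2),
  polynomial order 3;
* sub-peaks: local maxima with prominence ≥ 5% of the pulse amplitude;
* shoulders (a sub-peak visible only as an inflection) are recovered from
  maxima of negative second derivative, computed with a wider
  Savitzky–Golay derivative window (16.5% of the beat). A candidate must
  (a) exceed a curvature-prominence threshold scaled to an
  amplitude-sized feature 10% of the beat wide (relative factor 0.12),
  (b) lie outside the half-prominence width of every true maximum —
  a broad hump's own curvature ridge drifts off-apex under noise —
  and (c) carry at least 20% of the pulse amplitude;
* rule boundaries use a tie tolerance of 2% of pulse amplitude, with ties
  resolving toward the lower (less pathological) class; the class-1/2
  boundary treats P2 ≈ P1 as class 1 for the same conservative reason;
* class 4 requires a single visible maximum **and** width at half
  prominence ≥ 40% of the beat (narrower lone peaks fall through the
  cascade, spike-like ones — width < 3% — are artifacts);
* artifact screens, in order: duration outside 0.25–2.5 s; peak-to-peak
  amplitude outside 0.5–50 mm Hg (the only rule in physical units, by
  design); more than 30% of exactly-flat sample-to-sample steps (sensor
  dropout); no visible structure.

The cascade is exhaustive and exclusive — any finite segment receives
exactly one label — and, apart from the physical amplitude gate, invariant
to affine transforms of the pressure scale.

This classifier is a deterministic, interpretable implementation of the
published class semantics. It is not a reimplementation of any particular
trained model, and agreement figures against the synthetic generator
(≥ 95% on clean archetypes) say nothing about agreement with
expert-labelled clinical waveforms.

### PSI and summaries (`icppulse.metrics`)

PSI = Σ i·pᵢ over valid pulses in left-aligned, half-open 5-min windows
shifted every 10 s (window length and shift configurable). Windows with
fewer valid pulses than a validity floor — 60% of the beat count expected
at the cohort-typical beat duration (median over pulses) — yield an
undefined PSI and are excluded from aggregation; PSI from nearly-empty
windows would otherwise be dominated by a handful of beats. Per patient,
the first 24 h are summarized as:

* mean ICP: arithmetic mean of raw samples outside artifact-flagged
  segments (mm Hg);
* AmpICP: mean per-pulse peak-to-peak amplitude over valid pulses (mm Hg);
* mean PSI: arithmetic mean of defined window PSI values (median available
  as a config option).

### CT features (`icppulse.ct`)

Midline shift is present iff > 5 mm; mass lesions present iff total volume
> 25 cm³ — strict inequalities, so boundary values are negative cases.
Marshall categories I–VI are stored as 1–6 (category V is admissible even
though it can be empty in a given cohort). Rows with missing measurements
are excluded listwise and logged; duplicates are an error. No imputation.

### Cohort statistics (`icppulse.stats`)

The battery mirrors standard practice for skewed neuromonitoring metrics:
Shapiro–Wilk (3 ≤ n ≤ 5000) justifies the nonparametric route; group
contrasts use the two-sided Mann–Whitney U (exact null distribution when
n_A·n_B ≤ 400 and tie-free, tie-corrected normal approximation otherwise)
reported as median [Q1–Q3] (linear-interpolation quartiles); monotone
association uses Spearman's rho (mid-ranks, t-approximation p); binary
discrimination uses the rank-method AUC with half credit for ties.

ROC details: the 95% CI is DeLong by default (deterministic; a
single-member group contributes no estimable variance component), with a
seeded stratified bootstrap (2000 resamples) as an option. The
classification threshold maximizes Youden's J = sensitivity +
specificity − 1 under the strict `score > threshold ⇒ positive` convention
(matching the strict CT thresholds); ties in J break toward the lower
threshold, i.e. higher sensitivity. A paired DeLong comparison of the
mean-PSI AUC against the mean-ICP and AmpICP AUCs is emitted as a clearly
labelled extension — the core battery reports AUCs with CIs only.
Significance level 0.05 throughout; no multiple-testing correction by
default (Holm can be applied downstream), matching common practice for
exploratory cohort batteries.

## The synthetic generator: what it emulates, what it does not

### Single beats

Archetypes are sums of three Gaussian sub-waves on a beat-fraction time
base, linearly detrended so both endpoints sit at the minimum (beats then
concatenate without steps), and scaled so min = baseline and max − min =
pulse pressure exactly. The published class definitions are purely ordinal,
so the geometry below is chosen once for visual plausibility of a
triphasic pressure pulse:

| class | amplitudes (P1,P2,P3) | latencies (beat fraction) | widths σ |
| --- | --- | --- | --- |
| 1 | 1.00, 0.74, 0.50 | 0.14, 0.38, 0.62 | 0.045, 0.050, 0.050 |
| 2 | 0.80, 1.00, 0.55 | same | same |
| 3 | 0.62, 1.00, 0.85 | same | same |
| 4 | single component 1.00 | 0.40 | 0.19 (FWHM ≈ 0.45 beat) |

Default pulse pressure 8 mm Hg (cohort-typical AmpICP), baseline 0 relative
to the recording's mean-ICP term.

### Recordings

Beats are drawn with normal heart-rate jitter (default 60 ± 2 bpm, clipped
to 40–180), classes sampled per beat from a piecewise-constant scheduled
mixture, plus: sinusoidal slow waves (default 1.5 mm Hg, 60 s period, in
the 30–120 s physiological band), sinusoidal respiration (0.5 mm Hg,
0.25 Hz), white noise (0.1 mm Hg), and per-beat log-normal amplitude
jitter (σ = 5%). Artifacts replace a configurable fraction of beats with
one of three programmatic kinds applied to the composed signal: flatline
(hold the onset value), spike (flattened beat plus a 55–80 mm Hg, 10-ms
transient), truncated beat (second half held constant). All randomness
flows from a single integer seed; identical seeds give byte-identical
exports.

Not emulated: arterial-pressure coupling, B-wave morphology beyond simple
sinusoids, baseline drift from nursing manoeuvres, position changes, EVD
drainage, sensor-specific transfer functions. Passing tests therefore
demonstrate internal consistency of the pipeline on idealized physiology,
not clinical performance.

### Cohorts

Each patient has a latent severity s ~ N(0,1). With coupling strength
`severity_effect` (default 1.0), s drives:

* the class mixture: a discretized Gaussian kernel over classes 1–4
  centred at 2.0 + 0.7·s (spread 0.7), whose implied mean class number
  plus N(0, 0.6) measurement noise is the patient's mean PSI;
* midline shift and lesion volume: each from a standard-normal latent
  mixing s with independent noise, mapped monotonically (piecewise-linear
  for shift, log-normal for volume) with the cut point placed at the
  quantile that yields the requested prevalence (defaults 27/130 and
  40/130);
* Marshall and Rotterdam scores: the same latent construction binned at
  quantiles of cohort-realistic marginal category frequencies;
* mean ICP: 12.5 + `icp_effect`·s + N(0, 3.5) mm Hg with `icp_effect`
  defaulting to 0.8 — deliberately weak, so that morphology separates
  groups that mean pressure does not;
* AmpICP: 8.6 + 0.25·severity_effect·s + N(0, 2.8) mm Hg.

With `severity_effect = 0` every coupling vanishes and all associations
are null by construction. The default coupling strengths were fixed once
so that a 130-patient cohort lands in the regime the package is designed
to study — mean-PSI AUC for lesion detection near 0.73 against mean-ICP
AUC near 0.58, PSI group medians near 1.8 (lesion absent) vs 2.5
(present), and PSI–volume Spearman correlations in the 0.4–0.5 range —
rather than in an unrealistically easy or impossible one. The summary-mode
generator produces patient-level metrics directly; `recording_spec_for_severity`
maps the same couplings onto full signal specs when end-to-end runs are
wanted (problem sizes in tests use minutes-long signals per patient; the
couplings are identical at any length).

## Degenerate inputs and tie-breaks

* zero pulse pressure renders a flat beat; flat segments are artifacts;
* constant samples make Spearman undefined → error, and the heart-period
  estimator raises on spectra with no distinct cardiac peak (a cardiac
  peak must exceed 10× the median broadband floor);
* a single onset yields no segments; segments outside the duration gate
  are retained but pre-marked for the artifact screen;
* equal sub-peak heights within the 2% tolerance resolve to the lower
  class; equal Youden's J resolves to the more sensitive threshold;
* windows are anchored to elapsed recording time, not clock time.

## Known limitations

* The rule cascade encodes published shape semantics but its artifact
  class is necessarily an approximation; no clinical artifact taxonomy
  was available to calibrate against.
* Beat detection assumes a visible cardiac component; it makes no attempt
  to rescue stretches where the pulse is absent (e.g. during CSF
  drainage), and no ECG/ABP assistance is used.
* The generator's CT couplings are monotone by construction; it cannot
  probe non-monotone morphology–lesion relationships.
* Quartiles, tie conventions and CI methods are stated above; other
  conventions would shift third-decimal results on small cohorts.
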