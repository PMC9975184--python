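# Methods

## Scope and data model

One *session* is an acute seizure-induction experiment: ECoG from one or
two 8×8 epidural grids (2.5-mm pitch; contacts may be flagged
non-available and are then excluded from every statistic but never
dropped), a timeline of administrations (bicuculline induction, then DCZ or
vehicle as the treatment of record), and a stream of manually scored
convulsion events (Twitch/Tremor × contra/ipsi, Body, Head,
VoluntaryMovement; tremor implies duration ≥ 2 s, voluntary movements are
never counted as seizures).  Times are seconds from recording start; all
analysis re-expresses time as minutes relative to the treatment of record
(t = 0 at administration), because every window in the analysis is defined
around treatment.

Bundles are stored as plain text — ECoG as TSV (one row per sample, 17
mantissa digits, which round-trips IEEE doubles exactly, so
write∘read∘write is byte-identical), events as TSV, timeline and grid
descriptors as JSON.  Plain text was chosen for portability and exact
reproducibility of the round trip; EDF input is supported read-only through
`mne` (optional `edf` extra).

## Seizure amplitude

* Filters: Butterworth high-pass, 1 Hz corner, order 10; Butterworth
  band-stop 48–52 Hz, order 20 (band filters of order 2N are designed from
  N analogue poles, so `scipy.signal.butter(10, ..., "bandstop")`).  Both
  are applied zero-phase (forward–backward), which doubles the effective
  order; reflection padding is extended to 3 s because the 1-Hz stage rings
  for seconds.  The family is Butterworth — only corner and order are
  prescribed by the quantification being reproduced; Butterworth is the
  standard offline choice.
* Binning: bin k covers [k, k+1) min; the t = 0 bin belongs to the
  post-treatment period.  Pre-treatment span −15..0 min; post 0..60 min for
  DCZ and 0..15 min for vehicle (clipped to the recording).  Both the
  baseline window and the channel aggregation (mean over valid contacts of
  the injected hemisphere by default; median or a single contact by
  argument) are configurable because the aggregation is not uniquely
  determined by the definition of the measure.
* Normalization: values divided by the baseline-window mean, so the
  baseline mean of every normalized series is 1 (enforced to 1e−9 in
  tests).  Degenerate baselines (mean ≤ 0, e.g. an all-zero convulsion
  rate) are a hard error rather than a silent NaN.
* Significance: a bin deviates when it crosses the 95th percentile of the
  baseline-window normalized values.  Percentile convention: linear
  interpolation between order statistics (numpy default), verified against
  an independent sort-and-interpolate oracle.  The criterion is applied
  per-session; a cross-session mean series can be fed through the same
  functions.  Suppression onset is the start of the final run of
  below-threshold bins that persists to the end of the evaluation window,
  restricted to t ≥ 0.
* Display scaling (division by the max |value| over −15..12 min) is
  presentation-only; the percentile threshold is scaled together with the
  values, so deviation calls are invariant to it.
* Spectrograms: short-time Fourier transform, 1-s Hann window, 50 %
  overlap (unconstrained by the quantification; standard for 1–500 Hz
  content), each frequency row divided by its mean over a stated baseline
  window, reported as a power ratio (dB on request).

## Convulsion rate

Events of the requested categories are counted in the same 1-min bins,
smoothed with a 5-bin centered moving average stepped by one bin, then
normalized and thresholded identically to the amplitude series (shared
implementation).  Edge bins use the shrunken window by default (dropping
them is available by flag); smoothing precedes normalization.
Contralateral/ipsilateral is resolved against the DREADD hemisphere in the
timeline.

## Spatial spread

Amplitude maps are per-contact RMS of the raw signal over a window
(filtering optional).  Threshold maps use an inclusive cut
(value ≥ fraction × peak), peak ties broken by lowest contact index, and
coverage is reported as members/valid with the integer percent rounded half
away from zero — the convention that reproduces 9/63 → 14 % and
13/63 → 21 % exactly.  Half-maximum membership is nested inside
one-third-maximum membership by construction, and coverage is invariant to
uniform rescaling.  Physical-area reporting is out of scope: only channel
counts and fractions are produced.

## Treatment-effect model

Observation model per session s and bin t of the normalized series,
y = ŷ + u·d_M + v·d_T + ε, ε ~ Normal(0, σ²), with u = −1/+1 coding
exactly two subjects (more is a design error), v = 0/1 coding
vehicle/DCZ.  Process models: the basic trend ŷ follows a second-order
random walk (its increment is a Normal random walk with scale σ_y); the
treatment effect d_T follows a Cauchy random walk with scale σ_T; the
subject effect d_M is a single Normal(0, σ_M²) scalar.  Missing cells are
allowed; each session must contribute at least one observed pre- and
post-treatment bin.

Design choices the model statement leaves open:

* **Cauchy dispersion slot.** The walk's dispersion is written in the same
  notational slot as the Normal variances; it is read here as the Cauchy
  *scale* σ_T (mirroring how σ² denotes the Normal family's dispersion),
  with a `cauchy_square_scale` flag to use σ_T² instead.
* **d_T support.** d_T is defined over the whole bin grid with no hard
  zero constraint pre-treatment; the data identify its pre-treatment level,
  and pre-treatment intervals of ŷ + v·d_T are well defined.
* **Priors** (not prescribed): half-Cauchy(0, 2.5) on σ, σ_M, σ_y, σ_T;
  diffuse Normal(0, 10²) on ŷ at the first two bins and d_T at the first
  bin.  All configurable.
* **One joint fit** across both subjects and both treatment groups per
  outcome (amplitude and convulsion rate fitted separately), since the
  observation model contains u and v jointly.

### Inference

Gibbs sampler.  Each Cauchy increment is written as a Student-t(ν = 1)
scale mixture: Δd_T | λ ~ Normal(0, σ_T²/λ), λ ~ Gamma(½, ½).  Conditional
on the scales and λ, the latent block (ŷ, d_M, d_T) is jointly Gaussian
with banded-plus-rank-structure precision; it is drawn exactly in one shot
via dense Cholesky factorization (dimension 2T+1 ≈ 63, microseconds).  The
λ update is conjugate (Gamma(1, ½ + Δ²/2σ_T²)); the four scales are
updated by univariate slice sampling on the log scale.  Defaults: 4 chains
× 1000 post-warmup draws after 500 warmup iterations; split-R̂ (via arviz)
is computed for the scales and the reported window effects and warns above
1.05.  Every fit is a pure function of (data, priors, sampler config,
seed).

The MAP estimate is the stored draw maximizing the joint log posterior
(with the Cauchy terms evaluated exactly, mixing variables marginalized);
optional local refinement by Nelder–Mead is available, since "posterior
mode" is not otherwise algorithmically pinned down.  The joint density
itself is unit-tested term by term against an independently coded oracle at
1e−8.

### Evaluation

Per treatment group, the posterior draws of the window mean of ŷ + v·d_T
over the pre window [−3, 0) and post window [0, 3) (bins {−3,−2,−1} and
{0,1,2} under the half-open convention, t = 0 post) are summarized as the
MAP point and the central 99 % credible interval.  A treatment effect is
declared when the DCZ and vehicle post-treatment intervals are disjoint;
touching endpoints count as overlap.  Observed per-session window means are
reported alongside as descriptive points.

## Synthetic-data generator

The generator emulates the *statistical structure* the analysis assumes —
it is not a biophysical model:

* Phase schedule: baseline → spikes → spike-wave complexes →
  multi-spike-wave complexes → status epilepticus, contiguous and
  baseline-first.  Default session: 40 min, bicuculline at 4 min, treatment
  at 25 min (15 pre-treatment and 15 post-treatment whole-minute bins).
* Waveforms: 70-ms biphasic spike; spike-wave complex adds a ~330-ms slow
  wave (≈3-Hz complex rate); multi-spike-wave complexes carry 2–4 spikes;
  status epilepticus is a sustained ~3-Hz train.  Stylized electro-clinical
  shapes with config-exposed amplitudes and rates; no waveform constants
  are prescribed by the phenomena being emulated, so all are package
  choices.
* Background: per-channel independent 1/f ("pink") noise, 15 µV RMS —
  the conventional EEG surrogate.
* Spatial profile: Gaussian in grid distance from a focal contact, width
  per phase (non-decreasing with severity; an ∞ sentinel flattens it over
  the array).  Defaults are set so the half-maximum maps progress
  9 → 13 → 63 of 63 valid contacts across spikes → multi-spike-wave →
  status.
* Treatment: in DCZ sessions the epileptiform amplitude decays after a
  1-min latency with a 0.5-min time constant toward (1 − s) of its
  untreated level (default suppression fraction s = 0.85), and the spatial
  width simultaneously retracts toward the focal width, emulating the
  collapse of a spread discharge back to focal residual spikes.  Convulsion
  rates use a step: ×(1 − s) after the latency.  Vehicle sessions are
  untouched, and the random stream is consumed identically for both labels,
  so s = 0 makes DCZ- and vehicle-labelled outputs sample-identical.
* Events: independent inhomogeneous Poisson processes per category
  (thinning), phase-dependent rates that rise with severity; tremor
  durations 2 + Exp(2) s.
* Subjects: two, with opposite-signed effects implemented as a linear
  amplitude tilt (zero-mean over the pre-treatment window, so
  normalization is unaffected; post-treatment normalized levels carry the
  subject-signed offset, the structure the u·d_M term models).  One
  subject's seizure trends upward pre-treatment, the other downward.
* Cohort: 2 subjects × (3 DCZ + 2 vehicle) = 6 DCZ + 4 vehicle sessions;
  per-session seeds derive from (master seed, subject index, session
  index) via `numpy.random.SeedSequence`.

The default simulation sample rate is 250 Hz (hardware-grade 3 kHz is
supported via `sample_rate_hz`): every downstream metric — binned RMS,
normalization, spread fractions, event rates — is invariant to sampling
rate, and 250 Hz keeps a full cohort in memory comfortably.  Test fixtures
scale further down (120 Hz, 16-min sessions) for the same reason; these
sizes are the package's own choices and are stated here so results can be
regenerated at any scale.

What the generator does **not** emulate: realistic waveform morphology
variability, artifacts and electrode drift, inter-channel correlated noise,
spontaneous seizure recurrence after treatment, observer noise in event
scoring, and pharmacokinetics beyond the single latency/time-constant
envelope.  Passing tests therefore demonstrate correctness of the analysis
chain under the assumed structure, not robustness to real-data pathologies.

## Problem sizes and studies

The acceptance script (`scripts/acceptance.py`) runs: the three spread
worked examples; a 50-draw density-oracle comparison; 50 parameter-recovery
replicates at 2 subjects × 10 sessions × 31 bins (σ = 0.05, σ_y = 0.05,
σ_T = 0.1, σ_M = 0.2, step d_T = −0.7) with reduced-size fits (2 chains ×
300 draws); 20 null-calibration replicates (d_T ≡ 0); the filter and RMS
analytics; and one end-to-end pipeline run on the default cohort.  These
replicate counts and fit sizes are the package's standard study sizes; the
same studies can be scaled up through the function arguments.

## Known limitations

* The subject coding is defined for exactly two subjects; larger cohorts
  need a different random-effects structure (deliberately out of scope).
* The Gibbs sampler assumes at least three bins for the trend walk to be
  informative; with very short grids the trend is prior-dominated.
* u·d_M is identifiable only as a product (sign symmetry); reported
  quantities (ŷ + v·d_T) are invariant to the ambiguity.
* The interval-separation decision is a fixed rule, not a calibrated test;
  its false-positive behaviour under the null is characterized empirically
  in the acceptance suite rather than analytically.
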