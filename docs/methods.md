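# Methods

## Scope

`mitocal` quantifies three readouts of excitation-driven mitochondrial
remodelling in cultured myotubes and the statistics used to compare
experimental groups:

1. **Caffeine-evoked calcium-transient kinetics** from single-cell Fluo-4
   fluorescence traces: onset latency ("caffeine response time"), time to
   peak, amplitude, maximal rise rate (ΔF/ΔT), and the 25/50/90 % clearance
   times (t25/t50/t90) with right-censoring.
2. **Mitochondrial morphometry and SR contacts**: per-mitochondrion 2-D
   size (length × width), a fused/fragmented network classification, and
   the frequency of SR–mitochondrion contact sites.
3. **Line-scan colocalization** of a mitochondrial and an SR/ER marker
   channel, summarised by the Pearson correlation of the two profiles.

No raw recordings accompany the study this pipeline operationalizes, so a
synthetic-data layer generates traces, EM-style measurement tables and
two-channel image fields with known ground truth; every downstream stage is
validated against that ground truth.

## Transient model

A transient is modelled as baseline → latency → linear rise → single-
exponential recovery:

F(t) = F₀ for t < t_on;  F₀ + s·(t − t_on) for t_on ≤ t < t_peak;
F₀ + A·exp(−(t − t_peak)/τ) for t ≥ t_peak,

with t_on = t_app + latency, t_peak = t_on + rise_duration and amplitude
A = s·rise_duration, plus additive homoscedastic Gaussian noise. The shape
was chosen because it makes every reported metric analytic: ΔF/ΔT = s,
time-to-peak = rise_duration, and t_q = τ·ln(1/(1−q)), i.e.
t25 = τ·ln(4/3), t50 = τ·ln 2, t90 = τ·ln 10. Those closed forms are
emitted with each simulated trace and are the reference for all recovery
tests.

Defaults (configuration, not claims about any particular instrument):
sampling interval dt = 0.5 s, record length 400 s, stimulus application at
30 s. Group presets pin the model to published group means — e.g. the
control preset (latency 8 s, s = 70 fau/s, rise 8 s ⇒ A = 560 fau,
τ = 80/ln 2 s ⇒ t50 = 80 s) and the fission-blocked preset (14 s, 245
fau/s, 10 s ⇒ A = 2450 fau, τ = 114/ln 2 s). A single exponential cannot
simultaneously match independently printed t25/t50/t90 triples that are
not exponential-consistent; presets match amplitude, latency, time to
peak, ΔF/ΔT and t50, and the resulting t25/t90 follow from τ. Cohort
simulation adds between-cell lognormal variability (default CV 0.2) on
latency, slope, rise duration and τ.

### Metric extraction

- **Baseline**: mean ± sample SD over a pre-stimulus window (default 20 s).
- **Onset**: first time ≥ t_app at which F exceeds
  baseline + max(k·SD, floor) for 3 consecutive samples, k = 3. The
  absolute floor (default 1 fau) keeps the rule defined on noiseless
  traces where SD = 0. Response time is onset − t_app; a trace that never
  crosses is reported as a fully-flagged "no response" record, not an
  error.
- **Time to peak is measured from detected onset, not from application.**
  The published control values (response time 8 s, time to peak 8 s) and
  fission-blocked values (14 s, 10 s) are mutually consistent only as two
  separate legs.
- **Amplitude**: max post-onset F − baseline; ties broken earliest.
- **ΔF/ΔT**: centred moving-average smoothing (default 5 samples), central
  finite differences, maximum over [onset, peak]. Under noise the maximum
  of a noisy derivative is biased slightly high (measured ≈ +7 % at noise
  SD 1 % of A); the Monte-Carlo suite bounds the mean relative error at
  10 %.
- **Clearance**: t_q is the first post-peak time at which F falls to
  baseline + (1−q)·A, linearly interpolated between the bracketing
  samples. If the record ends first, the value is the remaining record
  length and a censored flag is set; group summaries exclude censored
  values and report the exclusion count. First-crossing detection is
  biased slightly early under noise (≈ −1 s at 1 % noise for τ = 60 s).
- No ΔF/F₀ normalisation: amplitudes stay in raw fau, as reported.

## Morphometry

- **2-D size = length × width.** On segmented images, length and width are
  the sides of the minimum-area enclosing rectangle of the object's pixel
  corners (longer side = length). Pixel corners, not centres, define the
  extent, so an axis-aligned a×b-pixel block measures exactly a×b; ellipse
  axes were rejected because they underestimate rod width. Rotation
  invariance holds to ~5 % (rasterization).
- **Segmentation**: Otsu threshold by default (fixed threshold available
  for reproducibility), 8-connected components, components below
  `min_area_px` (default 4) discarded. Blank images yield an empty list.
- **Fused classification**: a cell is fused when the largest object holds
  ≥ 50 % of total mitochondrial area or any object is ≥ 5 µm long; both
  thresholds are configurable and ties go to the lowest object id. The
  rule is this package's operationalization of what is usually a per-cell
  visual score.
- **SR contacts**: contact ⇔ SR distance ≤ d_max, default 30 nm — a
  typical MAM gap; the criterion used in published visual scoring is
  unstated, so d_max is a prominent knob. Frequency = contacts /
  mitochondria, counted per mitochondrion (the reading consistent with
  n = 50 per group). In image mode, distances come from the Euclidean
  distance transform of the SR mask sampled on each object's boundary
  pixels; in EM mode they are read from the object table (raw EM
  segmentation is out of scope).

## Colocalization

Line scans sample both channels by bilinear interpolation at unit-pixel
spacing along a user segment, averaging across integer perpendicular
offsets (`width_px`). The readout is Pearson r of the two profiles —
chosen over Manders coefficients because it needs no intensity threshold;
r is undefined (NaN) when either profile is flat.

## Statistics

- Two groups: unpaired two-tailed Student's t (pooled variance),
  df = n₁+n₂−2; Welch's form available behind a flag.
- ≥ 3 groups: one-way ANOVA.
- Binary outcomes (fused, contact): two-sided Fisher's exact test by the
  probability-mass rule (sum of hypergeometric probabilities ≤ the
  observed table's, small relative tie tolerance) — the convention of
  standard statistical software; other two-sided definitions exist.
  scipy.stats provides the implementations; tests verify them against a
  hand-rolled hypergeometric enumeration oracle on every 2×2 table with
  total ≤ 40, the ANOVA = t² identity, and a 2 000-replicate null
  calibration of the t-test's type-I error.
- Summaries are mean ± SE (sample SD/√n); a single observation reports
  SE = 0 with n = 1. Raw p-values only — no multiple-testing correction
  is applied, matching the reporting style the pipeline reproduces, and
  the report says so.
- The dispatcher's policy: boolean metric → Fisher (pairwise), two
  numeric groups → t-test, three or more → ANOVA.

## Synthetic image fields

Channel 1 renders non-overlapping rods (binary geometry, no
anti-aliasing, so ground truth is exact) with smooth within-rod
brightness structure; channel 2 is an SR texture (filtered random blobs)
whose intensity on mitochondrial pixels mixes the channel-1 signal with
an independent texture by `coloc_level`. A `contact_fraction` of rods get
an SR patch placed within contact distance; the rest keep an SR-free
exclusion zone. The generator emulates the proximity/intensity structure
the pipeline measures and nothing else: no point-spread function, no
photon (Poisson) noise, no out-of-focus light, no anisotropic pixel
sizes. Passing tests therefore demonstrate correctness of the
measurement code, not robustness to real microscope physics.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for interactive runs: 200-seed
Monte-Carlo recovery at noise SD 1 % of amplitude, 500-object morphometry
populations, 100 random grids for the distance oracle, 2 000 null
replicates for calibration, image fields ≤ 384². Determinism: every
stochastic routine takes an explicit integer seed (numpy
`default_rng`); identical parameters + seed give bit-identical outputs.
Degenerate inputs have defined behaviour throughout (empty foreground →
empty list; flat profile → NaN r; zero pooled variance → explicit error;
no response → flagged record).

## Known limitations

- The transient model has a sharp peak (kink), unlike dye-filtered real
  transients; amplitude estimates on real data would carry dye-kinetics
  bias the tests cannot reveal.
- The onset rule is an operationalization; hand-scored latencies in the
  literature may differ systematically by a few samples.
- Morphometry is strictly 2-D profile-based; no skeleton/topology
  metrics, no 3-D reconstruction, no time-lapse tracking.
- The EM mode trusts the measurement table; it does not segment
  micrographs.
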