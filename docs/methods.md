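# Methods

## Signal model and quantification

A recording is a video of fluorescence frames acquired at rate *f_s* while a
periodic uniform-field stimulus of frequency *f₁* (default 0.2 Hz, square
wave, 50 % duty) is presented. The analysis is stimulus-locked harmonic
extraction, as used throughout visual electrophysiology:

1. The time course (per pixel, or averaged over an ROI) is truncated to the
   largest whole number of stimulus cycles starting at the stimulus onset
   frame. With whole-cycle truncation the stimulus frequency falls exactly
   on a DFT bin, so no window function is needed and there is no leakage
   from the response into neighbouring bins.
2. **F0** is the mean of the truncated trace. **F1** is the amplitude of the
   DFT coefficient at the stimulus bin in the convention 2|X_k|/N: a pure
   cosine of amplitude *a* returns F1 = *a*. The **normalized response** is
   F1/F0, a unitless modulation depth; pixels or cells with F0 ≤ 0 are
   flagged invalid rather than propagating infinities.
3. **Phase** is the complex argument of X_k in (−π, π], measured from the
   analyzed segment's start (= stimulus onset). A cosine peaking at the
   light-on edge reports phase 0. For the square-wave stimulus the drive's
   own fundamental sits at −π/2 (sine-like), and the slow indicator adds a
   further lag (≈1.15 rad for the default kinetics at 0.2 Hz), so ON cells
   report phase ≈ −2.7 rad and OFF cells sit exactly π away. No lag
   compensation is applied: every downstream decision uses phase
   *differences* or an explicitly computed reference, never raw absolute
   phase.

### Noise floor and significance

The measurement floor is estimated per cell from the same record: the mean
and SD (n−1 denominator) of the amplitude spectrum (same 2|X|/N convention)
over a band far above the stimulus, 10–12 Hz by default. The band must
contain at least 3 DFT bins, which sets a minimum record length
(≥ 1.5 s × bins needed at 25 Hz; the default analyses use 15–120 s records
giving 31–241 bins). A cell is significant when F1 strictly exceeds
mean + 3·SD of the band amplitudes. Equality does not count; the boundary
case matters only at measure zero but the rule is documented as strict.

Under pure white Gaussian noise every amplitude bin is Rayleigh distributed,
so the criterion's false-positive rate has the closed form
exp(−(√(π/2) + 3√((4−π)/2))²/2) ≈ 0.0056 when the floor is known exactly.
Estimating the floor from finitely many band bins inflates this slightly
(the threshold is itself noisy); with ≥ 200 band bins the Monte-Carlo rate
stays within 3 standard errors of the closed form at 10,000 cells, which is
what the acceptance script verifies.

A subtlety worth knowing: a square-wave response's high odd harmonics land
in any fixed noise band (10.2, 10.6, … Hz), so even a noiseless responsive
cell has a tiny nonzero "noise" floor. The effect is ~10⁻² of F1 for the
default kinetics and never changes a significance call, but exact-zero
assertions on the floor are wrong by construction.

### Circular statistics and polarity

Phase uniformity across a population is tested with the Rayleigh test:
z = n·r² with r the mean resultant length, p by the large-sample
approximation p = exp(√(1+4n+4(n²−R²)) − (1+2n)) clamped to [0, 1] (Zar's
formula; the Monte-Carlo calibration in the tests confirms the rejection
rate at α = 0.01 is 0.01 ± 0.01 for n = 100). Rayleigh reporting in
population summaries uses significant cells only and α = 0.01.

ON/OFF polarity is a quadrant rule: a cell is ON if its phase lies within
π/2 of the ON reference phase, OFF if within π/2 of the reference + π, else
unclassified. The reference can be supplied, estimated from the data, or
computed from the model. The data-driven estimate uses the doubled-angle
resultant: the ON/OFF axis is ½·arg Σe^{2iφ}, which is insensitive to the
antiphase split that makes the plain circular mean cancel; the pole carrying
more cells is taken as ON. With a balanced ON/OFF mixture that choice is
inherently ambiguous, so the pipeline instead anchors the label physically:
`expected_on_phase` synthesizes a noiseless indicator-filtered ON response
to the configured stimulus and analyzes it identically, and that phase is
the ON reference. The clustering itself never depends on the anchor — only
which cluster gets which name.

## Synthetic imaging model

The generator emulates ganglion-cell-layer calcium imaging well enough to
exercise every analysis stage against known ground truth:

- **Field**: default 215 × 160 px at 1 μm/px (a 160 × 215 μm field); somata
  are disks with radii drawn from N(8, 2) μm clipped to [5, 15] μm
  (diameters ~10–30 μm), placed by rejection sampling with minimum center
  spacing 1.5 × mean radius (configurable; larger factors give
  well-separated fields). Placement failure raises an error naming the
  achieved count. Each soma has a darkened nucleus (inner 40 % of the
  radius rendered at 40 % intensity) over a flat background of 20
  fluorescence units; baselines are drawn uniformly from 80–120.
- **Responses**: each cell is ON, OFF, or unresponsive (default mix
  0.4/0.4/0.2). The drive is ±(a/2) times the stimulus square wave
  (a = response amplitude, peak-to-trough as a fraction of baseline,
  default 0.3–0.8), OFF cells in antiphase, filtered by the indicator
  kernel; fluorescence = baseline × (1 + filtered modulation).
- **Indicator kinetics**: difference of exponentials
  exp(−t/τ_decay) − exp(−t/τ_rise) with defaults τ_rise = 0.2 s,
  τ_decay = 1.5 s — chosen so the 0.2 Hz square wave is visibly low-pass
  filtered, as slow calcium indicators do; both constants are
  config-exposed. The public `indicator_response` normalizes the kernel to
  unit peak (the natural convention for impulse responses); the renderer
  uses the same kernel normalized to unit DC gain so a cell's realized
  modulation depth stays ≈ its nominal amplitude. The residual attenuation
  of the fundamental at 0.2 Hz makes the realized F1/F0 ≈ 0.286 × a; cohort
  generators invert this gain (measured on a noiseless unit trace, never
  assumed) when a target F1/F0 distribution is prescribed.
- **Noise**: additive per-pixel Gaussian, SD configurable. This suffices for
  testing the Rayleigh-amplitude null; it does not model photon shot noise's
  intensity dependence, detector nonlinearity, or photobleaching.
- **Motion**: an integer-step random walk per frame (step SD `jitter_sd`,
  reflecting boundary at `max_excursion`), applied by whole-pixel shifts
  with edge replication. `jitter_sd = 0` yields an exactly zero trajectory.
- **Frame rate**: default 25 Hz. The rate must exceed 24 Hz so the 10–12 Hz
  noise band lies below Nyquist.
- An optional multiplicative ramp on the first frames emulates first-trial
  adaptation after light onset; off by default.

What passing tests on this generator do **not** show: robustness to
intra-frame (scan-strip) distortion, non-rigid tissue motion, vascular
shadowing, indicator expression heterogeneity, or non-Gaussian noise. Those
belong to real-data validation.

## Registration

Per-frame translation is estimated by phase cross-correlation against a
reference (default: mean of the first 10 frames; alternatively the first
frame or any index), with subpixel precision 1/upsample. Correction
translates each frame by the negated displacement using bilinear
interpolation (exact for integer shifts) with edge-replicate or zero fill.
Translations only — no rotation, shear, or intra-frame correction; over a
~200 μm field frame-wise translation is the dominant component, and the
limitation is deliberate. When a co-registered reflectance channel is
present the pipeline estimates shifts on it and applies them to the
fluorescence channel. A constant (zero-contrast) stack returns zero shifts
with a degenerate flag rather than undefined correlations.

## Segmentation and tracking

Manual label masks are first-class input. The automated segmenter exists so
unattended end-to-end runs are possible; it uses the same cues a human
would: a composite of the normalized SUM image and the normalized F1
amplitude map (weight 1.0) is grey-closed with a 4 px disk (filling the
nucleus dip so each soma is one blob), Gaussian-smoothed (σ 1.5 px),
thresholded by Otsu for support, seeded by local maxima (min separation
8 px) and grown by watershed, keeping regions of 12–1200 px. Candidates
whose internal phase is incoherent (amplitude-weighted circular SD > 1 rad)
*and* coherent at the doubled angle (resultant > 0.5 — the signature of two
antiphase sub-populations rather than noise) are split along the dominant
phase axis: two fused somata of opposite polarity separate cleanly because
their phases differ by half a cycle. Mask validation drops ROIs below 4 px
and relabels to consecutive ids, reporting the mapping.

Cross-session tracking matches cell centroids between two visits by greedy
closest-first mutual exclusion after a rigid between-session translation
(estimated by registering the two SUM images when not supplied), rejecting
pairs beyond 5 μm. On soma mosaics (centers ≥ one diameter apart) this
agrees with optimal assignment ≥ 95 % of the time at 1 px centroid jitter;
the greedy rule is preferred for its transparency.

## Dosimetry

Retinal irradiance = pupil power / retinal patch area, with visual angle
converted to retinal distance by a magnification constant. Two mouse
conventions are exposed because they are mutually inconsistent and both are
in use: 34.4 μm/deg (the value under which 20 μW over an 8° patch gives
33.6 mW/cm²) and 32.0 μm/deg (the value equating a 5° scan to 160 μm).
Neither is silently preferred; `OpticalGeometry` makes the choice explicit
and results carry it as metadata. Cross-species equivalent power scales with
the squared numerical-aperture ratio (mouse 0.49, human 0.24 → ×4.168).
Expected cell counts are areal density × field area, reported exact and
rounded. The ANSI Z136 maximum permissible exposure at 620 nm for 8 h
(40 μW) is stored as a documented constant for report annotation, not
recomputed.

## Problem sizes and numerical choices

- Default analyses and tests run on 15–30 s records (375–750 frames at
  25 Hz, 3–6 stimulus cycles) over fields of 64²–256² px; calibration
  simulations use 120 s single-pixel records (241 noise-band bins).
- Noise-null calibration: 10,000 cells; Rayleigh calibration: 1,000
  replicates of n = 100; cohort recovery: n = 296 cells with generative
  F1/F0 ~ N(0.16, 0.08) clipped at 0.01 (the clip raises the cohort mean by
  ~0.003, well inside the recovery tolerance); polarity accuracy: 200 cells,
  response SNR (F1 / Rayleigh scale of the noise amplitude spectrum) ≈ 30.
- Whole-cycle truncation rounds the segment length to the nearest integer
  sample count; at 25 Hz / 0.2 Hz the cycle length (125 samples) is exact.
- The stimulus bin is the DFT bin nearest the stimulus frequency — exact
  under whole-cycle truncation.
- Ties and degenerate inputs: empty fields and empty masks are legal and
  produce empty outputs; a single-cell population reports SD 0 with its
  n = 1 visible; Rayleigh p is clamped to [0, 1]; all-constant videos
  register as degenerate with zero shifts.
- Determinism: every stochastic component takes an explicit seed;
  identical configuration and seed reproduce byte-identical outputs.

## Known limitations

- Frame-level rigid registration cannot correct within-frame scan
  distortion; residual strip artifacts in real raster-scanned data will
  inflate the noise floor.
- The F1-only analysis ignores response harmonics and transients; strongly
  nonlinear or adapting responses are summarized only by their fundamental.
- Per-trial versus concatenated analysis is configurable
  (`exclude_first_trial`, `frames_per_trial`), but no trend or mixed-effects
  modelling across trials or sessions is provided — population summaries are
  descriptive.
- The automated segmenter is tuned for the synthetic renderer's contrast;
  on real data its parameters (smoothing, closing radius, area bounds) are
  starting points, and manual masks remain the reference procedure.
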