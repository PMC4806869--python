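# Methods

This note records the scientific model behind `eitroi`, the parameters
that matter, the design choices made where the problem left the design
open, and what the synthetic phantom does and does not establish.

## The ΔZ image

A low-flow inflation maneuver is summarised per pixel by a signed
max–min value.  The magnitude is the difference between the temporal
maximum and minimum of the pixel's relative-impedance trace.  The sign
is taken from the covariance of the trace with the global signal (the
mean trace over the valid region): pixels whose impedance falls while
the lung inflates — mediastinal tissue, heart-adjacent regions — come
out negative, as out-of-phase pixels do in clinical max–min images.
Both magnitude and sign are invariant to frame reordering and to adding
a constant to every frame; `signed=False` gives the plain nonnegative
max–min.  No baseline renormalisation is applied: the input is assumed
to be reconstructed relative impedance change.

The valid image region is the quasi-circular 912-pixel subset of the
32×32 grid.  The device's exact pixel set is not public, so the package
constructs a deterministic stand-in: include every pixel whose center
lies within the smallest radius admitting at least 912 pixels, then
trim boundary-ring pixels — left/right mirror pairs together, ordered
by polar angle — until exactly 912 remain.  The result is left–right
symmetric by construction, which mirroring requires.  A device-specific
mask can be supplied as a 0/1 CSV instead.

## ROI definitions

With ΔZ_lung the valid-pixel values,

```
ΔZ_max = max(ΔZ_lung) − min(ΔZ_lung)
cutoff(t) = ΔZ_max · t + min(ΔZ_lung),   t ∈ [0, 1]
```

the fROI keeps pixels with ΔZ strictly above the cutoff.  Anchoring at
the true minimum matters: negative out-of-phase pixels shift the whole
cutoff scale downward, and a cutoff measured from zero would discard
far more pixels at the same nominal threshold.  Strict inequalities are
used both here and at the cardiac 50% rule; with continuous-valued
images the choice is immaterial, but it makes the degenerate t = 1 case
unambiguous (empty ROI).

The LAEM mirrors the fROI left–right by Boolean OR and subtracts the
cardiac area; fROI-heart subtracts the cardiac area without mirroring.
The cardiac area is computed from all valid pixels (not only within the
fROI), so it is the same set for every threshold of a given subject.

## Cardiac-area detection

Each pixel trace is band-pass filtered by zeroing every discrete
Fourier component outside [(1−b)·f_heart, (1+b)·f_heart], b = 0.20, and
the filtered trace's peak-to-peak excursion is compared across pixels;
pixels above 50% of the maximum are cardiac.  An RMS amplitude metric
is available (`CardiacParams(metric="rms")`).

Before the DFT, the line through the trace's first and last samples is
removed, then the mean.  This endpoint-anchored detrend is load-bearing:
a maneuver trace is a monotonic ramp, and the DFT's implicit periodic
extension turns its end-to-start jump into broadband 1/f leakage that
would otherwise dwarf the cardiac band in strongly ventilated pixels
(≈ 26% of the ramp excursion leaks with plain mean removal, ≈ 0.03%
after the endpoint detrend; an in-band tone is perturbed by ≈ 1% when
the record holds an integer number of cardiac cycles).  Rectangular
spectral zeroing of a finite record has inherent edge ringing: for
pathological record lengths (half-integer cycle counts) the recovered
peak-to-peak can deviate by up to ~15–19%.  The detection threshold is
relative, and all pixels of a subject share the same record length and
frequency, so this bias largely cancels across pixels; recordings
shorter than three cardiac periods trigger a warning.

The heart rate comes from subject metadata; spectral peak detection is
out of scope.  The passband must stay below Nyquist
(1.2 · f_heart < sample_rate/2 is enforced at construction).

## Inhomogeneity indices

GI = Σ|ΔZ_xy − median(ΔZ_lung)| / Σ ΔZ_xy over the ROI; the median of
an even pixel count is the mean of the two central order statistics.
CV = sample SD / mean (ddof = 1 by default, matching common desktop
statistics packages; ddof = 0 available).  Negative pixels enter both
formulas exactly as written — no clipping — so the denominators can
vanish; such cells raise typed errors and the pipeline records them as
flagged missing cells with the exclusion count reported downstream,
since there is no principled sentinel value for an undefined index.

## Group discrimination

The AUC is the Mann–Whitney estimator computed from midranks (ties
credited 0.5), with ARDS the positive class and scores used as-is.  Its
95% CI uses the Hanley–McNeil standard error

```
SE² = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)] / (n₊ n₋),
Q₁ = A/(2−A),  Q₂ = 2A²/(1+A)
```

with a normal quantile, clipped to [0, 1]; a seeded percentile
bootstrap (2,000 resamples) is available as `ci_method="bootstrap"`.
The p-value is the two-sided normal approximation to the Mann–Whitney U
with tie and continuity corrections; when the tie-corrected variance
vanishes (all scores equal) it is 1 by convention.  ROI pixel counts
are compared between groups with Student's pooled-variance two-sided
t-test (Welch available).  No multiple-testing correction is applied
across the 19-threshold sweep; the sweep is descriptive, not
confirmatory.

## The synthetic phantom

The generator emulates what the analysis assumes about a low-flow
maneuver cohort, not thoracic electrophysiology.  Each subject is

```
frames(t) = scale · [ amp_field · ramp(t) + cardiac(t) ] + baseline + noise
```

* **ramp** — raised-cosine monotonic inflation over 30 s at 25 frames/s
  (quasi-static maneuver; the analysis only consumes per-pixel extrema
  and cardiac-band content, so respiratory mechanics are not modelled);
* **amp_field** — two elliptical lungs filling most of the 912-pixel
  region (semi-axes ≈ 14 × 8 pixels, centers ±7.2 columns off the
  midline), with a plateau profile 1 − ρ⁸ — clinical ventilation maps
  are closer to a plateau with steep margins than to a peaked bump, and
  a plateau is what makes the GI median sit inside the ventilated range
  so that hypoventilation registers.  Per-subject anatomical
  variability in both groups: size jitter (×0.85–1.1), center-row
  jitter (±1.5 px), lateral peak imbalance (weaker lung ×0.75–1.0), a
  dorsoventral gradient (±30%) and a smooth multiplicative log-texture
  (SD 0.15).  Everything is blurred with a Gaussian point-spread
  (σ = 2 px) emulating the heavy spatial smoothing of EIT difference
  reconstructions;
* **disease (ARDS only, `defects_enabled`)** — a diffuse one-sided
  aeration-loss texture (log-SD 0.40, reductions only: injury removes
  aeration, never adds it) plus 1–3 focal patches (radius 3.5–7 px,
  attenuation ~ U(0, 0.4), 85% on one randomly chosen side, biased
  dorsally).  Both components are gated together so that disabling them
  makes the two groups exchangeable;
* **scale** — respiratory-system compliance drawn from N(57, 20²)
  (ARDS) or N(88, 17²) ml/mbar (control), normalised by the control
  mean.  GI, CV and all mask definitions are scale-invariant, so the
  compliance difference carries no group information by itself — it
  exists so that absolute ΔZ levels differ realistically between
  subjects;
* **cardiac** — a ventral-central patch (radius 2.8 px, slightly
  subject-left) oscillating at a heart rate drawn from U(60, 100)/min,
  sine amplitude 20% of the mean lung amplitude;
* **out-of-phase pixels** — 10% of the pixels in the shell just outside
  the lung boundary get inverted-sign ventilation at 15% of peak
  amplitude (at least one per subject, guaranteed inside the valid
  region), producing the negative ΔZ values the cutoff formula is
  sensitive to;
* **noise** — white per-frame Gaussian noise, SD 1% of the subject's
  peak amplitude, spatially correlated with the same point-spread.
  Per-pixel max–min over 750 frames amplifies a white floor roughly
  sevenfold, so this corresponds to an image-domain noise floor near 7%
  of peak ΔZ; a higher per-frame noise level buries the
  hypoventilation contrast between the groups under the extreme-value
  floor.

All draws descend from one `SeedSequence`, with per-subject spawned
children, so cohorts are bit-reproducible.

What passing tests on this phantom show: that the analysis chain —
cutoffs, mirroring, cardiac subtraction, indices, ranking statistics —
behaves as the method intends under controlled conditions, including
the qualitative ordering (mirroring re-includes silenced regions, so
LAEM discriminates best at mid thresholds while the plain fROI decays).
What they do not show: performance on real reconstructions, whose
artefacts (electrode errors, reconstruction nonlinearity, cardiac
harmonics, posture) the phantom does not contain.  The phantom's
near-perfect LAEM AUCs (~0.95–1.0) are cleaner than anything clinical
data would give; only the ordering and shape of the curves, not their
levels, are meaningful.

## Problem sizes and determinism

The default study analyses 36 subjects × 750 frames × 1,024 pixels and
completes in a few seconds on one CPU; the test suite and the
acceptance script run the full cohort (plus a disease-free negative
control) at that size.  Reports are written with fixed float formatting
(`%.10g`), so identical cohort, configuration and seed reproduce every
CSV byte for byte.

## Known limitations

* The 912-pixel mask is a shape-plausible stand-in; the device's true
  pixel set may differ (supply it via CSV if known).
* The signed max–min image assigns a sign per pixel from its covariance
  with the global signal; pixels with genuinely biphasic traces get the
  sign of their dominant phase.
* Cardiac-band detection assumes a metadata heart rate and at least
  ~3 cardiac periods of recording; cardiac harmonics outside the ±20%
  band are ignored.
* The Hanley–McNeil CI is a normal approximation; at n = 24/12 with
  AUCs near 1 it clips at the boundary.  The bootstrap option is
  preferable near the extremes.
* A relative cardiac threshold on a recording with no cardiac activity
  selects whatever residual band energy is largest; the mask is empty
  only when the band is exactly silent.
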