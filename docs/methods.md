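# Methods

## Model and conventions

A subject's input is one cardiac cycle of LV cavity volume, sampled once
per cine phase from the R-wave trigger (frame 0 = end-diastole, times in
ms, volumes in mL). The cycle is treated as periodic: differentiation
uses central differences with cyclic wrap, so frames 0 and N−1 take each
other as neighbours shifted by one R-R interval. Rates are converted to
mL/s exactly once, at the differentiation boundary. Temporal resolution
is R-R interval / number of phases.

End-systole is the frame of minimum volume, earliest frame on ties. The
E wave is the value at the first local maximum of the rate after ES
(local maximum: a sample strictly above its predecessor and not below its
successor, so the first sample of a plateau wins); the A wave is the
first local maximum after the post-E trough, and its absence (fused
waves) propagates as missing values, never zeros. On a monotone
decreasing post-ES rate the first post-ES sample is used with a warning —
batch runs must not crash on degenerate curve shapes.

DT fits a least-squares line to the descending limb of the E lobe (peak
inclusive to the first subsequent local minimum exclusive, ≥ 2 samples)
and extrapolates it to the zero-rate baseline; a two-point chord variant
is exposed in the configuration because the reference software's fit
window convention is not published. DVR locates the first upward
crossing of ESV + 0.8·SV after ES by linear interpolation between the
bracketing frames; nearest-frame rounding would bias by up to half the
temporal resolution (±15 ms at 30 frames). When the threshold is crossed
inside a single-frame jump, the interpolated time lies strictly inside
that frame interval.

E′ is the maximum positive time-derivative of the apex-to-annulus
distance inside the early-diastolic window, computed with the same
central-difference code as the volume curves. The window runs from ES to
ES + 0.6·(R-R − ES), truncated at the detected A-wave onset; the fraction
is a declared convention (the early window has no published definition
for this measurement), chosen to exclude atrial-phase lengthening so that
E′ remains a correlate of the tissue-Doppler e′. The CMR E/E′ keeps
units mL/mm. The mean E/E′ defaults to the mean of the two site ratios;
the echo grading ratio defaults to E over the mean e′ ("average E over
average e′"); both alternatives are switchable in `AnalysisConfig`.

Grading thresholds are strict as recommended (septal e′ < 8 cm/s,
lateral e′ < 10 cm/s, mean E/e′ ≥ 10; LVMi > 115 / > 95 g/m²). LVH can
promote one criterion to type I but never past the all-three rule. The
> 15 bpm heart-rate difference between modalities is a reported
exclusion, not a silent drop.

## Statistics

- ANOVA accepts raw groups or n/mean/SD summaries; the summary form uses
  SSB = Σnᵢ(mᵢ−m̄)², SSW = Σ(nᵢ−1)sᵢ², which equals the raw-data
  decomposition identically, not approximately.
- Fisher r×c is the Freeman–Halton extension with probability ordering
  (sum of probabilities of margin-consistent tables not exceeding the
  observed table's, relative tie tolerance 1e-7), exact log-factorial
  arithmetic, and a seeded Monte-Carlo fallback for tables too large to
  enumerate. It matches R's `fisher.test` to 7 digits on the tables in
  the test suite.
- ROC AUC is the rank statistic U/(n₁n₀) with ties counted one half; the
  p-value is the two-sided normal approximation with tie-corrected
  variance. Bands: poor [0.5, 0.7), good [0.7, 0.9), excellent [0.9, 1].
- ICC is fixed to the single-measure absolute-agreement two-way random
  form, ICC(2,1) = (MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n), because the
  study design ("two-way random model") does not pin the variant further.
  Bands: poor < 0.40, fair-to-good 0.40–0.75, excellent > 0.75.
- Bland–Altman: bias ± 1.96·SD of the paired differences, applied only to
  same-unit pairs (for CMR-vs-echo that is the dimensionless E/A only).
- The modality comparison of the diastolic time intervals (TPE, RTPA,
  R-R) uses a paired t-test: subjects are measured same-day on both
  modalities, and the comparison the design calls for is paired.
- p-values are displayed with two decimals above 0.01, four below, and a
  "<0.0001" floor; 0.05 is reported as the significance threshold but
  never used to filter data.

## Synthetic data

**Waveforms.** The continuous filling-rate model is a sum of
raised-cosine lobes: a negative ejection lobe ending exactly at the
declared end-systole with area −SV, then an E lobe and an optional A
lobe. Raised cosines were chosen over Gaussians for compact support —
the baseline between waves is exactly zero, so peak amplitudes, peak
times, the DVR crossing (root of the closed-form cumulative volume) and
DT (the identical estimator on a 1 ms grid of the exact rate) are all
available as ground truth. Closure V(0) = V(RR) is exact because the
constructor requires the lobe areas to balance the stroke volume within
1 %. Gaussian volume noise is optional and off by default.

**Index-recovery study.** The recovery study draws 100+ parameter sets
and asserts that analysis of the 60-frame sampled curve recovers E and A
within 2 %, RTPE/RTPA within one frame, DVR within half a frame and DT
within one frame of the dense-grid value. Three geometric conditions
make these tolerances about the estimators rather than about sampling
physics, and they dictate the draw ranges (R-R 1710–1790 ms, ES at frame
20 of 60, lobe widths 520–560 ms, E 150–230 mL/s, A 100–180 mL/s):

1. *Lobe resolution.* A central difference at step h attenuates a
   raised-cosine lobe of width w by ≈ (2πh/w)²/12, and grid misalignment
   of the peak costs another ≈ (2πh/w)²/16. Keeping the worst-case peak
   error under 2 % at h ≤ 30 ms requires w ≳ 17h ≈ 510 ms.
2. *ES on the frame grid.* The ES estimator returns the argmin frame, so
   off-grid end-systole carries up to ±h/2 quantization that would alone
   exhaust the half-frame DVR tolerance; the study therefore places ES
   exactly on a frame.
3. *Non-overlapping lobes.* When the E and A lobes overlap, the post-E
   trough is elevated and the DT extrapolation to zero becomes long-range,
   amplifying window-endpoint quantization beyond one frame; a zero-rate
   diastasis between the lobes pins the fit.

These are slow-heart-rate, broad-wave cycles by construction. Passing
the study shows the extraction chain is correct and converges at the
expected order; it does not show that a 200 ms atrial wave sampled at
30 ms is recovered to 2 % — it cannot be, by (1), and on clinical-rate
curves the A-wave amplitude is underestimated by roughly (2πh/w)²/12
(≈ 7 % at w = 200 ms). The fused-wave and pathological branches are
covered by separate tests.

**Cohort.** `simulate_cohort` draws paired echo/CMR measurement records
from grade-conditional truncated normals (±3 SD and positivity) whose
default means/SDs are a published 102-subject reference cohort with
grade mix 64.7/20.6/14.7 %. The echo E/A ratio is formed from the drawn
E and A; the CMR E/A is then drawn conditionally with cross-modality
correlation r = 0.71, standardised by the exact quadrature moments of the
truncated-normal ratio (a delta-method SD underestimates the ratio's
spread and would inflate the realised correlation to ≈ 0.80). CMR A is
derived as E ÷ (E/A). All other cross-variable correlations default to
zero and are the main realism gap: ROC separations between CMR indices
and the echo-derived grade come out conservative relative to a real
cohort, because in reality the grade-defining echo variables and the CMR
indices are correlated within grade. Heart rates are drawn as echo HR
plus N(0, 3 bpm), emulating an already-enrolled cohort in which the
> 15 bpm exclusion is rare. Randomness flows from one seed through
per-subject `SeedSequence` substreams: cohorts are byte-reproducible and
prefix-stable under partial regeneration.

The type I (pseudonormal) group is intentionally hard: its E/A
distribution (1.01 ± 0.26 by CMR) sits below the normal group's
(1.10 ± 0.38), so grading generated records from measures alone recovers
the generating label imperfectly — the tests assert that confusion is
present and that the reduced group is recovered far more reliably.

## Numerical choices and degeneracies

- ES ties break to the earliest frame; plateaus in peak detection break
  to the first sample.
- Volume-conservation check: |∮ dV/dt dt| ≤ 1 % of SV warns (never
  raises) — real curves are noisy; synthetic noiseless curves satisfy it
  to machine precision because the cyclic trapezoid of central
  differences telescopes to zero.
- Mask-stack volumes use disc summation with pixel area × (slice
  thickness + gap); the digitized-ellipsoid test shows convergence to the
  analytic volume as pixels shrink, against the disc-summed reference
  (the axial discretization is a separate, fixed error floor).
- `fisher_exact_rxc` guards enumeration at 2·10⁶ tables and suggests the
  Monte-Carlo path beyond that.
- Identical paired series return t = 0, p = 1 rather than NaN.

## Problem sizes

The test suite and the acceptance script use 100–120 waveform draws,
cohort sizes of 200–10 000, and 1 ms dense grids for oracles; the full
suite runs in well under a minute on one CPU and the acceptance script in
a few seconds.

## Known limitations

- No image segmentation or 3-D model fitting: curves, mask stacks and
  guide-point tracks are inputs.
- The generator emulates measurement-level marginals, not full
  physiological covariance; agreement statistics on synthetic cohorts are
  conservative (see above) and reader-variability (ICC) studies require
  real duplicate readings.
- The early-diastolic window for E′ and the DT fit window are declared
  conventions, configurable but not validated against the reference
  implementation, which is not public.
- Narrow atrial waves at clinical frame rates are systematically
  attenuated by central differencing (quantified above); a higher-order
  or spline derivative was deliberately not used so that the estimator
  matches the stated convention and stays transparent on 30-frame curves.
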