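# Methods

`atriakit` re-implements the measurement-and-statistics side of an atrial
cine-CMR technique-comparison study as a tested pipeline over synthetic
data. This note documents the models, the parameters that matter, the
numerical choices, and what the passing tests do and do not establish about
real data.

## The time-volume curve model

One cardiac cycle of atrial volume is described by four control landmarks:
Vmin at the ECG trigger (the atrium has just contracted), Vmax at end
ventricular systole (reservoir full), a mid-diastolic minimum at diastasis
(end of passive emptying), and a mid-diastolic maximum just before atrial
contraction (pre-A volume). The generator joins the control points
(0, Vmin), (t_max, Vmax), (t_dia, Vdia), (t_preA, VpreA), (1, Vmin) with
cosine half-waves, so each segment is monotone with zero slope at every
control point. Two consequences drive the design:

* the landmarks are exactly recoverable — the interpolant's extrema *are*
  the control values; and
* a 25-phase sampling grid loses almost nothing at the extrema (the local
  quadratic behaviour at a zero-slope point makes the sampling error
  second-order), which is why noise-free landmark recovery is accurate to
  well under one percentage point.

Default cycle fractions are t_max = 0.40, t_dia = 0.70, t_preA = 0.88
(jittered per subject, SD 0.015–0.03), matching the physiological sequence
of ventricular systole, diastasis, and atrial contraction at typical heart
rates. Per-phase additive Gaussian noise (default SD 1 ml) emulates
segmentation variability between phases.

## Emptying fractions

From the landmarks:

    TEF = 100 (Vmax − Vmin) / Vmax            — total / reservoir
    PEF = 100 (Vmax − Vdia) / Vmax            — passive / conduit
    AEF = 100 (VpreA − Vmin) / VpreA          — active / booster

with emptying volumes TEV/PEV/AEV as the corresponding ml differences.
The landmark ordering implies PEF ≤ TEF and AEF ≤ TEF algebraically; the
test suite checks this on 10⁴ random quadruples. Note the structural
identity `1 − TEF/100 = (1 − PEF/100)(1 − AEF/100) · ρ` with the refill
ratio ρ = VpreA/Vdia ≥ 1: TEF is *determined* by PEF, AEF and the refill,
a coupling that matters for cohort calibration (below).

## Landmark detection

The detector anchors at the global maximum of a circularly smoothed copy of
the curve (moving average, default window 3 phases) and walks forward in
cyclic phase order: first local minimum → diastasis; first subsequent local
maximum → pre-A; global minimum of the remaining segment → Vmin. Volumes
are always read from the **unsmoothed** curve. Because smoothing averages a
landmark with unequal neighbouring slopes, the located phase can be dragged
one phase towards the gentler segment; each located phase is therefore
snapped to the unsmoothed extremum inside the smoothing half-window. With
this refinement, noise-free recovery error is pure sampling error (worst
case ≈ 1 percentage point over 200 random phenotypes; ≈ 0.2 points for
study-like ones).

Curves without an interior local extremum (no atrial kick — severe heart
failure, atrial fibrillation) fall back to a single mid-diastolic phase
midway (cyclically) between Vmax and Vmin, with both mid landmarks equal
and a `no_kick` flag set. Ties at equal smoothed volumes resolve to the
earliest phase in cyclic search order; on an odd span the fallback midpoint
also takes the earlier phase. A constant curve or one with fewer than 8
phases is rejected as degenerate. On noisy near-degenerate kicks, the
unsmoothed read-offs can invert the mid-landmark ordering; the batch API
NaN-masks exactly the affected parameters (PEF and/or AEF) rather than
discarding the subject's volumes, and the single-curve API raises.

## Area-length volumetry

LA volume uses the biplane area-length formula V = (8/3π)·A₂·A₄/L from the
2- and 4-chamber views; RA uses the monoplane variant V = (8/3π)·A²/L from
the 4-chamber view only. The coefficient is kept at full floating precision.
The formula is exact for a prolate spheroid imaged through its long axis —
the convergence table in `analysis/02` shows the inscribed-polygon error
falling as ~1/n², two orders below the 2/vertices tolerance at the
200-vertex default.

Atrial length is not standardised; this package uses the distance from the
annulus-landmark midpoint to the farthest contour vertex, and the biplane
denominator takes the minimum across views (the conservative convention in
echo/CMR practice; `length_rule` exposes mean/2ch/4ch alternatives).
Contours are physical-mm polygons, y-down; both open and explicitly closed
vertex dialects are accepted.

The inverse operation (`contours_from_curve`) emits elliptical contours
with semi-axes a = (3V/(4πr²))^(1/3), b = r·a and annulus landmarks at the
two vertices adjacent to the basal apex, so the measured length approaches
2a and the round trip is the identity on volumes within polygon tolerance —
the oracle used throughout the pipeline tests.

## Cohort generation and calibration

Each subject carries, per chamber, a conventional-technique landmark set, a
CS (compressed-sensing) set, and two repeat-reader sets. Draws are
parameterised as (Vmax, TEF, PEF, AEF) per chamber because the calibration
targets live in fraction space; the landmark volumes follow algebraically.

Sampling is staged: the (Vmin, Vmax) pair is drawn with truncated redraws
(floor 8 ml on Vmin, at least two 2-ml gaps of headroom), then the
diastasis and pre-A volumes are drawn from normals truncated to the window
their ordering constraints leave open (exact inverse-CDF truncation — the
limit of redraw-until-valid). Staging matters: enforcing one landmark's
constraint then cannot distort another's marginal, which is what lets the
configured conventional-vs-CS disagreement survive generation intact. A
2 ml minimum separation between adjacent landmarks keeps the atrial kick
detectable at the default noise level.

**Technique disagreement** is applied at the derived-parameter level
(conventional − CS = bias + N(0, sd)), with defaults taken from the
emulated study's Bland-Altman rows (e.g. LAVmin bias −2.0 ml,
sd = (5.6 − (−2.0))/1.96 ≈ 3.88 ml). It acts on the functionally
independent subset (Vmin, Vmax, PEF, AEF); the TEF disagreement is then
implied, since five LA parameters overdetermine a four-landmark curve. RA
fractions carry no published disagreement and pass through unchanged.

**Reader jitter** is multiplicative per landmark volume (default 3 %),
drawn independently for each landmark — one global scale factor would
cancel out of every emptying fraction and make reader ICCs for TEF/PEF/AEF
exactly 1.

**Phenotype defaults.** The healthy-volunteer centre is the study's
conventional cohort medians (LAVmin 24.0 ml, LAVmax 70.3 ml, PEF 53.9 %,
AEF 40.3 %). The HFrEF centre is a calibration choice: a dilated
(LAVmax ≈ 100 ml), hypocontractile (PEF ≈ 30 %) atrium whose *population*
AUC ordering puts PEF first and LAVmin second among the seven report
parameters, mirroring the qualitative finding that conduit function and
minimal volume carry the diagnostic signal. Because TEF ≥ PEF pointwise
(the structural identity above), a PEF separation of AUC ≈ 0.99 forces
TEF's AUC to ≈ 0.89–0.95; the stable ranking therefore requires LAVmin's
separation to sit *above* TEF's, which places its absolute AUC (≈ 0.96)
above the study's printed value. The generator reproduces the ranking, not
the printed AUC magnitudes — those depend on cohort correlations no
four-parameter Gaussian model can pin down. A side effect of the ordering
constraints is that the HFrEF booster window is squeezed from below, so
AEF's effective separation is weak (AUC ≈ 0.55) — consistent with AEF
being the least reliable and least diagnostic parameter.

## Phantom frames and edge sharpness

The phantom is a tilted ellipse of blood-pool intensity on a myocardium
background; intensity crosses linearly over `edge_width_mm` measured
*normal* to the boundary (exact point-ellipse distance, solved by bisection
to ~1e-10 mm). A 20–80 % rise of a linear ramp spans 0.6 of its width, so
ground truth sharpness is 1/(0.6 w), recorded in the sidecar together with
an `under_resolved` flag when the ramp spans fewer than two pixels.

The measurement chain is: ROI crop → bilinear upsampling (output sample j
at input coordinate j/factor, so spacing divides exactly and planes stay
planes) → recursive Deriche gradient (causal + anticausal second-order
filters; smoothing kernel k(α|x|+1)e^(−α|x|) at unit DC gain, derivative
kernel −c·x·e^(−α|x|) at unit ramp response; borders replicated; verified
against direct truncated-kernel convolution to 1e-10) → binarisation at a
fraction of the gradient maximum → standard (ρ, θ) Hough accumulator (1°,
1 px bins), taking among the peak bins the supporting-point run of greatest
spatial extent → 8 profiles orthogonal to the line over its central 80 %,
sampled bilinearly → per-profile 20–80 % crossings by linear interpolation,
taking the pair that brackets the steepest point (centre of the
maximal-slope run, so a perfectly linear ramp is handled); profiles whose
levels are crossed more than twice, never, or only on one side are flagged
invalid. Sharpness is the mean of 1/d over valid profiles, in mm⁻¹.

Defaults: α = 1.0 on the upsampled grid, threshold fraction 0.5, upsample
factor 4, profile half-length 8 mm, sample step 0.25 upsampled pixels.
None of these is sharply determined by the workflow description; all are
exposed in `SharpnessConfig`.

Two operating regimes matter. The *oracle* regime (tests and
`analysis/04`) uses 0.75 mm pixels and a large, locally flat ellipse, where
all widths 2–6 mm are resolved and the measurement lands within 5 % of
1/(0.6 w); the residual −2 to −3.5 % bias is corner-cutting of the clamped
ramp by bilinear interpolation plus slight profile obliquity on the curved
boundary. The *acquisition-like* regime uses the study's 1.5 mm pixels on a
96² frame, where a 2–3 mm ramp is under-resolved by the sidecar's own
definition and absolute sharpness reads low — there the pipeline asserts
only the conventional-vs-CS *ordering*, which is robust. Absolute sharpness
values from the study (0.045 vs 0.034 mm⁻¹) are not reproducible anyway:
they depend on the unpublished α, threshold, upsampling and profile length
of the original script, and on true scanner edge profiles that are not
linear ramps.

## Statistics battery

* **Mann-Whitney U**: exact enumeration for tie-free samples with
  n₁+n₂ ≤ 12, otherwise the tie-corrected normal approximation with
  continuity correction (via scipy); zero rank variance returns p = 1.
  The technique comparison applies it to paired data as the emulated study
  did; a Wilcoxon signed-rank path would be the statistically preferable
  paired analysis and is a one-line swap at the call site.
* **ICC**: two-way, absolute agreement, computed from the ANOVA mean
  squares; single-measure ICC(A,1) by default (individual readings are
  compared), average-measure ICC(A,k) available. Verified against
  brute-force sums of squares to 1e-10 and cross-checked against pingouin.
* **Bland-Altman**: differences oriented conventional − CS (the emulated
  study's LAVmin bias −2.0 with larger CS medians fixes this orientation);
  LoA = bias ± 1.96·SD(n−1), symmetric about the bias by construction —
  the arithmetic identity the acceptance suite verifies against the
  published rows.
* **Fleiss κ** through statsmodels, with the qualitative band scale
  (poor < 0 … almost excellent > 0.81) and an explicit error when a single
  category is always used (chance agreement 1).
* **ROC/AUC** via the Mann-Whitney identity U/(n₁n₂) with midranks; the
  per-parameter expected direction (volumes higher in HFrEF, emptying
  fractions lower) is applied before ranking. The operating point
  maximises the Youden index, lowest cutoff on ties. Cross-checked against
  trapezoidal integration.
* **DeLong** paired-AUC test from the empirical covariance of the
  structural components; identical predictors short-circuit to p = 1.
  The variance estimate agrees with a 2000-replicate subject-level
  bootstrap within 15 % at n = 60.
* **KS normality** against a normal with the sample's own mean/SD, used
  only to gate median/IQR vs mean ± SD reporting. Estimating the
  parameters from the sample makes the asymptotic p conservative (the
  Lilliefors caveat) — acceptable for a reporting gate, mirroring common
  SPSS usage.
* No multiple-testing correction; p-values are per-comparison, mirroring
  the emulated analysis. Quartiles are type-7 (linear interpolation), the
  SPSS-compatible convention.

## Pipeline and problem sizes

`run_study` chains generator → contour round trip → landmark detection →
statistics and emits the three report tables (seven technique-comparison
rows; observer ICCs on study-like subsets of 20 HV + 19 HFrEF inter and 20
HV intra; AUC/sensitivity/specificity plus DeLong per parameter) and the
phantom sharpness comparison. Failed rows are marked with the failing
stage's message and do not abort the run; everything is rounded only at
serialization (1 decimal for ml/%, 2 for ICC/R²/AUC) and a fixed seed
yields byte-identical reports.

Validation runs use 82 + 19 subjects (the study's groups) for reports,
500 per arm for disagreement recovery (2 SE ≈ 0.35 ml on the LAVmin bias),
and 50 seeds for the AUC-ranking frequency; a full 500-per-arm run takes a
few seconds on one core.

## What the synthetic data does not capture

The generator emulates parameter-level structure: landmark ordering, group
separation, technique bias/spread, reader jitter, and a clean ramp edge. It
does not emulate image-level reality — segmentation errors correlated
across phases, flow artifacts, arrhythmic cycle-length variation, sloped or
overshooting scanner edge profiles, or correlations between atrial size and
function beyond the structural identity. Passing tests therefore establish
that the *measurement and statistics machinery* is correct and internally
consistent at the study's problem sizes, not that the study's cohort values
would be reproduced on real scans.
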