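# Methods

## The model

`okcrp` analyses anterior-corneal power change induced by overnight
orthokeratology (OK) along the two principal corneal meridians. The
corneal refractive power (CRP) at radial distance `x` (mm) from the
videokeratoscopic centre is the single-surface refraction power obtained
by tracing an axis-parallel ray to the cornea and intersecting the
refracted ray with the instrument axis:

    P_R = n' / (z + x / tan(θi − θt)),
    θi  = asin(x / r_a),      sin θt = sin θi / n',

where `z` is the sagittal height (mm), `r_a` the axial radius of
curvature (mm) reported by the topographer, and `n' = 1.3375` the
keratometric refractive index. Lengths are carried in millimetres and the
axial-intercept denominator is converted to metres, so `P_R` is in
dioptres. Because `r_a = x √(1 + z'²)/z'` (the normal-axis intercept),
`θi = atan(z')`: the formula is a deterministic function of the sag
profile and its meridional slope. At the apex the printed expression is
0/0; the analytic paraxial limit `(n' − 1)/r_a` is used instead.

Two consequences of this construction are worth knowing:

* On a sphere `P_R(x)` *increases* with `x` (longitudinal spherical
  aberration of the refracted ray). On conics the aberration term
  balances the growth of `r_a` at `Q = −1/n'² ≈ −0.56`; corneas more
  prolate than that show decreasing `P_R(x)`, milder ones (including the
  typical `Q ≈ −0.25`) still show an increase. The test-suite pins both
  regimes against an independent vector-refraction ray trace.
* `P_R` at a point depends on the *slope* there, not on local curvature,
  which drives the decentration behaviour described below.

### Zonal analysis and the CPC power ratio

Profiles are evaluated at 16 fixed signed positions (±0.5 … ±4.0 mm,
0.5 mm steps; positive = nasal or superior). The 1 mm chord (2
locations) is the corneal centre, the 4 mm chord (8 locations) the
central region, and the 5–8 mm chord (4 locations per side) the
paracentral regions. Per subject and meridian:

* centre change = mean power change at the two centre locations (the
  natural scalar for a two-location centre);
* per side, the maximum paracentral change *relative to the centre
  change* and its location (a maximum, not an average, so a decentred or
  oversized treatment zone is not washed out); the maximum is signed;
* CPC power ratio = relative maximum / |centre change|.

Cohort summaries are the **mean of the per-subject ratios**, not the
ratio of the cohort means — the two differ because the ratio is a
nonlinear per-subject statistic. Subjects with |centre change| < 0.25 D
are treated as non-responders and excluded from ratio summaries (the
ratio is numerically unstable near a zero denominator); the threshold is
configurable and every exclusion is warned about. Mean-of-ratios is
tail-sensitive: a responder just above the threshold can contribute a
large ratio, which is visible in default-cohort summaries.

### Statistics

Per location, the per-subject changes are tested against zero with a
normality-gated scheme: Shapiro–Wilk at α = 0.05 routes to a paired t
test (normal) or a Wilcoxon signed-rank test. Bonferroni correction uses
the 16 locations of one meridian as the family, matching how per-meridian
profiles are reported. Meridian asymmetry is tested by the same gated
scheme on the per-subject difference between the two sides' relative
maxima, and the centre–paracentral relationship by Pearson correlation of
centre change against relative maximum. Degenerate zero-variance inputs
short-circuit (no change → p = 1; uniform nonzero change → p = 0). An
omnibus (mixed-model) stage is deliberately not included; the
per-location tests carry the localisation burden.

## The synthetic-cornea generator

Baseline corneas are conics of revolution. Defaults: apical radius
`r0 ~ N(7.80, 0.22²)` mm, matching an adult myopic cohort summary;
asphericity `Q ~ N(−0.25, 0.10²)` — an assumption (typical prolate adult
values), since baseline asphericity is not part of the emulated summary.

### Treatment model (power-target inversion)

OK remodelling is *specified in power space*, where clinical numbers
live: the programmed change field is

    ΔP(d) = a_c · exp(−(d/w_c)⁴) + A · exp(−(d − r_ann)²/(2σ_ann²)),

a flat-topped (super-Gaussian) central flattening plus a Gaussian
steepening annulus, as a function of distance `d` from the treatment-zone
centre. `a_c` is scaled so the field equals `delta_center` exactly at
d = 0.5 mm — the corneal-centre measurement location — and the annulus
peak is `annulus_amp` at `r_ann`. Defaults (`delta_center ~ N(−2.0,
0.8²)` D, `annulus_amp ~ N(+2.5, 0.7²)` D, `r_ann ~ N(3.0, 0.25²)` mm,
`σ_ann = 0.6` mm, `w_c = 1.5` mm) programme a relative paracentral
maximum near 4.5 D and a CPC ratio near 2.25, inside the clinically
reported range.

The post-treatment surface is obtained by *inverting* the power formula:
given the target `P_post(x)` the relation fixes `θi − θt` at every
radius, Snell's law then fixes the slope, and `dz/dx = F(x, z)` is
integrated outward from the apex (RK45, rtol 1e-10). The resulting sag
perturbation is stored as a PCHIP interpolant whose exact derivative
supplies the slope, keeping `(x, z, r_a)` mutually consistent. The
realised change is verified at the centre location and annulus peak to
0.05 D (it is exact to ~1e-4 D in practice). A Gaussian-bump-in-sag
model was considered and rejected: a sag bump's *power* peak sits about
one σ inside the bump centre, so the argmax of the realised change would
not sit at the programmed annulus radius.

Decentration shifts the perturbation field bodily by
(`decenter_x`, `decenter_y`) (positive = nasal/superior); sag is
re-referenced to vanish on the instrument axis, as a topographer reports
it. The measured asymmetry then *emerges* from the axis-referenced
geometry rather than being imposed: at the shifted zone centre the slope
is unchanged, so the measured central flattening weakens there, and a
temporally decentred zone produces a larger *nasal* relative maximum
(≈ 1 D for a 0.5 mm shift) — the direction reported clinically for
temporally decentring lenses. The programmed-change calibration is
checked in the treatment-centred frame, where it remains exact.

### Sampling and noise

Grids emulate a raw videokeratoscope export: up to 300 hemi-meridians
(1.2° apart) × 32 radial samples spanning 0.25–4.5 mm, bracketing the
0.5–4.0 mm analysis range so interpolation never extrapolates.
Measurement noise is a single physical source: independent Gaussian
perturbation of sagittal height per sample per map, default 0.3 µm.
Monotonicity of sag along a ray is restored by a running maximum, and
the slope — hence `r_a` — is re-derived from the noisy heights by
Savitzky–Golay differentiation (window 9, order 3), standing in for the
instrument's smoothed processing. With these defaults the per-map axial
power repeatability is ≈ 0.4 D at 0.5 mm falling to ≈ 0.07 D
paracentrally, in line with clinical videokeratoscopy; averaging the
four replicate maps of a visit halves it.

What the generator does **not** emulate: tear-film and fixation
artefacts, regionally varying baseline asphericity (nasal–temporal shape
asymmetry), epithelial biomechanics, and angularly correlated noise.
Passing tests therefore demonstrate correctness of the *analysis* under
a cornea that satisfies the model's own assumptions, not robustness to
every clinical artefact.

## Numerical choices

* Interpolation along hemi-meridians: monotone shape-preserving
  piecewise cubic (PCHIP) of sag and axial radius at the 0.5 mm offsets,
  then power evaluation; PCHIP avoids the overshoot an ordinary cubic
  spline produces at the steep treatment-zone edge. Linear interpolation
  is available by configuration. Missing coverage propagates as missing;
  nothing is extrapolated or imputed, because silent imputation would
  bias the paracentral maxima.
* Principal-meridian lookup accepts the nearest hemi-meridian within
  half the grid's angular spacing (real exports rarely sample exactly
  0/90/180/270°). Angles follow the topographer convention: 0° nasal
  for a right eye, counterclockwise positive; left eyes put nasal at
  180°, resolved from the grid's `eye` metadata.
* Averaging replicate maps: per-position mean over the maps where the
  position is present; a position missing in more than half the maps is
  reported missing, with a warning.
* Ties in the paracentral argmax break toward the smaller |x|.
* Trigonometry is in radians internally; degrees appear only in
  interfaces describing azimuths.
* The measured paracentral maximum is evaluated on the 0.5 mm grid, so
  a power peak between grid points is underestimated by up to
  `1 − exp(−(0.25)²/(2σ_ann²))` of the annulus amplitude (~2% of the
  ratio for the defaults). Parameter-recovery studies therefore hold the
  annulus radius on-grid; the default cohort keeps the radius random and
  absorbs the small bias.

## Problem sizes of the simulation studies

Replicate studies (null error rates over 1000 cohorts; decentration
power over 25 cohorts of n = 19) sample only the four principal
hemi-meridians with one map per visit — the analysis consumes nothing
else, and this keeps thousands of full-pipeline runs inexpensive.
Single-cohort studies (parameter recovery at n = 50, the default n = 19
cohort) use the full 300 × 32 export with four maps per visit.

## Known limitations

* The power formula is meridional; no 2-D power maps, tangential-power
  or aberrometric analysis.
* The treatment perturbation solved per meridian rides on a surface of
  revolution; strongly astigmatic baselines are out of scope.
* The asymmetry test's level is approximately nominal: the per-subject
  statistic is a difference of two maxima, whose distribution is
  symmetric but not normal; the Shapiro gate routes most such cohorts to
  the signed-rank test, and the observed null rejection rate stays
  within Monte-Carlo error of 0.05.
* Left-eye handling is a convention flag only; no anatomical
  nasal–temporal shape differences are modelled.
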