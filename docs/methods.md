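# Methods

## The morphometric model

All measurements operate on a single annotated optic-nerve-head B-scan:
two Bruch's membrane opening (BMO) points, two anterior laminar insertion
(ALI) points, and an ordered polyline tracing the anterior lamina
cribrosa (LC) surface. Coordinates are micrometres in the scan plane with
the axial axis increasing posteriorly; pixel annotations are converted
once, on read, through the scan's μm/pixel scale.

The line through the two BMO points is the depth reference. With unit
axis **u** along that line and unit normal **n** oriented posteriorly,
every annotated point maps to frame coordinates (t, d) = ((p−b₀)·**u**,
(p−b₀)·**n**). From these:

- **ALID** (anterior laminar insertion depth): d of each ALI point;
  per-scan ALID is the mean of the two sides. Negative values (insertion
  anterior to the BMO line) are legal but flagged.
- **D**: |t₂ − t₁| between the two ALI projections onto the BMO line.
- **S**: the signed area between the anterior-LC polyline and the BMO
  line, restricted to t ∈ [t₁, t₂], by trapezoidal integration of d over
  t. The polyline is linearly interpolated at the exact clip abscissae;
  anterior excursions subtract.
- **mLCD** = S / D, the area-based mean LC depth.
- **LC curvature index** = mLCD − mean ALID.

The index measures the average posterior deviation of the LC surface
from its own insertion chord. Two properties follow from the definition
and are enforced by tests: adding any linear-in-t depth trend (a tilt or
offset of the whole lamina relative to BMO) shifts ALID and mLCD equally
and leaves the index unchanged; and rigid motion of the whole annotation
changes nothing, because all quantities live in the BMO frame.

### "Vertical distance" under a tilted BMO line

Depth is measured perpendicular to the BMO reference line (frame-rotated
depth), not along image columns. This choice makes every result
invariant to scan tilt and matches the geometric construction in which
the bounding lines run from the ALI to the BMO plane. Because real
annotation practice may have used image columns, a strict-vertical mode
(`strict_vertical=True`, or `--strict-vertical` on the CLI) measures
image-column distances instead, for sensitivity analyses. The two agree
exactly when the BMO line is horizontal in the image and diverge
smoothly with tilt.

### Aggregation

Each eye contributes horizontal and vertical scans (nominally the
central three of a five-line cross scan). Per-meridian ALID, mLCD and
index are means over that meridian's gradable scans — one to three are
accepted, and the count used is recorded — averaging per scan first,
then across scans. The overall index is the mean of the two meridian
indices and is reported as absent, never imputed, when a meridian has no
gradable scan.

## Synthetic data

The profile generator emulates the two canonical anterior-LC
cross-sections: a U-shaped parabolic bowl (horizontal meridian) and a
W-shape (vertical meridian) in which a central anterior ridge — the
region carrying the central retinal vessel trunk — interrupts the bowl.
The noiseless depth profile over the insertion span is

    depth(t) = chord(t) + h·(1 − (2t/D − 1)²) − r·exp(−(t − D/2)²/(2w²))

with bowing amplitude h, ridge height r and ridge width w (default D/6;
the ridge's functional form is not constrained by any published
measurement, and a Gaussian bump was chosen as the smoothest unimodal
option). A parabolic bowl has mean depth (2/3)h above its chord, so the
ground-truth curvature index of a noiseless U-profile is exactly
(2/3)h; generator ground truth is nevertheless computed by dense
trapezoidal quadrature (10⁵ + 1 samples) so it remains valid for every
shape. Axial Gaussian jitter (SD `noise_sd`) models annotation noise and
is applied before the whole annotation is rotated by the BMO tilt angle.
At 200 polyline vertices the measurement pipeline recovers noiseless
ground truth to well under 0.5 μm (observed ≈ 0.003 μm).

The cohort generator draws per-eye morphometry and covariates for a
POAG group (n = 123) and a healthy group (n = 92) from the published
group means and SDs (ALID and index per meridian; age, IOPs, refraction,
axial length, corneal thickness, disc/rim area, cup-to-disc ratio, RNFL
thickness, visual-field MD; female/diabetes/hypertension fractions). No
ALID–mLCD covariance is published, so the generator draws ALID and the
index independently and sets mLCD = ALID + index — one admissible joint
distribution that matches both marginals and makes the defining identity
hold row-wise by construction. Covariates with physical lower bounds
(corneal thickness, RNFL, IOPs, axial length, disc and rim area) are
resampled when a draw violates positivity. Severity labels follow the
visual-field MD cut at −6 dB; the boundary value itself is assigned to
the moderate-to-advanced group (both published inequalities are strict,
and the boundary is unpopulated under continuous draws).

What the generator does not emulate: within-eye between-scan
correlation, measurement error correlated across meridians, covariate
intercorrelations (each covariate is drawn independently within group),
and non-Gaussian tails. Passing distributional tests therefore shows the
statistical machinery behaves correctly at the published first and
second moments, not that real OCT annotations behave this way.

The rater-matrix generator draws y[s,r,k] = μ + subjectₛ + raterᵣ + ε
with independent Gaussian components, the additive model under which the
absolute-agreement ICC equals σ²ₛ/(σ²ₛ + σ²ᵣ + σ²ₑ).

## Reliability statistics

ICCs are the absolute-agreement forms of the two-way model, computed
from the ANOVA mean squares of a complete subjects × raters table:
ICC(A,1) = (MSₛ − MSₑ)/(MSₛ + (k−1)MSₑ + k(MSᵣ − MSₑ)/n), with the
average-measure form ICC(A,k) obtained by the Spearman–Brown extension
and F-based 95% confidence intervals (McGraw & Wong). Intra-observer
ICCs treat one observer's repeat series as the second factor
(subjects × 3 repeats), reported per observer; the inter-observer ICC
represents each observer by their mean of three repeats. Repeats within
a cell are always averaged before the two-way decomposition in the
inter-observer case. A constant matrix has no subject variance to agree
about; its ICC is flagged undefined rather than reported. Designs with
missing cells are out of scope. The implementation is cross-checked in
tests against an independent package's two-way absolute-agreement ICC
and against direct-summation ANOVA oracles.

## Cohort statistics

Two-group comparisons use Student's t with pooled variance (Welch's
correction available behind a flag, since heteroscedastic groups are
plausible but pooled-variance t is the specified default) and Pearson's
chi-square without continuity correction for categorical traits.
Severity comparisons use one-way ANOVA across healthy / mild /
moderate-to-advanced with Scheffé's post-hoc criterion: each pairwise
contrast is referred to F(g−1, N−g) after dividing by g−1, giving
simultaneous coverage over all contrasts.

The GLM ladder regresses the overall curvature index on each covariate
alone (OLS; β with 95% CI on conventional clinical units — vertical C/D
ratio is reported per 0.1 increase), then builds multivariate models
from the covariates screening at p ≤ 0.10 (boundary ties enter). The
optic-disc descriptors {disc area, rim area, vertical C/D ratio, RNFL
thickness, visual-field MD} are mutually collinear expressions of
cupping, so they are partitioned across five models — (disc area +
RNFL), (disc area + MD), (rim area), (vertical C/D + RNFL),
(vertical C/D + MD) — rather than entered jointly; the partition is data
about the analysis design, not an algorithm, and is configurable. All
other entered covariates appear in every model. Rank-deficient designs
raise an error naming the aliased columns.

## Numerical choices

- Equality tolerances on geometric invariants: 1e-6 μm absolute.
- Degenerate geometry (coincident BMO or ALI points, zero clip span,
  non-monotone polyline projection) raises a typed error; a reversed
  polyline is normalized to ascending t, not rejected.
- Vertices lying exactly on a clip abscissa are reused, not duplicated,
  so clipping never creates zero-length segments.
- All generators are pure functions of (spec, seed) via
  `numpy.random.default_rng`; identical specs give byte-identical
  outputs.

## Problem sizes used in the checks

Worked-example and group-mean identities are measured on noiseless
2000-vertex profiles; invariance and recovery suites use 60–200
vertices; ICC parameter recovery averages 200 simulated 20 × 2 matrices;
distributional reproduction uses 200 cohort replicates at the published
group sizes (123/92 and 92/92/31). At these sizes the full suite runs in
well under two minutes on one core.

## Known limitations

- The index reduces a surface to two meridional cross-sections; oblique
  LC morphology is invisible to it, exactly as in the source protocol.
- The area integral assumes the anterior LC projects monotonically onto
  the BMO line; strongly overhanging laminae would violate the
  annotation contract and are rejected rather than measured.
- The cohort generator's independence assumptions (see above) make it
  unsuitable for studying covariate-adjustment behavior beyond
  first-order recovery; multivariate coefficient patterns on real data
  will differ because real covariates are correlated.
- Under the published effect sizes, a pooled t-test at α = 0.001 with
  n = 123/92 has noncentral-t power of roughly 0.6–0.7 per meridian, so
  a single cohort draw reproduces the published "P < 0.001" on both
  meridians slightly less than half the time; the separation itself
  (direction and significance at α = 0.05) is essentially always
  reproduced.
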