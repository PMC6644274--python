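# Methods

## Problem and scope

After cataract surgery the refractive outcome depends critically on where
the intraocular lens (IOL) settles along the eye's axis: an error of
1 mm in the postoperative anterior chamber depth (ACD) translates to
roughly 1.4 D of refractive error in an average eye.  `lenspos`
implements the anterior-segment analysis behind one approach to this
problem: describe the preoperative crystalline lens by circle fits to its
two surfaces in a meridional AS-OCT section, derive three axial landmarks
— the anterior, equatorial and posterior surface depths (ASD, ESD, PSD)
— and relate them to the postoperative IOL position and to the refractive
prediction error of the SRK/T formula.  A calibrated synthetic-cohort
generator stands in for per-eye clinical data so the entire pipeline is
exercisable and testable end to end.

All depths are measured from the posterior corneal vertex, positive
toward the retina, in millimetres; corneal thickness is excluded.  The
lens axis is assumed to coincide with the measurement axis; a fitted
circle whose centre sits more than a tolerance (default 0.2 mm) off the
axis is rejected as tilted rather than silently projected.

## Lens geometry

Each lens surface is a circle in the meridional plane.  Circle fitting
uses the algebraic (Kåsa) least-squares objective, solved as a linear
system — closed-form, deterministic and exact on noise-free arcs down to
a 1 mm aperture.  On shallow noisy arcs the algebraic fit is slightly
biased toward smaller radii relative to geometric (Pratt/Taubin) fits;
for the apertures used here (≥ 2 mm chord on radii of 5–14 mm) the bias
is far below the segmentation noise, and the fit routine is isolated so a
geometric refinement could be swapped in without interface changes.

With on-axis circles `(z_a, R_a)` (anterior) and `(z_p, R_p)`
(posterior):

* `ASD = z_a − R_a`, `PSD = z_p + R_p`, `LT = PSD − ASD` (identity);
* `ESD = (z_a² − z_p² − R_a² + R_p²) / (2 (z_a − z_p))`, the depth of
  the plane through the two circle–circle intersection points — the
  radical plane of the pair, restricted to genuinely intersecting
  circles.

The closed form is validated against a brute-force oracle that walks one
circle densely and bisects for the crossing point (agreement to 1e-6 mm
on 1000 random valid pairs).  Non-intersecting *and tangent* pairs are
hard errors: a tangency touches in a single on-axis point and defines no
equatorial plane, and falling back to the radical axis would silently
change the construction's meaning.  For every valid pair
`ASD < ESD < PSD` holds.

## Position and refraction predictors

**C constant.**  The IOL centre is predicted at a fixed fraction of the
preoperative lens thickness behind the preoperative ACD:
`IOL_C = ACD_pre + C·LT`.  The effective C of an operated eye is
recovered as `(ACD_post + t/2 − ACD_pre)/LT` with `t` the IOL central
thickness; predictor and recovery are exact algebraic inverses.  The
default IOL thickness (1.02 mm) is the difference between the cohort's
mean posterior and anterior IOL surface positions and is configurable.

**SRK/T.**  The optical ACD follows the published chain — corneal radius
`r = 337.5/K`; corrected axial length (identity below 24.2 mm, quadratic
above); corneal width and height via the Pythagorean construction with
the radicand clamped at zero; `ACDconst = 0.62467·A − 68.747` and offset
−3.336 mm.  The predicted refraction is the thin-lens vergence solution
at the spectacle plane (vertex 12 mm by default, a convention the source
analysis does not state and we expose as a parameter), using the optical
axial length `AL + 0.65696 − 0.02029·AL` and indices 1.336/1.333.  All
constants sit in one table (`SRKT_CONSTANTS`) so errata apply in one
place.  Supported ranges: AL ∈ (15, 40) mm, K ∈ (30, 60) D, power
∈ (−10, 40) D; outside them the functions raise rather than extrapolate.

**A-constant optimization** finds the A zeroing the cohort-mean
prediction error (measured spherical equivalent minus predicted
refraction) by Brent root bracketing on A ∈ [110, 125]; the residual
mean error is below 1e-6 D.  Zero *mean* (not median) error is the
optimization target.

## Cohort statistics

Summaries use the sample SD (n−1).  Correlations are Pearson
product-moment with two-sided p from the exact t transform.  Bonferroni
correction is applied within each analytic family — the lens-thickness
family (9 tests), the C-constant-prediction and IOL-position families
(3 each) and the prediction-error family (4) — because those blocks are
the natural hypothesis families of the analysis; the family map is
configurable, and corrected p-values cap at 1.  Partial correlations
(single control variable, age) use the first-order closed form; the
residual-on-residual route is kept as a test oracle only, plus a
cross-check against `pingouin`.  The position regression is ordinary
least squares (via `statsmodels`), with standardized coefficients
`b·sd(x)/sd(y)` and the multiple R².  No multiplicity correction is
applied to regression inference.  Rounding (2 dp for mm and D, 3 dp for
p) happens only when reports are written; in-memory tables keep full
precision.

## Synthetic cohort

The generator emulates a cataract cohort of 79 eyes of older adults.
Defaults (means ± SD): age 69 ± 11 y on (26, 86); LT 4.48 ± 0.37 mm on
(3.64, 5.40); ASD 2.79 ± 0.38 mm; ACR 10.21 ± 1.32 mm;
PCR 6.01 ± 0.53 mm; AL 24.60 ± 1.51 mm on (21.74, 28.47);
corr(age, LT) = 0.53, corr(LT, ASD) = −0.65, corr(LT, ACR) = −0.60,
corr(LT, PCR) = −0.12; anterior IOL position
`0.25·ASD + 0.15·ESD + 0.44·PSD − 0.47` plus settling noise at
population R² 0.71; prediction-error SD 0.45 D correlated 0.65 with the
(anterior IOL − SRK/T ACD) difference; IOL thickness 1.02 mm; aperture
4 mm.  Corneal power is *not* part of the emulated cohort description;
K ~ N(43.5, 1.5) D is an explicit assumption (a typical phakic
distribution), quarantined so nothing checked against the cohort depends
on it, and the generation A constant (118.4) and target refraction
(−1.5 D, in 0.5 D clinical power steps) likewise only shape the
refraction channel.

Design choices worth stating:

* **Moment-matched truncation.**  Age/LT (jointly) and AL are truncated
  to the cohort ranges by rejection.  Naive truncation of a normal with
  the target moments shrinks them (the age upper bound, 1.5 SD above the
  mean, would cut sd(LT) from 0.37 to ≈ 0.34 through the age–LT
  correlation).  The parent distributions are therefore calibrated — by
  a deterministic quadrature-plus-root solve for the rectangle-truncated
  bivariate normal, and the `truncnorm` closed forms for AL — so the
  *truncated* draws carry the target means, SDs and correlation.
* **ASD from moments.**  ASD given LT is linear with slope
  `r·sd(ASD)/sd(LT) = −0.668` and intercept fixed by the means; the
  residual SD completes sd(ASD) = 0.38.  The sample regression line of
  ASD on LT then emerges as ≈ `−0.67·LT + 5.78`.
* **PSD and ESD are never drawn.**  PSD is the identity ASD + LT; ESD is
  computed through the geometry module from the sampled circles.  Their
  moments and correlations — sd(PSD) ≈ 0.314 (closed form), corr(LT,
  PSD) ≈ 0.39, mean ESD ≈ 4.24 mm, and the IOL-position correlations
  (≈ 0.67/0.74/0.74) — are emergent and treated as validation, not
  calibration.
* **Settling noise calibrated on a pilot.**  The noise SD of the IOL
  position model is set on an internal 20 000-eye pilot (a fixed child
  seed) as `sd(fit)·sqrt((1 − R²)/R²)`, so the population R² equals the
  target without ever regressing on the cohort being generated.
* **Seeding.**  One master seed; all sub-draws (lens block, pilot,
  optics, position noise, refraction noise) use children of its
  `SeedSequence` in a fixed spawn order.  Identical parameters give
  byte-identical CSVs.  Eyes failing the range or geometry screens are
  redrawn and counted; counts land in the provenance sidecar.

What the generator does *not* emulate: longitudinal lens growth (the
age–LT link is cross-sectional), measurement error in the depths
themselves (surface noise enters only through the optional
surface-sampling path), non-normal or heteroscedastic ASD residuals, and
any realistic joint distribution of K, AL and IOL power.  Consequently
the cohort's SRK/T predicted-ACD *level* (and every real-cohort p-value)
is not reproduced — passing tests show the pipeline's internal
consistency and its agreement with the reported cohort *structure*, not
agreement with unreported per-eye clinical data.

## Problem sizes and numerical choices

Calibration and emergent-moment checks run at n = 5000 (sampling error
on a correlation ≈ 0.012, comfortably inside the ±0.03–0.06 bands);
pipeline-level checks run at the study's n = 79; the surface-sampling
Monte-Carlo comparisons use 300–500 replicates of 50-point arcs.  The
circle-fit collinearity test uses a rank test with a scale-relative
tolerance; the A-constant bracket is [110, 125]; tangency and
non-intersection raise instead of returning limits.  Degenerate inputs
(constant variables, collinear predictors, control variables collinear
with a correlate) raise with specific messages rather than propagating
NaNs.

## Known limitations

The Kåsa fit's small-radius bias is uncorrected (documented above).  The
equatorial construction is a single-meridian calculation; no two-meridian
averaging or lens tilt re-derivation is attempted.  The Bonferroni family
convention is declared, not recovered from the source analysis.  The
generator's K distribution assumption caps how far the refraction channel
can be compared with the real cohort.
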