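# Methods

`acangle` quantifies the anterior chamber angle (ACA) from segmented
anterior-segment OCT (AS-OCT) boundary polylines and grades it on the
three-level scale used in gonioscopic practice — small (SA), moderate (MA)
and large (LA) angle, the ordinal collapse of Scheie grades III–IV / II /
open+I.  This note records the model, the numerical choices, and what the
synthetic data do and do not establish.

## Coordinate frame and inputs

Each radial B-scan is a 2-D cross-section: x lateral (mm), y axial (mm)
increasing posteriorly.  The inputs per scan are the full-width posterior
corneal boundary (continuing peripherally into the inner corneoscleral
wall), the anterior iris surface of each side, and a manually clicked
scleral spur per side.  Sixteen meridians at 11.25° give 32 angle sections
per eye; section index k is centred at k·11.25°, with 0° temporal for a
right eye and 90° superior.

## Angle parameters

For one section, with the spur projected onto the wall polyline
(tolerance 50 µm):

* **AODSS** — perpendicular distance from the wall at the spur to the
  anterior iris.
* **AOD750** — the same cast from the wall point 750 µm anterior to the
  spur.  The offset is measured as *arc length* along the wall, the
  standard AS-OCT convention.
* **TISA750** — area bounded by the two AOD segments, the wall and the
  iris (shoelace on the sampled polygon).
* **LID** (light intersection distance) — the line from the corneal
  endothelial apex (the most anterior vertex of the full-width posterior
  cornea, ties broken toward the scan centre) that grazes the most
  protruding point of the iris, extended to its next intersection X with
  the wall.  LID = |X − spur| (Euclidean; an along-wall variant is exposed
  via `distance="arc"`), signed negative when X lies anterior to the spur.
  This emulates the limiting optical path of a gonioscopic lens: a high
  iris bombé intercepts the view early (X on the cornea, LID < 0), a flat
  iris lets the ray reach the recess (LID > 0).

On a discrete polyline, "grazing the most protruding point" is the
supporting line of the iris vertex set as seen from the apex: the vertex
minimizing the polar angle of the apex ray on that side, with collinear
runs resolved toward the most peripheral vertex.  For a flat or posteriorly
bowed iris this limit is the iris root itself, in which case X is the root
and LID is (plus) the spur-to-recess distance — which is why LID saturates
near +0.1…+0.25 mm in wide-open angles while varying continuously through
negative values as bombé increases.

Closed (appositional) angles return 0 for the distance/area parameters;
only geometric impossibility (ray leaving the imaged region, boundaries
crossing inside the TISA region) is reported as missing, with a reason.

### Numerical choices

* The spur is snapped to the nearest *point on* the wall polyline (segment
  projection), not the nearest vertex: projection keeps the snap error at
  the chord-sagitta level (< 1 nm at 5 µm sampling) rather than half a
  sample spacing, which matters for micron-level reproducibility.
* All ray/polyline intersections are segment-by-segment with a 10⁻⁹ mm
  tolerance; the first intersection along the ray wins.
* The wall tangent used for the perpendicular casts is a symmetric chord
  over ±0.1 mm.  A single-segment tangent is exact on noise-free data but
  hostage to axial segmentation noise (≈0.085 rad tilt at 3 µm noise on
  5 µm spacing); the chord window is exact on circular arcs and keeps the
  tilt near 0.02 rad.
* Arc-length bookkeeping (the 750 µm offset, LID's anterior/posterior
  sign) runs on a moving-average-denoised copy of the wall (±25 µm
  window).  Independent axial noise inflates raw chord length by
  E[√(h²+δn²)]/h — ≈30% at the default noise level — which would drag the
  "750 µm anterior" landmark toward the spur; the averaging removes this
  while biasing a 6.5 mm arc by well under 0.1 µm.  The iris is *not*
  smoothed (its bombé summit may legitimately be a sharp feature).
* TISA polygons that self-intersect by only a micro-bowtie at the corners
  (segmentation noise) are repaired via `buffer(0)`; a repair that changes
  the enclosed area by more than 1% is reported as a degenerate region
  instead.

## Grading model

The grading model is a proportional-odds (cumulative logit) regression on
one or more angle parameters X, written with the minus-sign convention

    Q_SA    = logit(P_SA)        = α₁ − Σᵢ βᵢ Xᵢ
    Q_SA+MA = logit(P_SA + P_MA) = α₂ − Σᵢ βᵢ Xᵢ

so that a positive β means larger parameter ⇒ wider grade.  Each section
or quadrant is assigned the grade of highest probability; exact ties
resolve toward the narrower grade (clinically conservative).  The shipped
reference model uses LID alone with α₁ = −2.111, α₂ = 0.019,
β_LID = 10.231 (`acangle/assets/lid_reference_2020.json`); its grade
boundaries sit at LID ≈ −0.180 and −0.025 mm.

Fitting is maximum likelihood: BFGS on (α₁, log(α₂−α₁), β) with an
analytic gradient, three starts (empirical-cumulative-logit start plus two
seeded perturbations), convergence to gradient norm ≤ 1e-8 where
attainable.  Standard errors come from the finite-differenced observed
information at the optimum.  Complete separation is detected (per-datum
NLL below 1e-8 or parameter magnitudes beyond 10³) and raised as a
non-finite MLE rather than returned.  The open/closed variant is the same
machinery with a single threshold, using LID alone.

Stepwise selection is forward on the likelihood-ratio test (entry
P < 0.05, ties by column order) with backward removal at P > 0.10.  The
quadrant-level modeling unit is the quadrant mean of the section values;
majority vote over section grades is available as an alternative.

## Validation statistics

* Correct rates: trace/total overall, diagonal/row-sum per class.
* Weighted kappa defaults to *quadratic* weights
  w_ij = 1 − ((i−j)/2)²: on the reference validation confusion table this
  weighting yields 0.772 where linear weights yield 0.677, so quadratic is
  the weighting consistent with the reported agreement.  With exactly two
  raters (gonioscopy vs model) the statistic is the two-rater weighted
  Cohen kappa.
* AUC is the Mann–Whitney estimator with half credit for ties, oriented so
  AUC > 0.5 means "smaller parameter ⇒ narrower grade".
* ANOVA is classical fixed-effects one-way (k−1, N−k); an infinite F
  (zero within-group variance, unequal means) reports P = 1e-300 rather
  than 0.  Pairwise group tests are Welch t-tests with optional Bonferroni
  (off by default).
* Bland–Altman limits of agreement are mean difference ± 1.96 SD.

## Synthetic data

The geometric generator emulates one angle section with a circular-arc
cornea (radius 6.5 mm by default), a parabolic-bombé iris from the pupil
margin to the iris root on the wall, and the spur a small arc offset
anterior to the recess.  Axial Gaussian noise (default 3 µm) emulates
segmentation jitter; the lateral sampling grid is fixed, as in a real
B-scan, so noise is axial only.  Every generated section carries its
analytic (noise-free) parameter values computed in closed form —
line/parabola/circle intersections, tangency from the apex, Gauss–Legendre
quadrature for the area — independently of the measurement code.

The grade presets place the noise-free LID well inside the three grade
regions of the reference model and near the reference per-grade means:

| preset   | ACD (mm) | bombé (mm) | root depth | recess offset | LID (mm) |
|----------|---------:|-----------:|-----------:|--------------:|---------:|
| narrow   | 1.90     | 0.50       | 2.50       | 0.25          | −0.304   |
| moderate | 2.20     | 0.55       | 2.80       | 0.25          | −0.098   |
| wide     | 2.30     | 0.35       | 3.00       | 0.13          | +0.117   |

Group-level sampling draws LID/AOD750/TISA750 per grade as Gaussians with
the reference modeling-cohort means/SDs and sizes 34/29/48 (SA/MA/LA);
cross-parameter correlation is configurable and defaults to independent.
The stepwise-selection fixture instead generates grades from LID through
the reference model and adds companions correlated with LID at ρ = 0.7 —
informative marginally, uninformative given LID — because stepwise
selection is only exercised meaningfully against correlated competitors.

What passing tests on these data show: the geometric extraction is correct
to the micron against exact constructions; the fitting machinery recovers
known coefficients; the statistics reproduce published summary values
computed from published tables.  What they do not show: robustness to real
segmentation failure modes (vessel shadows, angle-recess blur, spur
mislocalization beyond 50 µm), iris shapes outside the parabolic family
(plateau iris, iridotomy notches), or the sampling variability of a real
clinical cohort.

## Problem sizes used in the checks

The reproduction suite uses 100 random closed-form scenes for the geometry
check, 200 replicates for the AUC comparison, 1000 for the ANOVA
separation rate, and 100 self-simulated cohorts of n = 500 for parameter
recovery — sizes at which the Monte-Carlo error of each summary is well
below its acceptance band.

## Known limitations

* LID is undefined (reported missing) when the grazing ray exits the
  imaged region; very wide angles with a short scleral wall can therefore
  lack LID while AOD/TISA are present.
* The supporting-vertex rule is exact for convex-anterior iris profiles;
  strongly non-convex segmentations raise a support failure rather than
  silently grazing an interior fold.
* The generator's per-grade geometry is a one-parameter family per preset
  plus jitter; it is designed for correctness testing, not for emulating
  population anatomy distributions.
* Quadrant anchoring of the 8-section blocks (blocks starting at the 45°
  boundary sections) is a convention; any consistent anchoring preserving
  the section centres gives the same per-section map.
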