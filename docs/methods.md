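# Methods

## Coordinate conventions

All analysis happens in a canonical anatomical frame: `u` (x) proximal →
distal, `v` (y) dorsal, `w = u × v` (z) radial for a right-side bone; origin
at the proximal extreme of the outer surface. Left-side bones are reflected
across the u–v (sagittal) plane and relabeled right before mapping, so one
angular convention serves both sides.

Automatic orientation takes `u` as the dominant principal axis of the outer
vertex scatter, signed so the broader end (larger RMS radial spread over the
end decile — phalangeal bases are broader than trochleae) is proximal, and `v`
as the second principal axis, signed away from the mean deviation of per-slice
centroids from the proximodistal chord (phalanges bow palmarly, so centroids
deviate toward the palm). Both signs accept explicit hints, which real
specimens with unusual morphology may need; meshes whose first-to-second
principal extent ratio is below 1.2 are rejected as unorientable. Operator-set
"standard anatomical position" in interactive software is not reproducible;
this automatic procedure is a deterministic, testable surrogate, not a
re-creation of any particular operator's choices.

Ray angles are measured from mid-dorsal (+v), increasing toward +w, i.e.
counterclockwise about +u. Map rows run proximal → distal over shaft-length
fractions 0.02–0.98; row j sits at 2% + j·1% of shaft length.

## Thickness cartography

The analysis shaft is the window 20–80% of maximum bone length (configurable;
recorded in every output). The protocol grid is fixed at 97 sections × 50
semi-landmark rays. Section contours come from exact plane–mesh intersection;
per surface the largest closed loop is kept and extra loops are logged. Rays
are cast from the **outer-contour area centroid**; the landmark on each
surface is the **farthest** ray–contour intersection, which guarantees the
outer landmark lies outside the inner one on non-convex contours. Where the
inner (endosteal) contour is absent or missed — a solid section — the inner
landmark falls back to the centroid (thickness = full centroid-to-outer
distance) and the cell is flagged; flagged cells are excluded from means and
profiles and imputed (group column mean) only when assembling the statistics
matrix, with counts logged. This keeps the imputation auditable rather than
silent.

Thickness maps are standardized by dividing every cell by maximum bone length
(measured as the u-extent of the outer surface, the distal-most trochlea to
proximal-most base distance). Standardizing twice is an error, and mean maps
refuse mixed standardization states.

The proximodistal profile is the per-level mean over the 50 angular cells.
Peak location applies a centered moving average (window 5 rows ≈ 5% of shaft;
configurable) before the argmax, because raw per-row means on jittered meshes
produce spurious argmax jumps; ties in the smoothed profile are broken by the
raw profile and then proximally, so a flat profile reports the proximal-most
level and a sharp single-row peak is not displaced by its own smoothing
plateau.

## Cross-sectional mechanics

Polygon area, centroid and second moments use the exact closed-form boundary
sums (Green's theorem) with orientation normalized to positive area; annular
(cortical) properties subtract the inner polygon from the outer and transfer
moments to the combined centroid by the parallel-axis theorem, so
J = I_xx + I_yy holds exactly by construction. Moment axes follow x = w
(radial), y = v (dorsal).

J is evaluated at 35/50/65% of **maximum bone length** (not shaft length —
the two reference frames are distinct and both are recorded in metadata) and
standardized as J/L⁴, the dimensionally homogeneous choice; the exponent is a
first-class parameter recorded in every output, since length-standardization
conventions differ across the literature.

Curvature: section centroids across the shaft window are projected to the
sagittal plane and a circle is fitted — Kåsa algebraic fit plus one
Gauss–Newton refinement pass. The included angle is the arc the whole bone
subtends on that circle, 2·arcsin(L/2R). Fits with R > 50× shaft length are
reported as exactly 0° (straight); the threshold is arbitrary but recorded.
The fitted radius and RMSE are returned so borderline fits can be inspected.

## Group statistics

Standardized maps are flattened row-major (level-major, then angle) to a
specimens × 4850 matrix. PCA mean-centers but does **not** rescale columns —
all cells share units (dimensionless standardized thickness); a
correlation-matrix variant is available by flag. The basis comes from SVD
with a deterministic sign convention (largest-magnitude loading positive), so
scores are reproducible across runs and platforms.

CVA runs on the first three PC scores by default (configurable), solving the
symmetric generalized eigenproblem of between-group versus pooled
within-group covariance; axes are scaled so the pooled within-group
covariance is the identity in canonical space, making canonical Euclidean
distance a Mahalanobis distance.

The one-sample Hotelling T² uses the exact F transform
F = T²(m−p)/(p(m−1)) on (p, m−p) degrees of freedom.

Typicality probability of a specimen for a group is the upper-tail χ²_k
probability of its squared canonical distance D² to the group centroid
(k = number of canonical axes). The large-sample χ² form is the default; an
F-based small-sample variant for a new observation,
F = D²·m(m−k)/(k(m−1)(m+1)) on (k, m−k) df, is selectable, and results are
labeled with the variant used — published typicality values rarely state
their formula, so both are explicit here. Leave-one-out classification
refits the CVA without the held-out specimen and assigns to the nearest
centroid.

## The synthetic generator

The generator emulates the features of phalangeal cortical bone that the
analysis is meant to detect, with exact ground truth:

- **Geometry**: elliptical cross-sections (dorsopalmar/radioulnar aspect
  ratio, default 1.15) swept along a circular sagittal arc of given included
  angle (default 30°, palmar bowing), with the radioulnar semi-axis
  interpolated quadratically through base (6 mm), midshaft (4.5 mm) and
  trochlear (5 mm) values over a 40 mm bone — proportions in the range of
  hominid proximal phalanges, with base > trochlea so end-based
  proximodistal disambiguation works. Epiphyses are radius flaring only; no
  articular morphology.
- **Thickness field** t(s, θ) > 0: baseline t0 (default 1.2 mm) + axial
  profile (monotone increase, or mid-peak with linear rise to `peak_frac`
  and partial fall) + dorsal raised-cosine window (mid-dorsal ± 60°) +
  two wrapped-Gaussian palmar ridge crests (default centers π ± 0.7 rad,
  sd 0.35 rad) active over an axial window with smoothstep ramps. Axial
  coordinates are parameterized in fractions of the shaft window so a peak
  at 0.65 lands at map row 65%.
- **Inner surface**: the outer polar radius minus t(s, θ) along each
  section-center ray, so the field is exact in ray-angle coordinates.
  Generation fails loudly (reporting s, θ) if thickness reaches the local
  radius.
- **Noise**: i.i.d. radial vertex jitter (surface roughness). This does not
  simulate segmentation error, partial-volume effects, trabecular
  incursions, or real articular ends — so passing tests demonstrate the
  correctness of the measurement chain on clean tubular geometry, not
  robustness to real micro-CT artifacts.
- **Cohorts**: per-individual parameters perturb a group base spec —
  multiplicative log-normal on amplitudes and sizes (preserves positivity),
  additive normal on angular/positional parameters — with invalid draws
  resampled up to 100 times. A single seed drives everything through
  spawned `SeedSequence` children.

The study conditions used by the tests and the acceptance script: two groups
of 15 ("ape-like": ridge_amp 1.5 mm, monotone axial gradient; "human-like":
dorsal_amp 1.0 mm, mid-peak at 0.65), dispersions of 10% on amplitudes and
0.05 on peak location — group differences of several within-group standard
deviations, as intended for a positive-control separation test. The blended
"intermediate" specimen averages the two thickness fields 50/50.

## Numerical choices and problem sizes

- Mesh resolution defaults to (200 axial × 100 circumferential) vertices;
  recovery benchmarks use (400 × 200), where the mapped field matches ground
  truth to well under 1% of local thickness. Cohort analyses in the test
  suite and acceptance script run at the default resolution, which keeps a
  30-bone end-to-end run under a minute while leaving recovery errors an
  order of magnitude below the tolerances being tested.
- Ray–polygon intersection accepts hits within an epsilon past segment
  endpoints so rays passing exactly through a contour vertex (common when
  mesh vertices sit at the ray angles) register on both adjacent edges; the
  farthest-hit rule makes the duplicate harmless.
- Plane sections are perpendicular to the straight anatomical axis u, not to
  the curved centerline — the standard practice for cross-sectional
  geometry; for strongly curved bones the two differ most near the ends.
- Statistical calibration checks (Hotelling type-I rate, typicality
  uniformity) use 2000 Monte-Carlo replicates; at that size the observed
  rejection rate has a binomial standard error of ~0.005 around 0.05.

## Known limitations

- Automatic orientation relies on base-versus-trochlea breadth and palmar
  bowing; pathological or heavily damaged specimens need axis hints.
- Sections with multiple cortical islands (severe non-convexity, damage)
  keep only the largest loop per surface.
- The typicality χ² form ignores reference-sample size; use the F variant
  for small groups.
- The synthetic generator's realism gap (no articular ends, no segmentation
  noise) means biological effect sizes on real material may behave
  differently from the forced-separation cohorts used here as positive
  controls.
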