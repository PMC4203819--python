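# Methods

This note records the measurement models, the parameter choices with
their rationale, the numerical decisions, and the limitations of the
synthetic-data generators.

## Geometry

Each annotated frame carries three cell-outline points and three
ring-outline points (plus an optional apical axis). A circle is
determined exactly by three non-collinear points; `circle_through_points`
solves the algebraic form `x² + y² + Dx + Ey + F = 0` as a 3×3 linear
system and reports the RMS residual (zero on exact inputs). Collinearity
is rejected with a scale-free test: triangle area below `1e-6` times the
squared largest pairwise distance. The test suite checks the fit against
an independent perpendicular-bisector construction.

Metrics, from cell radius `R`, ring radius `r`, center distance `D`:

- closure `= 100 (1 − r/R)`; the raw ratio `100 · r/R` is retained as
  `ring_fraction_pct`. Closure is the quantity that rises to 100% as the
  ring constricts, which is how closure curves are conventionally drawn.
- asymmetry `= 100 · D/R`.
- apical displacement = signed projection of the ring-center offset on
  the unit apical axis (µm).

Annotation noise can push `r` marginally above `R`; ratios in
`(1, 1.02]` are clamped to zero closure (`RATIO_TOL = 0.02`, about the
relative jitter of a 0.05 µm click error on a 2.5 µm cell), larger
violations raise an error. Both metrics are invariant under similarity
transforms (rotation, translation, uniform scale), which the tests
verify on randomized transforms.

## Closure kinetics

- **Crossing times**: first upward crossing of a level, linear
  interpolation between samples. Traces are aligned at the 50% crossing
  (`t_mid`) before population averaging.
- **Smoothing**: centered moving average, window 3 (shrinking
  symmetrically at the edges). One frame interval of smoothing removes
  click jitter without visibly biasing a logistic sampled at 0.5 min.
- **Speeds**: `np.gradient` of the smoothed closure (second-order,
  non-uniform grids supported). Peak speed is the maximum; closure at
  peak is reported alongside.
- **Average 20–80% speed**: least-squares slope of closure vs time over
  the 20–80% window, with interpolated virtual samples appended at the
  exact crossings so the window is honored regardless of sampling phase.
  The endpoint variant `60/(t80 − t20)` is also reported; for a logistic
  the OLS slope is slightly higher (≈11.4 vs ≈10.8 %/min at
  `k = 0.5 /min`), and both are exercised in tests.
- **Monotone guard**: if the smoothed closure drops by more than 5
  points anywhere, the trace is rejected (`NonMonotoneTraceError`) —
  ring regression of that size indicates a failed annotation or furrow
  regression, which this pipeline does not model. `ClosureKinetics.fit`
  logs and drops such traces (recorded in `results.failed`) and raises
  only if no trace survives.
- **Population curves**: mean ± SEM on a common grid — time grid 0.5 min
  (after midpoint alignment) for closure and speed, closure grid 2% for
  asymmetry. SEM uses the sample standard deviation (ddof = 1) divided
  by √n, consistently everywhere in the package; grid points with fewer
  than 3 contributing traces are flagged (`low_n`).
- **Logistic fits**: `c(t) = 100 / (1 + exp(−k(t − t0)))` via
  `scipy.optimize.curve_fit`, initialized from the observed maximal
  gradient. The peak speed of this law is `25k` %/min at 50% closure.

## Study conditions of the simulated cohort

The generator defaults are the study conditions, chosen once from the
biology and the imaging physics, and used unchanged in the worked
example, the acceptance script and the recovery tests:

| parameter | value | rationale |
|---|---|---|
| `k` | 0.72 /min | peak speed `25k` = 18 %/min, typical of small epithelial cells |
| `t0` | 5 min | midpoint a few minutes after anaphase onset |
| `R0` | 2.5 µm | VPC-scale cell radius |
| `alpha` | 0.4 | apical drift fraction: center offset `D = α (R0 − r)`, so asymmetry = α × closure |
| `dt` | 0.5 min | 30 s frame interval, standard for this imaging |
| `jitter_sigma_um` | 0.05 | half a 0.1 µm pixel of click error per coordinate |
| `closure_span` | (1, 95)% | at 95% closure the ring diameter is 0.25 µm ≈ the optical resolution limit; beyond it the three ring points are not resolvable clicks |
| cohort size | 20 | typical cells-per-condition for this kind of study |

Annotation points are placed at fixed angles (cell 90°/210°/330°, ring
30°/150°/270°) with isotropic Gaussian jitter per coordinate; times are
stored in seconds in annotation files and converted to minutes on read.

Near full closure the ring radius approaches the jitter amplitude and
the three-point circle estimator becomes heavy-tailed; at these settings
roughly one trace in twenty trips the monotone guard and is dropped,
which the pipeline reports rather than hides.

## Morphometrics and scaling

- **Cell volume**: box model `L · H · T` with thickness
  `T = n_zsteps · z_step` (default z-step 0.6 µm) — the standard
  coarse estimate for roughly cuboidal epithelial cells.
- **Furrow breadth**: baseline = mean + 2 SD of the outer quarters of
  the intensity profile; breadth is the longest contiguous run above
  baseline. The time-averaged breadth uses the first ≤5 frames where a
  domain is detected, on apical and basal profiles separately.
- **Division-plane perimeter**: ellipse with semi-axes height/2 and
  thickness/2, Ramanujan's approximation
  `π[3(a+b) − √((3a+b)(a+3b))]` (error < 10⁻⁴ for the aspect ratios
  here).
- **Scaling fits**: OLS with intercept (statsmodels), reporting slope,
  intercept, standard errors and R². `ScalingRegression` can pool
  external reference points (e.g. published large-cell measurements)
  into a joint fit across cell sizes.
- **ROI intensity**: mean over a rectangular ROI divided by the mean of
  a background ROI (half-open pixel rectangles).

The population generator draws lengths and cross-sections lognormally
(matched arithmetic mean and CV; defaults 10% and 5%) around stage
means that halve at each division round, and breadths on a ground-truth
line (slope 0.16, intercept 0.3 µm, σ = 0.1 µm) against length.

## Statistics

Unpaired two-sample t-test (pooled-variance default, Welch variant) and
one-way ANOVA via scipy; with two groups `F = t²` exactly, which the
tests assert, and null rejection rates are checked against the nominal
α by simulation. Identical constant groups return a zero statistic with
p = 1; zero-variance groups with unequal means are rejected as
degenerate input. SEM is sd(ddof = 1)/√n throughout.

## Synthetic imaging

Frames are `background + I · exp(−(ρ − r)² / 2σ_r²)` with ρ the distance
to the ring center, voxel size 0.1 µm, ring σ_r = 0.15 µm (diffraction-
scale band width), optional Gaussian read noise. Kymographs are per-
frame maximum projections along one axis; passing `strip_halfwidth`
restricts the projection to a narrow strip through the frame center —
the classic furrow kymograph in which the ring appears as two bands
converging at separation `2r(t)`. (A full-frame projection of an annulus
is a top-hat, not two bands, so the strip is the scientifically correct
default for band-tracking.)

What the generators emulate: logistic closure with apical drift,
annotation jitter, stage-structured size variation, diffraction-scale
ring bands with read noise. What they do not: furrow regression or
pausing, anisotropic cell shapes (cells are circles in the annotation
plane), photobleaching, z-attenuation, point-spread blur beyond the
radial Gaussian, or segmentation errors other than isotropic click
jitter.

## Numerical choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived child seeds are reduced below 2³¹.
- Circle fits use exact linear algebra, not iterative least squares —
  three points determine the circle, and the residual is only a
  diagnostic for (accidental) overdetermined input.
- Population averaging interpolates only within each trace's observed
  domain (no extrapolation); nan-aware means/SEMs are used at partially
  covered grid points.
- The model layer follows the statsmodels convention: a model object is
  constructed from data, `fit()` returns a results object carrying
  estimates, uncertainties, `summary()` and plots — familiar to users of
  the scientific Python stack.

## Limitations

- The box volume and ellipse perimeter are coarse geometric models;
  absolute volumes/perimeters inherit their bias.
- Three-point circle fits are exact but not robust: a single bad click
  propagates directly into `r`, `R` and `D`. The monotone guard and the
  clamp catch the gross failures, not subtle ones.
- The logistic is a descriptive closure law; real traces with plateaus
  or biphasic speeds will fit poorly (the per-trace standard errors
  flag this).
- Asymmetry is a planar measurement; out-of-plane furrow tilt is not
  modeled or corrected.
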