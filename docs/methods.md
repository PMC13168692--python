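# Methods

## Geometric size estimation

The three tagmata are approximated by ideal solids sized from six
caliper measurements (mm): head width (m1) and thickness (m2),
mesosoma width (m3), metasoma width (m4), and the two metasoma
tergite spans (m5: tergites 1–3; m6: tergites 4–6 in females, 4–7 in
males).  Castes differ only in which tergite ends m6; no formula
depends on caste.

* Head: cylinder.  Which measurement is the diameter is a genuine
  convention choice; the default takes the thickness (the smaller,
  more circular cross-section) as diameter and the width as axis, and
  closes both end caps.  Both choices are flags on
  `EstimationConvention`.
* Mesosoma: sphere of diameter m3 (SA = πd², V = πd³/6).
* Metasoma: cylinder (diameter m4, length m5) joined to a cone (base
  m4, height m6).  The external surface is the cylinder lateral plus
  one anterior cap plus the cone lateral π·r·√(r² + m6²); the
  junction disc is internal and never counted.  At m6 = 0 the cone
  degenerates continuously to a posterior cap and the solid to a
  closed cylinder.

Lengths must lie in (0, 100) mm; the upper bound catches unit
mistakes (micron or pixel inputs) since no bee approaches 100 mm.
Per-specimen sums over tagmata are exact by construction.  Because
every formula is homogeneous, scaling all measurements by k scales SA
by k² and V by k³ to machine precision — asserted as a property test.

## Mesh morphometrics

Specimen models are triangulated surfaces read through trimesh
(OBJ/PLY/STL).  Per-face tagma/appendage labels come from OBJ
object/group lines or from a sidecar CSV of face-index ranges; STL
carries no labels, so STL meshes are measured whole-body only.
Surface area is the half-cross-product sum over selected faces;
volume is the absolute signed sum of origin tetrahedra (divergence
theorem).  Both are computed in-package and cross-checked against
trimesh's independent implementations in the test suite.

Scale calibration multiplies vertices by known/measured from a
scale-bar record and re-checks three independent verification pairs
at a configurable tolerance (default 2%), failing loudly with the
offending pairs.

Volume needs a closed, consistently oriented selection.  Inconsistent
winding is repaired (via trimesh) or rejected — a flipped face can
never silently corrupt the signed sum.  A label selection cut from a
closed body leaves boundary loops; each loop is planar-fan capped
about its centroid before summation, and cap area never enters
surface area (which reports external surface only).  Faces with area
below 1e-12 mm² are dropped at load with a logged count.  Hair is
assumed already removed from the model surface; no boundary-layer or
hair handling is attempted.

## Paired comparison statistics

For each scope (head, mesosoma, metasoma, tagmata sum) and quantity
(SA, V), geometric and model values are joined per specimen.
Reported per group: percent error |geo − model|/model × 100 as
mean ± SE over specimens, mean signed error (geo − model; negative ⇒
underestimation), and a paired test on the differences.  Shapiro–Wilk
at α = 0.05 gates between the paired t-test and the Wilcoxon
signed-rank fallback; when normality fails both p-values are kept in
the output, since either may reasonably be reported.  Percent errors
are shown only for significant groups by default (NA otherwise),
with a flag to report them everywhere.  No multiple-testing
correction and no outlier rejection are applied.

The correction factor inverts the error: SA_theoretical =
SA_geometric·(1 − e)⁻¹ with e a *fraction* (the parameter name says
so explicitly, because the ×100 confusion between Eq.-style percent
and fraction is the classic bug here).  Whenever geometric ≤ model,
correcting by the specimen's own percent error reproduces the model
value exactly; this round trip is asserted at machine precision.
Cohort-level correction uses the mean percent error per (tagma,
quantity); tagmata whose difference is not significant are left
uncorrected by default.

## Allometric scaling

OLS of log₁₀ SA on log₁₀ V; the slope β is the scaling exponent,
with a Wald 95% CI.  Isometry (β = 2/3) is tested by a t-test on the
slope — algebraically identical to a single-constraint linear
hypothesis test.  Numerically exact fits (e.g. a pure sphere family,
zero residual) are detected and handled without forming a 0/0
statistic.  Methods are compared with the full interaction model
log₁₀SA ~ log₁₀V × method and a type-II ANOVA on the interaction.
Base-10 logs throughout; natural logs would change only the
intercept.  Major-axis or phylogenetic regression is out of scope.

## Heat budget

Steady state: Q_M + Q_E + Q_R + Q_C = 0, gains positive and losses
negative, all in mW.  Q_M and Q_E come from linear models of
mass-specific rates (mW·g⁻¹) against air temperature, multiplied by
body mass (default 0.0753 g, a typical worker in flight); the
evaporative model supplies a loss magnitude and the budget applies
the sign.  Longwave exchange per tagma:

    Q_R,tagma = [a·ε_C·σ·T_i⁴ − ε_S·σ·T_x⁴]·SA_tagma

with defaults a = 0.98 (body absorptivity), ε_C = 0.90 (borosilicate
chamber), ε_S = 0.98 (body surface), σ = 5.67×10⁻⁸ W·m⁻²·K⁻⁴.
Temperatures convert to kelvin (+273.15) inside this expression only;
SA converts mm² → m² and the result W → mW.  The chamber wall is
identified with air temperature; tagma surface temperatures are
linear in air temperature.  Whole-body Q_R sums the three tagmata.
Convection is back-calculated as Q_C = −(Q_M + Q_E + Q_R) — a
residual, not a mechanistic model — so closure holds exactly by
construction, and between two surface-area methods the difference in
Q_C equals minus the difference in Q_R identically.

The evaluation grid is 20–50 °C in 5 °C steps.  Surface-area error
propagates by rescaling each tagma's SA by (1 − e)⁻¹; because Q_R is
linear in SA, the corrected radiative flux rescales per tagma by
exactly that factor at fixed temperatures.  Each route is regressed
as Q = intercept + T_air + method + T_air·method with a type-II
ANOVA; when the interaction is not significant, method differences
are read as intercept shifts.  The convection/radiation crossover is
located by fitting a line to each route's |Q| over the grid and
intersecting the fitted lines (matching the regression-based reading
of the budget); a raw grid-interpolation variant is also exposed.
Solar (shortwave) radiation, conduction and transient dynamics are
deliberately absent.

Empirical thermal-response coefficients are not bundled: they arrive
via a YAML config (`thermal_models_from_dict`).  The package ships a
clearly-labelled *synthetic* preset for testing (see below).

## Synthetic data

Solid meshes: icospheres (vertices exactly on the sphere, so measured
SA/V approach the analytic values from below, monotonically in
subdivision) and angular-section cylinders/cones with shared junction
rings, so composites are watertight and the junction disc is absent —
matching the estimator's cap conventions exactly.  Default
resolutions (subdivision 4; 128 sections) keep the mesh/formula gap
well under 0.3%.  The composite bee is three disjoint labelled
components; its attached truth equals the caliper-formula estimates
for the same measurements, exactly.

Perturbation: a seeded, mean-centred sum of low-order sinusoids in
each vertex's direction angles displaces vertices radially from the
component centroid; topology is untouched (closure preserved) and
each component is rescaled back to its original enclosed volume, so
non-zero amplitude can only roughen the surface.  Measured SA is
non-decreasing along an amplitude ramp — asserted on the generated
sequence rather than claimed in general.

Cohorts: specimens are isometric rescales of a baseline worker
(m1..m6 = 3.5, 2.0, 4.0, 4.2, 4.0, 3.5 mm) under a log-normal size
distribution (sd of log₁₀ V = 0.1, i.e. roughly the size spread of a
small worker series) with small per-measurement shape jitter
(ln-sd 0.02).  True ("model") values are the formula values inflated
by per-tagma underestimation fractions — defaults: head SA 26.4% /
V 39.3%, mesosoma SA 44.1% / V 50.3%, metasoma 5% — with surface
areas additionally tilted so true SA scales with true V at a
configurable exponent.  Observed "geometric" values carry
multiplicative log-normal noise (ln-sd 0.10, which yields percent-
error standard errors of a few points at n = 11).  The truth log
records every injected fraction, the seed and the draw of size
factors.  What the generator does **not** emulate: real photogrammetric
artifacts (holes, hair remnants, calibration drift), inter-specimen
shape covariance, or caste differences — so passing tests demonstrate
the statistical machinery and error propagation, not the fidelity of
any particular specimen series.

Thermal presets: the `synthetic-worker` set follows the qualitative
physiology of a flying worker — metabolic heat declining with air
temperature, evaporative loss rising, tagma temperatures above air
with the excess shrinking as air warms — but its coefficients are
synthetic and labelled as such.  The crossover preset is constructed,
not tuned: given the radiative series for a set of tagma areas, the
metabolic/evaporative lines are solved so that the fitted |Q_C| line
equals the fitted |Q_R| line exactly at the target temperature
(default 35 °C), which makes the detected crossover exact to
rounding.  The construction verifies that the residual stays a loss
across the grid (otherwise |Q_C| would not be linear) and fails
loudly if not.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.default_rng(seed)`;
  seeds are mandatory in cohort specs and generators are bitwise
  deterministic under a fixed seed.
* Exact-fit regressions (two points, or zero residual) are flagged
  rather than reporting meaningless CIs; all-zero paired differences
  are reported as a degenerate comparison (t = 0, p = 1) instead of
  dividing by zero.
* Problem sizes in the test and acceptance runs — 200 replicates of
  n = 11 cohorts, subdivision-4 spheres, 128-section solids — were
  chosen as the smallest sizes at which the statistical claims are
  stable; everything completes in seconds.
* CSV outputs are written with 6 significant digits to keep diffs
  stable; mesh OBJ exports use full precision so measured values
  round-trip exactly.

## Known limitations

* Tagma boundary provenance on real meshes (cut planes vs manual
  selection) is the user's responsibility; the package only consumes
  labels.
* Boundary-loop capping is planar-fan; heavily non-planar or
  non-manifold boundaries are not handled beyond an explicit error.
* The bundled thermal coefficients are synthetic stand-ins; any
  physiological conclusion requires empirical coefficient sets
  supplied via config.
* Q_C as a residual absorbs every unmodelled route (conduction,
  shortwave); interpreting it strictly as convection assumes those
  are negligible in the source data's chamber conditions.
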