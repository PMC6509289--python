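# Methods

This note documents the models, numerical choices and defaults behind
`srtmkit`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Kinetic model

The simplified reference tissue model (SRTM) expresses a target-tissue
time-activity curve (TAC) through a reference-region TAC assumed free of
specific binding:

C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·∫₀ᵗ C_R(s)·e^(−k2a(t−s)) ds

- **R1** (unitless): relative delivery K1/K1′, near 1 when perfusion is
  symmetric between hemispheres.
- **k2** (min⁻¹): efflux rate from the target tissue.
- **k2a** (min⁻¹): apparent efflux rate; the binding endpoint is
  BP_ND = k2/k2a − 1, stored nowhere and always derived, so the model
  identity holds exactly.

Rates are per minute throughout the kinetics layer; frame schedules are
stored in seconds and converted at the boundary. The model is evaluated
at frame midpoints rather than frame-integrated: with 10-s early frames
and curve time constants of minutes, midpoint sampling errs well below
the estimator tolerances used anywhere in the package, and it keeps the
basis construction a single closed-form pass.

## Continuous-time reconstruction and convolution

The convolution requires C_R between sampling points. Two reconstructions
are used:

1. **Exact sum-of-exponentials.** Synthetic reference curves are
   biexponentials, and a `TimeActivityCurve` can carry that analytic
   description; convolution with e^(−θt) then uses the exact closed form
   (with the t·e^(−θt) limit when θ coincides with a curve rate). SRTM
   forward simulation propagates the analytic form — the SRTM output of a
   sum of exponentials is again a sum of exponentials — so phantoms are
   generated without discretisation error.
2. **Piecewise-linear interpolant** through (midpoint, value) knots with
   C_R(0) = 0 for sampled data (e.g. a reference TAC extracted from an
   image). Each linear segment is convolved analytically and accumulated
   with the semigroup recursion F(t_k) = F(t_{k−1})·e^(−θΔ) + segment
   integral, which is exact for the interpolant and deterministic. On the
   default 50-frame schedule the reconstruction error against the exact
   path is below 1% of the curve maximum and is dominated by the earliest,
   smallest-valued frames.

## Basis-function fitting (BFM)

k2a = θ is discretised on a grid, 100 values on [0.05, 0.4] min⁻¹ by
default. Grid spacing is logarithmic by default — the natural choice for
a rate parameter whose effect is multiplicative — with linear spacing
available. For each θ the two-parameter weighted linear problem
C_T ≈ β1·C_R + β2·B_θ is solved by 2×2 normal equations; the θ with the
smallest weighted RSS wins, ties breaking to the smallest θ for
determinism. Then R1 = β1, k2a = θ*, k2 = β2 + β1·θ*. Weights are uniform
by default; frame-duration weights are available. Negative β2 or BP_ND
are returned as-is and flagged in diagnostics — clamping is a
presentation choice and would bias the recovery statistics the tests
measure. A grid solve whose normal matrix is singular (zero reference,
zero basis) is skipped; if every θ is degenerate the fit raises a
singular-fit error.

The grid resolution bounds the method error: one log step is a factor
(0.4/0.05)^(1/99) ≈ 1.021 in k2a, i.e. at most ~1% after rounding to the
nearest grid point, which propagates to ≲ 0.03 in BP_ND at BP_ND = 1.5.
The independent nonlinear least-squares fitter (`fit_srtm_nls`,
trust-region reflective on (R1, k2, k2a)) provides the oracle: on
noiseless data the two routes agree within one grid step by construction,
and the test suite verifies this across randomised parameter sweeps.

## Voxelwise mapping

`fit_image` computes the basis once and runs only the linear stage per
voxel, vectorised over all voxels (running minimum over θ, so memory
stays at a few maps regardless of grid size); a 60×60×40×50 image fits in
about a second on one CPU. Voxels with degenerate or zero-signal fits are
excluded from the validity mask and left NaN — never interpolated.
Coordinates are voxel-centre based, 0-indexed, mm = origin + index·voxel
size; images are assumed co-registered to a common template space
(registration is out of scope). The reference VOI is a user-placed sphere
specified by centre and volume (default 0.014 cm³, radius derived as
(3V/4π)^(1/3) ≈ 1.495 mm), membership being voxel centres strictly inside.

## Iso-contour lesion segmentation

Interactive threshold picking is replaced by a reproducible rule: the
peak BP_ND voxel is located inside a search region (a box around a
nominal lesion position, or the hemisphere contralateral to the reference
VOI), the threshold is either a fraction of that peak (default 0.5) or an
absolute BP_ND, and the segment is the 26-connected component of
above-threshold voxels containing the peak (6/18-connectivity
configurable). The rule and resulting threshold are recorded in
provenance. Summaries are the mean BP_ND over the mask and volume =
voxel count × voxel volume.

## Baseline normalisation

Longitudinal values are normalised per animal to the first study day,
either as a ratio (value/baseline, baseline ≡ 1) — the default — or as a
difference (value − baseline, baseline ≡ 0). Both conventions appear in
the literature for this design, and they are not equivalent for the
mixed model downstream; the mode is explicit in config and provenance.
Ratio mode refuses zero baselines.

## Longitudinal mixed model

The design is two groups × five days with every animal imaged at every
day. The model is a saturated group×day cell-mean structure plus a
per-animal random intercept, which induces compound-symmetry covariance
with within-animal correlation ρ = σ²_animal/(σ²_animal + σ²_resid).
Estimation is REML (ML available) via `statsmodels.MixedLM`; on this
small design the default optimiser can walk into a singular profiled
covariance, so the fit falls back through bfgs → cg → powell. Tables
whose within-cell residual variation is numerically zero (exact cell-mean
data from a zero-variance generator) short-circuit to the exact
least-squares solution with zero variance components, which REML cannot
profile. Balancedness is checked and reported, not required.

Contrasts are linear combinations of cell means with SEs from the fixed
effects covariance and two-sided t tests on residual degrees of freedom
n_obs − n_cells (40 − 10 = 30 in the default design). This is a
deliberate, documented convention — mixed-model software differs in its
denominator-df defaults (containment, Satterthwaite, Kenward-Roger), and
the residual-df choice is simple, reproducible and slightly liberal: the
within-animal stratum of the balanced design has 24 df, and the measured
type-I error of the interaction contrast is ~0.055–0.058 at nominal 0.05
over 1000 null replicates (inside the binomial 99% band). The rebound
readout is the difference-in-differences contrast
(μ_treated,d2 − μ_treated,d1) − (μ_control,d2 − μ_control,d1), computed
for all day pairs; raw p-values are reported, with a Holm adjustment
helper available but off by default.

A note on detectability: for n = 4/group the interaction contrast's SE
is exactly σ_resid under this model (animal intercepts cancel in
within-animal differences), so an offset of 3σ_resid gives noncentrality
3 and a two-sided power ceiling of Φ(3 − 1.96) ≈ 0.85 — no estimator can
reach 90% power at that effect size and sample size. The acceptance
suite states this effect size explicitly and records the measured power
(~0.82–0.84); `run_design_power` lets users recompute power for any
cell-mean pattern, variance components and n.

## Synthetic data

The generator emulates the study conditions end to end; all generators
are pure functions of (spec, seed).

- **Acquisition**: 50 contiguous frames — 30×10 s, 15×60 s, 5×300 s —
  45 minutes total.
- **Reference curve**: C_R(t) = A(e^(−λ_slow·t) − e^(−λ_fast·t)) with
  A = 100 kBq/mL, λ_fast = 0.6, λ_slow = 0.03 min⁻¹: zero at injection,
  delivery peak near 5.26 min, slow washout — a plausible low-binding
  tissue curve; real reference TAC shapes for this tracer are not
  published, so magnitudes are realistic defaults, not reconstructions.
- **Phantom**: 60×60×40 voxels at 0.5 mm isotropic (rat-brain scale).
  Three kinetic classes share R1 = 1 and k2 = 0.3 min⁻¹ and differ in
  BP_ND: background 0.1, a 2-mm-radius striatum-analogue lesion sphere at
  1.5, and a contralateral reference patch at exactly 0 at the lesion's
  mirror position. The reference VOI sits inside that binding-free patch:
  a reference region with residual binding would bias every downstream
  BP_ND by construction, and the phantom's purpose is a ground truth in
  which the whole chain is identifiable — all k2a (0.12–0.3 min⁻¹) lie
  inside the default θ grid. Truth maps encode the generating parameters
  exactly.
- **Noise**: Gaussian with per-frame SD σ0·sqrt(C/Δt), independent across
  frames and voxels — a count-statistics-inspired surrogate for
  reconstructed-frame noise (variance grows with activity, shrinks with
  frame duration). σ0 = 0 is exactly the identity.
  `sigma0_for_peak_fraction` calibrates σ0 to "x% noise at the peak
  frame". Full sinogram/Poisson simulation and reconstruction are out of
  scope.
- **Longitudinal tables**: compound-symmetry draws around a cell-mean
  pattern; the rebound preset starts both groups at BP_ND 1.5, declines
  the control group slowly, dips the treated group during treatment and
  overshoots the control trajectory at day 65 (shortly after treatment
  stops) by 0.55, converging again by day 142.

What passing these tests shows: the estimators recover their own
generating model at study-scale noise, the segmentation recovers known
geometry, and the statistics are calibrated under the stated covariance.
What they do not show: robustness to violations the phantom does not
contain — reference-region specific binding, partial-volume and
resolution effects, motion, registration error, non-Gaussian
reconstruction noise, or R1/k2 heterogeneity beyond the three classes.

## Study-mode pipeline

`run_study` simulates one compact phantom per animal per day
(32×32×20 voxels by default, with fitting restricted to a lesion search
box plus the reference patch — the fitted quantity, lesion-mean BP_ND, is
unchanged by the restriction) with the scan's true lesion BP_ND drawn
from the CS model around the rebound pattern, runs every scan through
extraction → mapping → segmentation → summary, normalises to day 30 and
fits the mixed model with all pairwise contrasts. Runs are deterministic
given config + seed (byte-identical output tables), and each result
bundle embeds the grid, threshold rule, VOI, seed and full config needed
to re-run it.

## Known limitations

- Frame-midpoint model sampling (not frame-integrated); adequate for the
  default framing, untested for very long frames over fast kinetics.
- The piecewise-linear reconstruction underestimates sharply peaked
  reference curves between early midpoints.
- Residual-df contrasts are slightly liberal on small designs (see
  above); no Satterthwaite/Kenward-Roger approximation is provided.
- The iso-contour rule assumes a single dominant lesion; multiple lesions
  require separate search regions.
- No partial-volume correction, smoothing, motion or registration
  handling.
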