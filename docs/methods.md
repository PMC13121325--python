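# Methods

This note documents the models, numerical conventions and design choices
behind `lafovkin`. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from external
measurements.

## Kinetic models

### One-tissue compartment model (radiowater)

Tissue perfusion is quantified with the one-tissue compartment model

    dC_T/dt  = K1·C_A(t) − k2·C_T(t)
    C_PET(t) = C_T(t) + V_A·C_A(t)

where `C_A` is the arterial input corrected for the tracer-arrival delay,
`K1` (mL·min⁻¹·mL⁻¹) equals perfusion *f* for freely diffusible water,
`p = K1/k2` is the water partition coefficient (distribution volume), and
`V_A` is the arterial volume fraction of the voxel or region. Two derived
measures are reported: the blood-corrected perfusion `H2Oflow = K1·(1−V_A)`
and the distribution volume `K1/k2`.

The fit is parameterized as `(K1, p, V_A)` with `k2 = K1/p` derived, so
the physiological constraint on the partition coefficient is a plain box
bound. Default bounds: `K1 ∈ [0, 18]` mL·min⁻¹·mL⁻¹ (printed as
0–1800 mL/(min·dL)), `p ∈ [0, 1]`, `V_A ∈ [0, 0.8]`. Estimation is
bounded trust-region non-linear least squares restarted from 100 initial
vectors drawn uniformly inside the bounds from a single seeded generator;
residuals are weighted by frame duration by default (uniform weights via a
flag). Convergence: `ftol = 1e-9` on the cost, at most 500 function
evaluations per start. The tracer delay is chosen on a discrete grid
(default −5…+15 s in 0.5 s steps at the regional level) by best fit, ties
going to the smallest delay.

### Dense-grid evaluation

All convolution models are evaluated on a uniform 1 s grid. The sampled
input (one value per frame, referred to the frame midpoint) is treated as
piecewise linear through (0, 0) and its samples; the exponential
convolution `∫C_A e^{−k(t−s)}ds` uses a one-pole recursion that is exact
for piecewise-linear inputs, and predictions are averaged over each
frame's duration before comparison with measured frame means. This makes
forward simulation and fitting numerically consistent: a curve generated
by the forward model is exactly representable by the fitter, which is why
noiseless recovery in the tests is exact to optimizer precision rather
than merely "close".

The one caveat of the midpoint convention is the sharp bolus onset: a
frame-averaged arrival frame re-interpreted as a midpoint sample smears
the leading edge across roughly one frame. Tests that compare against
closed forms therefore evaluate away from the onset.

### Dual-input liver model

The liver receives arterial and portal-venous blood. The portal input is
modelled as a unit-gain single-exponential dispersion of the arterial
curve, `C_PV(t) = β·∫C_A(s)e^{−β(t−s)}ds` (default β = 0.5 min⁻¹, fitted
when a liver TAC is available), and the combined input is the convex
combination `C_liverIF = r_A·C_A + r_PV·C_PV` with `r_A + r_PV = 1`.
Fitting is two-stage: a joint bounded NLS over `(r_A, β, K1, p, V_A)`
determines the flow split, then the standard 1TCM is refitted against the
rebuilt combined input; that second fit (including its delay) is the
reported liver result, and its delay and input are what liver voxels
inherit in parametric imaging. The joint stage evaluates the portal and
combined curves through the same sample-at-midpoints path used when the
combined input is constructed explicitly, so the two stages agree exactly
on noiseless data.

The dual-input model is weakly identified in `(K1, k2)` — a long, shallow
RSS valley. The acceptance run quantifies the practical consequence: over
50 noisy replicates (5% Gaussian noise) the coefficient of variation of
`K1/k2` is roughly a third of that of `H2Oflow`, which is why the
distribution volume is the preferable liver readout.

### FDG quantification

Glucose metabolism uses only linear/graphical estimators:

* **Patlak**: OLS of `C_T(t)/C_p(t)` on `∫₀ᵗC_p/C_p(t)` over frames with
  midpoint ≥ t\* (default 20 min, configurable — the linearity onset is a
  user choice, not a fitted quantity). The plasma running integral is
  computed by trapezoid on the densely resampled curve including the
  linear rise from (0, 0), which bounds the bias from coarse early frames.
* **FUR**: mean late tissue activity divided by the plasma integral up to
  the window midpoint (window defaults to the final frame). FUR carries a
  `+V·C_p(T)/∫C_p` bias relative to Patlak Ki that only becomes small once
  the plasma curve has cleared; the tests demonstrate ≈10% agreement at a
  90-min horizon.
* **SUV**: mean activity normalized by injected dose per body weight,
  tissue density 1 g/mL.
* **Glucose uptake**: `GU = Ki·C_glu/LC` with per-organ lumped constants
  (brain 0.65, myocardium 1, skeletal muscle 1.16, 1 elsewhere; editable
  as JSON).

Whole-blood→plasma conversion divides by `1 − HCT·(1 − R)` with `R` the
red-cell-to-plasma tracer ratio (default 0).

The irreversible two-tissue model (k4 = 0) exists only as a simulation
oracle in the phantom module; its late Patlak slope equals
`K1·k3/(k2+k3)`, which the Patlak implementation reproduces within 2% on
a one-hour schedule.

## Voxel-level estimation

Two linearized 1TCM estimators:

* **Basis-function method** (default): 500 exponential-convolution basis
  curves on a uniform k2 grid over [0, 6] min⁻¹. Per voxel and basis, the
  two-coefficient non-negative LS problem in (K1, V_A) is solved in closed
  form (unconstrained 2×2 solution projected onto the active-set edges),
  which reduces the whole bank to a few matrix products per voxel block —
  10⁴ voxels fit in about a second on one core. The smallest-RSS basis
  wins, ties to the smaller k2.
* **Three-parameter NNLS**: the integral form
  `C(T) = θ1·∫C_A − θ2·∫C + θ3·C_A(T)`, θ ≥ 0, mapped back via
  `K1 = θ1 − θ2·θ3` (clipped at 0), `k2 = θ2`, `V_A = θ3`. The tissue
  integral exploits that TAC samples are frame averages (cumulative
  value×duration is exact), which matters at the bolus.

Per-voxel delay is a lookup over a delay grid with one basis bank per
delay shared across all voxels; liver voxels instead inherit the ROI-level
combined input and delay. Parametric maps carry NaN outside the mask and
include an `h2o_flow = K1·(1−V_A)` map; maps are written one NIfTI per
parameter.

Subregion clustering is agglomerative (Ward by default) on the
one-dimensional parameter values, k = 3 by default, output labels ordered
by ascending cluster mean. ROIs above 50 000 voxels are clustered on a
seeded subsample with nearest-mean assignment of the rest (the only
departure from permutation invariance, and the reason a seed is part of
the interface).

## Input-function extraction

The descending-aorta IDIF automates the manual delineation protocol:

1. blood-phase reference image = mean of the bolus-phase frames (up to the
   heart-curve peak for water, first two minutes for FDG) — chosen for
   blood/tissue contrast with noise averaging;
2. axial landmark = boundary of the inferior third of the myocardium's
   z-extent;
3. per axial slice moving downward for 10 cm, the reference-image maximum
   is located within a 20 mm in-plane disc around the previous accepted
   position; jumps beyond 10 mm are rejected and gap-filled by linear
   interpolation of the in-plane path between accepted neighbours;
4. the IDIF is the per-frame mean over the one-voxel-per-slice string
   (optional in-plane dilation for partial-volume averaging).

Search radius and continuity threshold are configuration, since the
underlying protocol states the construction but not its parameters.

## Motion and ROI utilities

Rigid transforms are 6-DOF (translation mm, x-y-z Euler rotations in
degrees about the image centre). Registration maximizes masked NCC with a
deterministic two-level Powell search (coarse level: ×2 downsampling after
Gaussian smoothing); if the optimum does not improve on the initial
transform, the initial transform is returned flagged. On smooth phantom
frames, injected shifts ≤ 8 mm and rotations ≤ 5° are recovered to a few
hundredths of a voxel/degree.

The synthetic dynamic reference paints each segmented organ with its own
TAC value per frame — by construction identical to a noiseless phantom
frame inside organs, which the tests assert exactly.

ROI trimming erodes by a metric distance using the Euclidean distance
transform with the physical voxel sampling, so anisotropic voxels are
exact; eroding a mask to nothing is an error naming the ROI. The motion
QC metric tracks, per ROI, the point at (mean x, max y, max z) of the ROI
voxel coordinates — implemented in voxel-index space converted to mm, the
one place where an anatomical-axis convention had to be fixed.

Frame-selection rules: water start frame = first frame after the heart
peak below half-peak; FDG start frame = first frame whose NCC against the
reference frame exceeds 0.8 (configurable); reference frame = highest NCC
against the CT-like image, ties to the later frame. A rule that never
triggers returns the last frame with a warning rather than failing.

## Synthetic phantom

The phantom is the package's validation instrument: geometric organs
(z-aligned aortic cylinder, myocardial/kidney-cortex ellipsoidal shells,
liver/spleen/medulla/muscle ellipsoids) rasterized without overlap, driven
by a tri-exponential bolus arterial input and per-organ kinetic models
(blood, 1TCM, irreversible 2TCM, dual-input liver with r_A = 0.25 and
β = 1 min⁻¹). Organ centres are fractions of the field of view, radii in
mm, so one geometry serves every grid size above the ≈96 mm in-plane
minimum at which the organs still fit disjointly.

Defaults: 96×96×192 voxels at 3 mm; radiowater schedule 26 frames / 5 min,
FDG schedule 24 frames / 44 min; PSF 3.5 mm FWHM Gaussian (matching
scanner-class resolution; set to 0 for construction-identity tests);
per-frame rigid motion injectable; noise Gaussian with
`σ² = α·value/duration` — the first-order post-reconstruction PET noise
model, chosen over Poisson to keep the duration-scaling law analytic
(tests verify the √duration behaviour empirically). Tissue K1 values span
muscle 0.05 to kidney cortex 2.5 mL·min⁻¹·mL⁻¹ with per-organ delays of
2–6 s. The bolus defaults give a tail ≈25% of peak, large enough for
recirculation to matter and small enough that half-peak-based rules are
meaningful.

What the phantom does **not** emulate: attenuation/scatter, reconstruction
artefacts, non-rigid (respiratory/cardiac) motion, intra-organ kinetic
heterogeneity, and anatomy beyond geometric primitives. Passing tests
therefore demonstrate correctness of the estimators and the processing
logic under the stated noise model — not robustness to everything real
scanners produce.

## Pipeline

`lafovkin run` executes phantom → idif → fit → voxelwise → cluster →
collect → qc, skipping stages whose outputs exist unless `--force`, and
writes a JSON run log (stage, status, duration, config hash). The config
is validated strictly before any computation; a single seed controls the
phantom noise, all fit restarts and clustering subsampling, and the
results tables are byte-identical across repeated runs. Desk-scale
problem sizes (32×32×64 grids, coarse 2–3 s delay grids, reduced restart
counts) are used in the automated runs; they are the sizes at which every
property of interest is already decided.

## Known limitations

- The exact portal-vein input model of the original dual-input literature
  is not reproduced; the unit-gain exponential dispersion is a standard
  stand-in with β exposed and fitted.
- Regions with very high arterial fraction (K1–V_A collinearity) remain
  poorly identified; fixing V_A is possible via the bounds but no
  automatic detection is attempted.
- Whole-body diffeomorphic motion correction is out of scope by design;
  only the rigid synthetic-reference correction used for the IDIF
  sub-image is provided.
- FUR and Patlak t\* defaults are conventions, not estimates; both are
  plain configuration.
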