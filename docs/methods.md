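# Methods

This note documents the models, estimators and synthetic-data generators in
`corset`: their assumptions, the parameters that matter, the numerical
choices, and what the synthetic tests do and do not establish about real
microscopy data.

## 1. Vertex model of the gonadal tube

### Geometry

The gonad is modeled as a straight cylindrical monolayer of hexagonal-prism
cells. Basal polygons lie on the outer cylinder (the basement membrane) and
never move; apical polygons open into the rachis and are free. Rings of
`n_circ` cells stack along the axis with a half-pitch circumferential offset
on alternating rings, which gives the honeycomb topology: every apical
vertex is shared by exactly three cells. The axial direction is periodic
(the periodic images are bookkept through shift tables, so vertex
coordinates never wrap). Cross-sections of adult gonads show 10–12 germ
cells around the rachis; the default is `n_circ = 10` (the offset-ring wrap
requires an even count) with `n_axial = 16` rings, i.e. 160 cells. The ring
pitch makes the basal hexagons regular in the unrolled plane; a
`pitch_factor` argument exposes the cell aspect, to which the calibrated
contractility proved insensitive (<1 % between basal-regular and
apical-regular aspects).

### Energy

```
w = Σ_lateral faces A  +  Σ_cells α_c P_c²  +  (ψ/2) Σ_cells (v_c − 1)²
```

* **Lateral tension.** Cell–cell adhesion and cortical tension over the
  lateral faces enter as an effective surface tension, set to 1 — the
  energy unit. Each shared face is counted once. Lateral quadrilaterals are
  non-planar; their area (and the cell volumes) use a fixed two-triangle
  split, which is exact for the polyhedral geometry it defines.
* **Apical contractility.** The actomyosin ring bordering each cell's
  apical opening contracts its perimeter. It enters as `α P²` per cell —
  contractility in the standard vertex-model sense, not a constant line
  tension. This choice is load-bearing, not cosmetic: with a constant line
  tension `α P`, the inward pull of the ring does not diminish as the ring
  shortens, so once the tube narrows past a threshold it collapses outright
  — no stable narrow-tube morphologies exist and the observed
  narrow-rachis phenotypes have no model counterpart. With `α P²` the pull
  is proportional to the current perimeter, narrow equilibria are stable,
  wide-tube and narrow-tube solution branches coexist, and α is
  dimensionless (independent of the arbitrary choice of length unit), as a
  bare reported number must be. Apical faces carry no area term — they are
  openings, not surfaces. Basal faces carry no term — they are fixed.
* **Compressibility.** Cells have a preferred volume (the wild-type average
  cell volume, which is the volume unit, so the preferred value is exactly
  1) and a soft quadratic penalty `(ψ/2)(v − 1)²`. The prefactor
  convention was selected among the candidates (`ψ/2`, `1/(2ψ)`,
  `v₀/(2ψ)`) by the model's observable behaviour at ψ = 0.38: only the
  soft `ψ/2` form reproduces the experimentally calibrated sensitivity of
  the diameter ratio to contractility (ratio ≈ 0.85 at half the wild-type
  contractility, ≈ 0.41 just before the narrow-branch fold). The calibrated
  α itself is insensitive to this choice (<1 %), because the calibration
  point sits near v = 1 where the volume term exerts almost no force.

Lengths are in units of the basal radius; at construction every cell volume
is exactly 1 by choice of the axial pitch and the volume unit.

### Relaxation

Only apical vertices move. The energy gradient is analytic (triangle-area,
edge-length and determinant derivatives, scattered per vertex) and is
verified against central finite differences (step 1e-6, relative 1e-4) in
the test suite. Minimization is L-BFGS with the analytic gradient;
equilibrium is declared when the largest per-vertex force magnitude falls
below `force_tol` (default 1e-6 in model units). Accepted iterates are
monotone in energy (asserted by test). An inversion guard returns a large
constant energy whenever any cell volume drops below 0.02 or an apical
vertex approaches the axis (radius < 0.02): the line search then rejects
the step, and a run into the collapsed regime terminates *flagged*, never
raising. Relaxing the 160-cell tube takes well under a second.

### Calibration and phase diagram

`calibrate_alpha_wt` bisects α until the relaxed equilibrium hits the
wild-type ratio `d_r/d_g = 0.56` at ψ = 0.38 (ratio tolerance 0.005, α
tolerance 5e-4). With the defaults this gives **α_WT ≈ 0.2297**. A
relaxation that runs into the collapse fold counts as "below target" for
the bisection, since collapse only happens on the high-contractility side.

`phase_diagram` relaxes the tube on a grid of (α/α_WT, ψ) — by default 8
relative-contractility values × 6 compressibilities spanning ψ ∈
[0.30, 0.50] around the calibration point — with continuation: each grid
point is seeded from its row neighbor's equilibrium (`from-wide` sweeps α
upward, `from-narrow` downward), which follows one branch of minimal-energy
solutions. Past a critical α the narrow branch folds and the tube has no
tubular equilibrium; after the first unconverged point of a row, up to
three bisection steps in α are inserted so the row's last equilibria
approach the fold (otherwise the narrowest isoline cannot be bracketed).
Points are labeled *wide* or *narrow* relative to the wild-type ratio, and
isolines of fixed `d_r/d_g` (0.75, 0.56, 0.41 — the measured wide-mutant,
wild-type and narrow-mutant morphologies) are extracted by linear
interpolation along each ψ row. The whole default diagram, including
calibration, runs in well under a minute.

A caution that follows from the calibrated model's own steepness: near the
wild-type point the ratio responds strongly to α (d ratio/d α ≈ −4), so a
few-percent difference in the calibrated α — e.g. from a different cell
count per ring or lattice discretization — translates into several
hundredths in the ratio obtained when relaxing at a *fixed* numerical α.
Comparisons across discretizations are therefore made in α/α_WT, which is
also how the phase diagram is parameterized.

### Modulated contractility and pearling

`relax_modulated` assigns each cell `α(z) = base + amp·sin(2πz/λ + φ)` from
its construction apical-centroid z. The pearling amplitude is
`(max r(z) − min r(z)) / mean r(z)` over the per-ring profile of apical
centroid radii. At the full modulation (amp = 0.5 α_WT, λ = tube length,
ψ = 0.38) the high-contractility band is driven past the uniform-tube fold:
the constriction deepens until the inversion guard halts the minimization,
i.e. the model tube pearls toward local pinch-off, with the constriction
phase-locked to the contractility maximum (the flagged, guard-limited state
is reported as such). At half that modulation a smooth converged pearled
equilibrium exists (amplitude ≈ 0.8 versus <1e-6 for the uniform tube).

### Non-goals

Quasi-static minima only (no viscous dynamics); no neighbor exchanges (T1
transitions); no osmotic or fluid-flux modeling; the periodic cell length is
fixed during relaxation (the gonad is embedded in the worm and length
changes are not modeled).

## 2. FRAP analysis

Double normalization corrects the bleached-ROI trace for background and
acquisition photobleaching using the reference ROI; full-scale calibration
maps the (single, noisy) bleach frame to 0 and the pre-bleach mean to 1.
The post-bleach curve, with time reset so the first fitted frame sits at
`t = dt`, is fitted by unweighted least squares with `P (1 − e^{−kt})`,
bounds `P ∈ (0, 1.2]` (fits above 1 are flagged, not clipped) and `k > 0`;
the half-life is derived as `ln 2 / k`, never refit. Initialization: P from
the final-quartile mean, k from the time the curve first reaches half that
plateau. A flat curve raises an explicit "no recovery" error rather than
silently returning P = 0.

Estimator behaviour worth knowing: when the movie ends well before the
plateau (k·T ≲ 2.5) and per-point noise is a few percent, the likelihood
has a ridge toward (large P, small k); single-trace mobile fractions are
then right-skewed and replicate means overestimate P by several points.
This is a property of the prescribed estimator at those acquisition
settings, visible in the slow/low-mobile synthetic regime, and is the reason
slow-pool mobile fractions should be read with that bias in mind.

## 3. Laser-ablation analysis

**Recoil.** Pre-cut, the edge-to-edge distance is fitted linearly; post-cut
by `L∞ − A₁e^{−(t−t_c)/τ₁} [− A₂e^{−(t−t_c)/τ₂}]`, anchored at the nominal
cut frame. The double-exponential fit is initialized by exponential peeling
(log-linear tail fit for the slow mode, early residual for the fast mode),
which makes the noiseless fit exact to rounding. The effective cut time t₀
is the intersection of the two fitted curves, searched on the bracket
between the last pre-cut and first post-cut samples and, if noise pushes
the crossing slightly earlier, on a one-frame widened bracket (failing
both, the midpoint is used and the result flagged). The initial recoil
velocity is the analytic derivative of the post-cut model at t₀. A weak
recoil gives the double model too much freedom and it can grossly
overestimate the velocity at the cut; the `auto` rule therefore rejects the
double model for the single one when its velocity at the cut exceeds 1.5×
the largest
finite-difference velocity over the first 3 s post-cut, or when any of its
parameters has a relative standard error above 1. Note the finite-difference
bound itself under-resolves a fast mode when τ₁ is comparable to the frame
interval, so the auto rule is conservative there; fits of traces known to be
double-exponential should request `model="double"`.

**Total displacement** is `L(t_cut + 50 s) − mean pre-cut L` (sign
preserved), with an explicit error if the trace ends earlier.

**Bridge segmentation and tracking.** Bright signal is thresholded by
Niblack's local rule `mean + k·std` (radius 35 px, k = 0.2 — note the sign
convention: brighter-than-local-context; scikit-image's `mean − k·std` is
called with the sign flipped), lightly closed, and the enclosed interiors
(the bridge openings) are labeled; objects under the minimum area are
dropped. Openings are tracked across frames by maximum pixel overlap (ties:
intersection-over-union, then centroid distance); a track terminates when
nothing overlaps it. Circularity is `4π·area/perimeter²`, clipped at 1,
with the perimeter measured on a lightly smoothed marching-squares contour —
the raw binary iso-contour is a staircase that overestimates smooth
boundaries by ~6 %, so the smooth-contour convention is used and recorded.

## 4. Cytoplasmic-streaming PIV

Single-pass PIV: 32×32 px windows with 50 % overlap, mean-subtracted
cross-correlation per window pair. The linear correlation is normalized by
the per-lag overlap area — without this the triangular overlap ramp biases
the peak toward zero by ~0.1–0.2 px, a 10–20 % speed error at the
displacements of interest — and lags with less than a quarter of the full
overlap are excluded. The peak is refined by 3-point Gaussian interpolation
in each axis; vectors whose peak-to-second-peak ratio falls below 1.2 are
flagged invalid and excluded from all summaries.

Whole-gonad drift is estimated separately by subpixel phase correlation
over a region dominated by static structure, and subtracted:
`v_r = v_p − v_g`. With the distal→proximal axis along +x, summaries report
the time-averaged mean axial velocity `v_rx` and mean speed
`s_r = √(v_rx² + v_ry²)` (per-vector speed, then averaged) over the first
200 s by default. The mean speed is by construction at least the magnitude
of the mean axial velocity.

## 5. Morphometrics

**Bridge perimeters** follow the particle-analysis chain: maximum
projection of consecutive slices (3 around the brightest corset slice by
default), Gaussian blur σ = 1, Niblack radius 35 px, connected components
of the enclosed openings, then the size filter 50–900 px² and circularity
filter 0.45–1.00 applied in pixel units exactly as stated. Because the
`mean + k·std` threshold sits above the edge midpoint, the raw openings are
systematically eroded by a fraction of the blur width; the *retained*
objects are therefore re-measured on the local half-max intensity contour
(marching squares on the image at the midpoint between the opening's floor
and the surrounding rim's brightness), which removes the offset for
symmetric edge profiles. Detection and filtering are unchanged by this
refinement, and it is switchable (`refine=False`).

**Tube geometry** is measured on orthogonal (y, z) cross-sections at three
equally spaced axial sites (each averaged over ±2 px): the corset channel's
radial intensity peak (parabolically refined) gives the rachis radius, the
membrane channel's outermost peak the gonad radius, and per-angular-sector
corset peaks give cell heights — an automated surrogate for manual height
measurements, validated only against synthetic truth.

**Colocalization / variability.** Line profiles are width-averaged (7 px),
background-subtracted (global 5th percentile by default) and compared by
Pearson correlation; the coefficient of variation is sd/mean of a
background-subtracted profile. Both are invariant to multiplicative
intensity rescaling, and Pearson to affine rescaling with positive gain.

## 6. Synthetic-data generators

Every generator returns its artifact plus a `GroundTruth` record (name,
all numeric parameters, seed); identical seeds reproduce outputs
bit-identically. Defaults are the wild-type study conditions (FRAP
P = 0.795, t½ = 37 s; recoil v₀ = 1.12 µm/s with τ = 1 s and 8 s and 70 %
of the initial velocity in the fast mode; streaming 4.71 µm/min axial flow;
tube d_g = 25 µm, heights 5.5 µm so d_r/d_g = 0.56, bridge radius 1.5 µm,
0.25 µm voxels; profile correlation 0.59).

* **FRAP** series invert the analysis model: pre-bleach level 1 above a
  constant background (0.1), a bleach to 20 % of the signal
  (`bleach_depth` 0.8), recovery `P(1−e^{−kt})` from the bleach frame, and
  one shared multiplicative acquisition-bleaching factor on the bleached
  and reference ROI — exactly the perturbation double normalization
  cancels, which the tests verify pointwise to 1e-6. Additive Gaussian
  noise on all three ROI traces.
* **Recoil** traces are linear pre-cut and double-exponential post-cut with
  amplitudes `A₁ = f₁v₀τ₁`, `A₂ = (1−f₁)v₀τ₂`, so the derivative at the
  cut equals v₀ exactly, the trace is continuous, and `f₁` is the fraction
  of the initial velocity in the fast mode. Default frame interval 0.25 s
  (fast streaming acquisition; a 1 s interval undersamples the τ₁ ≈ 1 s
  mode and roughly triples the noisy-velocity error).
* **Speckle movies** hold two particle populations in horizontal bands:
  "structure" speckles (top quarter) advected by drift alone, cytoplasmic
  speckles advected by flow + drift, each wrapping periodically within its
  band. Rendering is bilinear splatting plus a periodic Gaussian PSF blur
  (the blur must wrap to match the particle wrap, or registration is biased
  at the percent level); the exported structure mask keeps clear of band
  boundaries where the PSF mixes the populations. Under-seeded PIV windows
  (<5 particles expected) are recorded as a warning in the ground truth.
* **Tube stacks** render a straight two-channel cylinder along x: membrane
  = basal shell + radial T-partitions (with apical crossbars), corset = the
  inner tube with one circular opening per cell and a brightened rim around
  each opening, cells laid out as angular sectors × axial columns with
  offset rings. The truth records `d_r = d_g − 2·mean(height)`, recommended
  top-tangent slices for en-face bridge projection, and the mid-plane
  index. `corset_surface_mask` gives the unrolled surface for
  topology-level checks (one opening per cell).
* **Correlated profiles** are jointly Gaussian with exact population
  correlation ρ, affinely shifted to positive intensities; ρ = ±1 gives
  sample correlation ±1 exactly.

What the generators deliberately do not emulate: curved (U-shaped) gonads,
Poisson/camera-specific noise statistics (additive Gaussian by default),
depth-dependent PSFs, out-of-focus light, or biological heterogeneity
beyond the per-cell height/bridge-radius fields. Passing the recovery tests
therefore demonstrates that the estimators are unbiased and correctly
implemented under known imaging physics at realistic SNR — not that they
are robust to every artifact of live microscopy.

## 7. Problem sizes and tolerances used by the test suite

The default tube is 10×16 cells (160 cells, 320 free vertices); unit tests
use 10×6 where a relaxation result only needs to exist. The phase diagram
runs at the default 8×6 grid. FRAP acceptance checks use 10 replicates of
16–21-frame traces; recoil sweeps use 100 traces; PIV checks use 128×128
movies of 8–100 frames. The full suite runs in well under a minute on one
core. Convergence tolerances: force 1e-6 (relaxation), ratio 0.005 and α
5e-4 (calibration), gradient check relative 1e-4, symmetry checks 1e-10.
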