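# Methods

This note documents the models, conventions and numerical choices behind
`sbmech`, and what the synthetic study does and does not establish.

## Forward model of a layered specimen

A specimen is a 1-D series stack: ordered bone layers (superficial first,
2 mm each by default) plus a "remainder" lumping the non-mineralized
cartilage and the bone outside the analysis layers. Under the
stress-controlled sinusoid σ(t) = σ_m − σ_a·cos ωt, each part contributes
strain

ε(t) = σ(t)/E − (σ_a·tan δ/E)·sin ωt + R(t)

- *E* (MPa) is the part's modulus. The in-phase strain is exactly σ/E, so
  the middle-50 % slope of a loading branch recovers *E* with only
  second-order bias — the property the estimators are tested against.
- δ is a phase lag solved in closed form from the part's requested
  steady-state loop energy-loss fraction *H* at the protocol frequency:
  tan δ = 2Hσ_m / (πσ_a(1 − H/2)). This is the branch-split normalized
  hysteresis of the resulting elliptical loop, so the generator's
  `loss_fraction` is, by construction, the value the hysteresis estimator
  should report once transients die out (verified to 1 % after cycle 10).
- R(t) is residual strain: cycle *k* adds r·exp(−c(k−1)), accrued during
  the loading half in proportion to the normalized stress and retained
  thereafter. Because the accrual adds apparent compliance that decays
  geometrically, per-cycle stiffness rises monotonically toward *E* — the
  rapid-then-gradual stiffening seen in cyclic compression of
  cartilage-bone. Defaults in the fixture study: bone layers
  r = 1×10⁻⁴, c = 0.5 (their stiffness barely moves over cycles 1–9);
  remainder r = 2.5×10⁻³, c = 0.35 (the whole specimen stiffens ~10 % over
  100 cycles, carried by the cartilage-dominated remainder). This division
  reflects the observation that whole specimens stiffen with cycling while
  the bone layers do not, and is a modeling convenience, not a claim about
  tissue physics.

The record carries a 1 s slice of the 20 N preload plateau (the remainder
of the 5 min hold is steady state and adds only samples), then the first
quarter-cycle blends linearly from the preload stress onto the sinusoid to
avoid a stress discontinuity. Displacement is re-zeroed at the end of
preload; the reference length for engineering strain is the specimen length
at that instant. Gaussian displacement noise (default 0.5 µm) emulates
actuator/load-train noise.

Known consequence: cycle 1's loading branch includes the ramp, so its
stress window is slightly asymmetric and cycle-1 stiffness estimates carry
a ~2–3 % downward bias relative to the generating modulus (quadrature
sampling plus first-cycle residual accrual). This is a property of the
measurement definition on a viscoelastic first cycle, not an estimator
defect; cycle-2+ estimates sit within ~1 %.

## Mechanics estimators

- Cycles are delimited at stress minima (the test is load-controlled);
  only complete min→max→min cycles are returned, indexed from 1.
- "Middle 50 %" is interpreted on the *stress range* of the loading branch
  (25–75 % of the branch span), which makes the window load-level-defined
  and sampling-rate invariant; the bounds are configurable.
- Hysteresis uses the loading work as denominator and integrates each
  branch over its own strain span, so open loops (residual strain) count
  unreturned deformation as dissipated. A retraced loop gives exactly 0;
  full dissipation gives 1. Both conventions (window definition,
  denominator) are the package's documented readings of ambiguous common
  practice.

## DIC

Subset tracking is ZNCC template matching (FFT-based) over a search
window, refined to subpixel either by a 3×3 correlation-peak quadratic fit
(on log-correlation, exact for Gaussian-shaped peaks) or by an iterative
Gauss–Newton minimization with an affine subset shape function. The affine
model matters: layer strains of stiff deep bone involve ~0.1–0.5 px
relative band motion, where the translation-only parabola's pixel-locking
bias (~0.02 px) is material; the Gauss–Newton refiner reaches the
interpolation noise floor (~10⁻³ px) and models the linear displacement
gradient within a subset instead of aliasing it into the center estimate.
Defaults: subset 31 px, step 8 px, search radius 20 px, acceptance score
0.6 — stated choices, configurable; commercial packages do not publish
theirs.

Layer strain is the relative mean axial displacement of two horizontal
bands at the layer bounds over the gauge between them, compression
positive. In the pipeline the sampled bands are inset from the nominal
bounds by the subset radius so every correlation window sees only in-layer
material (displacement is kinked exactly at the bounds, where material
properties change); within a layer strain is uniform, so the inset gauge
measures the same quantity.

Synchronization aligns per-cycle peaks of the video-derived actuator
displacement to the 500 Hz record with one time offset; each peak time is
refined by a local quadratic fit, so a frame-subsampled video channel is
not quantization-limited. Frames are rendered at 32 evenly spaced instants
per analyzed cycle (cycles 1, 2, 3, 5, 9), mirroring the camera-memory
constraint that limits layer analysis in practice; the per-cycle layer
stiffness is fitted on the loading-branch frames inside the middle-50 %
stress window (≥ 5 frames).

## Synthetic volumes and morphometry

Trabecular structure is a per-slice quantile threshold of a smoothed
Gaussian random field inside a cylindrical footprint, so the realized BVTV
matches its target within 0.01 by construction (and exactly equals the
recorded voxel counts). Optional depth gradients give the
superficial-high-BVTV / deep-high-BMD pattern of subchondral bone. Two
homogeneous HA phantom rods (0.25/0.75 g/ccm) sit in corners outside the
specimen. Grayscale is gs = 0.45 × density(mg HA/ccm) plus Gaussian noise
(sd 4), a documented affine convention under which the conventional
thresholds are meaningful: bone ≈ 405 gs sits between the lower threshold
(a few hundred) and the 550 label threshold, stain labels are rendered at
650 > 550, and nothing approaches the 1000 upper threshold. "Damage" labels
are sampled on pore-surface bone voxels within the top 1 mm of bone at the
requested fraction of that zone's bone voxels.

Morphometry mirrors scanner-software practice: Gaussian smoothing (sigma 1
voxel, support 2) then inclusive band thresholding; the per-specimen visual
lower-threshold refinement is replaced by a deterministic default (midpoint
of the background and tissue grayscale modes, override available). Analysis
slabs are flat half-open depth intervals below the median interface depth
(superficial [0.5, 2.5) mm, deep [2.5, 4.5) mm), eroded 1 mm from the
lateral edges via an exact Euclidean distance transform. BMD is tissue
mineral density over mineralized voxels with a one-voxel peel (partial-
volume surface voxels otherwise bias the tissue mean low by ~1 %); BVTV
always uses the unpeeled mask. BSA is the triangulated 0.5-iso-surface of
the smoothed mask (accurate to ~1–3 % for ≥ 0.1 mm features at 4–16 µm
voxels); voxel-face counting is provided only as a cross-check since it
overestimates curved surfaces by up to ~50 %. Surface geometry reports
cartilage thickness, interface angle vs the vertical side (90° = flat), and
evenness as the signed area between the interface profile and its
end-to-end chord (positive = convex).

## Statistics

Continuous outcomes are fitted as Gaussian linear mixed models with a horse
random intercept by REML (statsmodels MixedLM), Wald-z p-values and 95 %
CIs; cycle enters as a categorical fixed effect. Selection follows the
conventional two-step screen: candidates enter at p < 0.20 univariably,
backward elimination removes the largest-p term until all are < 0.05, ties
in p break by covariate name order so selection is deterministic; supplied
two-way interactions among retained mains are tested afterwards, and a
retained site-by-covariate interaction triggers site-stratified refits.
Pairs with |Pearson rho| > 0.60 are flagged so only the better-fitting
member (lower AIC/BIC) is offered to a model. ML and alternative df
approximations are out of scope.

## The fixture study and problem sizes

`make_fixture_study` draws 10 horses × 3 sites with site/layer generating
means set to the published first-cycle descriptive values (layer moduli,
loss fractions, BVTV/BMD levels and gradients, damage fractions); remainder
moduli are solved so the whole-specimen series stiffness lands at the
published totals. Horse- and specimen-level lognormal multipliers (sd 0.12
and 0.10) give realistic between-horse clustering, one palmar specimen
carries a microfracture flag, and ages/geometry follow the reported
means ± sd. Imaging and volumes are scaled for desk hardware as the
package's stated problem sizes: 60 µm voxels on a 110×96×96 grid (vs 4 µm
on a full scanner), 0.03 mm/px speckle frames of 224×200, 32 frames per
analyzed cycle. At these sizes a full 30-specimen imaging run takes a few
minutes on one core.

What passing tests show — and don't. The generator produces elliptical
loops, geometric residual-strain decay, flat interfaces, Gaussian-blob
trabeculae and noise-free load channels; real specimens have irregular
interfaces, spatially heterogeneous moduli, non-elliptical loops, scanner
artifacts and richer damage morphology. Recovery results (e.g. median
cycle-1 layer stiffness within a few % of truth) therefore validate the
*estimators and workflow*, not the biological conclusions; numerical
equivalence with any commercial DIC or scanner software output is not
claimable.

## Known limitations

- No fatigue-life or creep modeling, no machine-compliance correction, no
  stereo DIC, no trabecular thickness/separation metrics, no pre/post-stain
  registration.
- The statistics stage reports Wald-z inference, anti-conservative for very
  few groups; with 10 horses coverage is near-nominal (checked by
  simulation).
- Cycle-1 layer stiffness carries the small viscoelastic first-cycle bias
  described above.
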