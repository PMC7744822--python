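# Methods

`muskstrain3d` maps regional skeletal-muscle deformation in 3D from
velocity-encoded phase-contrast (VE-PC) MRI accelerated by compressed
sensing. This note documents the models, the numerical choices, and what
the synthetic phantom does and does not establish about real data.

## Processing model

The chain mirrors a dynamic VE-PC study of the calf during cyclic isometric
plantar-flexion: multi-coil k-space, undersampled along the phase-encode
(ky) axis with a different variable-density pattern per temporal frame, is
reconstructed into complex images per velocity-encode segment; velocity maps
are formed by phase difference against the flow-compensated reference
segment (v = VENC·Δφ/π); the velocity series is shading-corrected and
denoised; every voxel is tracked through the contraction–relaxation cycle;
strain-rate tensors come from spatial velocity gradients per frame and
Lagrangian strain tensors from gradients of the accumulated displacement on
the reference grid; eigenvalues are sorted ascending and labelled fiber
(lowest, compressive), out-plane (intermediate, small), in-plane (highest,
cross-sectional expansion); the invariants are the maximum shear

L_max = (2/3)·√[(Lxx−Lyy)² + (Lxx−Lzz)² + (Lyy−Lzz)² + 6(Lxy²+Lxz²+Lyz²)]

and the volumetric strain L_vol = tr(L). Strain-rate values are stored in
1/s and reported ×10³ (i.e. 10⁻³ s⁻¹, "milli-strain per second") in record
tables, matching the convention of in-vivo reports where a table entry of
−940 corresponds to −0.94 s⁻¹.

## Synthetic phantom

No raw in-vivo data are available, so validation rests on a phantom with
analytically known kinematics.

**Deformation.** Displacement is separable, u(X, t) = g(t)·w(X)·A(X−c).
`A` is a constant symmetric matrix with principal strains
(a_f, a_out, a_in): a_f = `amplitude_fiber` (default −0.25, mid-range of
reported in-vivo fiber strains at 30–40 %MVC), a_in = r·(−a_f) and
a_out = (1−r)·(−a_f) with `anisotropy_ratio` r = 0.95. The construction is
incompressible (principal strains sum to zero) and transversely anisotropic
(out-plane/in-plane ratio ≈ 0.053). The contractile axis is tilted 15° from
the image y axis (the muscle long axis). `g(t)` is a cosine
ramp–plateau–release over 17 frames of 142 ms (cycle ≈ 2.4 s), zero at the
first and last frame so the cycle closes exactly.

**Geometry.** Two elliptical "muscles" (MG, Sol) sit inside a smooth
leg-shaped magnitude object on a 64×48×3 grid at 2×2×5 mm. The spatial
envelope w equals 1 on the labelled muscle and decays to zero at
`envelope_extent` (1.9) times the muscle semi-axes through a 7th-order
polynomial step whose first three derivatives vanish at both ends. Two
consequences are intentional: (i) strain inside the muscle label is
spatially uniform and analytically exact, so ground truth for ROI
comparisons carries no discretization ambiguity, and (ii) the boundary
shear between muscle and surroundings is carried by a smooth C³ taper layer
*outside* the label, so finite differences of the field converge at O(h²)
everywhere. The FOV-sized analogue (semi-axes ≫ FOV) degenerates to the
spatially uniform linear deformation used by closed-form tests.

**Velocity convention.** The stored per-frame velocity is the mean material
velocity over the frame interval attributed to the frame-start
configuration: v_t(x) = [g(t+1)−g(t)]/Δt · U(X_t(x)), with X_t the inverse
of the frame-t deformation map, computed to machine precision by a
vectorized Newton iteration. This models velocity encoding integrated over
a frame interval and makes the Eulerian field exactly consistent with
material-point trajectories, so tracking error measures interpolation
fidelity rather than an arbitrary mismatch between the generator and the
integrator. The analytic strain-rate ground truth is the exact chain-rule
gradient of this Eulerian field.

**Acquisition.** VENC 10 cm/s (peak phantom velocities ≈ 0.8 cm/s, well
inside the dynamic range, as in vivo); 8 coils modelled as Gaussian lobes
around the FOV perimeter with smooth per-coil phase, normalized to unit
sum-of-squares; per-frame ky masks sample round(n_ky/CS) lines — a fully
sampled central band (12.5% of lines) plus lines drawn without replacement
with probability ∝ distance⁻² from the center. Additive complex Gaussian
noise is available (`noise_sd`, default 0); eddy currents, relaxation and
coil noise correlations are not modelled.

**What the phantom does not show.** Real muscle has heterogeneous strain,
fat/connective-tissue infiltration, phase noise at low magnitude,
through-plane fiber curvature and subject motion. Passing tests establish
the correctness of the *computational chain* (encoding → reconstruction →
tracking → tensors → statistics), not in-vivo accuracy; in-vivo group
values from the literature are used only as plausibility scales.

## Reconstruction

Per slice and encode segment the reconstruction solves
argmin_m ‖M F S m − y‖² + λ‖Ψm‖₁ by nonlinear conjugate gradient
(Polak–Ribière+) with a smoothed ℓ1 (ε = 10⁻⁶ on the normalized scale), in
two stages: Ψ = unitary temporal FFT, then Ψ = projection onto the temporal
principal components (SVD basis) of the stage-1 result, initialized from
it. Coil sensitivities are self-calibrated: frame-averaged reference-segment
k-space, restricted to the ky band sampled in every frame with a Hamming
taper, inverse-transformed and normalized by root sum-of-squares on the
object support (threshold 10% of peak). Defaults: λ₁ = λ₂ = 0.01 of the
peak zero-filled magnitude, 8 outer × 20 inner iterations.

Two numerical choices matter:

* **Exact line search seed.** Along a search direction the data-consistency
  term is an exact quadratic, so each line search starts at its analytic
  minimizer and backtracks only for the ℓ1 term. Without this the optimizer
  crawls (the quadratic's optimal steps are far from unit scale).
* **Data-consistency safeguarded steps.** Steps are capped where the
  sampled-entry residual would exceed its value at the start of the step,
  and directions that would inflate it for any positive step are refused
  (after a steepest-descent restart). Together with a zero initial estimate
  this makes the data-consistency residual non-increasing across iterations
  by construction — a stated contract of the solver — at no measured cost
  in accuracy on the phantom (velocity RMSE inside the object 0.014 cm/s
  at CS factor 4, versus 0.017 cm/s for zero-filling and 0.014 cm/s for the
  unconstrained optimizer).

At full sampling with λ = 0 the first NLCG step lands exactly on the
sensitivity-weighted least-squares solution, so the fully sampled pipeline
is an analytic oracle for the whole chain: any miscalibration of FFT
conventions, coil combination or the phase-difference step would break the
< 10⁻⁶ cm/s velocity round trip. Phase errors common to all encode
segments (e.g. the phase of the self-calibrated maps) cancel in the
phase difference, which is why self-calibration from low-resolution data
does not bias velocities.

## Preprocessing

The denoiser is the classic edge-stopping diffusion filter, explicit
6-neighbor flux form with conductance c(g) = 1/(1+(g/K)²), K = 4,
N = 10 iterations, step δ = 0.0625 (the scheme is stable and
extrema-bounded for δ ≤ 1/6; the flux form conserves the global mean
exactly under the reflecting boundary). The filter runs independently per
velocity component and frame over the 3-slice volume — the minimal reading
of a "3D" filter for multi-component time series. Phase-shading correction
fits a 2D polynomial (order 2 by default) to the reference-frame phase over
a static-tissue mask per slice and subtracts it from all frames; the model
is deliberately replaceable since shading provenance (coil phase versus
eddy currents) differs between systems.

## Tracking and tensors

Tracking integrates x_{t+1} = x_t + v(x_t, t)·Δt by forward Euler with
trilinear interpolation (RK2 midpoint variant behind a flag); points are
free to wander within the extent of the boundary voxel (half a voxel beyond
the outermost center — important for the small through-plane motion of the
outer slices of a thin slab), beyond which they are clamped and flagged,
and flags exclude those voxels from ROI statistics. Out-of-plane tracking is limited by the 5 mm slice
thickness of the 3-slice acquisition — accepted, as the through-plane
deformation component is small by design and in vivo.

Volumetric strain is the most noise-sensitive index: it sums three
gradient components, so voxel-scale phase noise from an accelerated
acquisition inflates |L_vol| well above the deformation's true (zero)
dilatation — the same effect that makes in-vivo |L_vol| reports (0.09–0.36)
exceed what muscle incompressibility allows. The phantom incompressibility
check therefore evaluates the deformation-measurement chain (velocity
series → denoising → tracking → strain) where the discretization-level
median |L_vol| is ≈ 0.013; the value with the CS-factor-4 reconstruction in
the loop (≈ 0.05 on the noiseless phantom) is computed and reported
alongside it by the acceptance script.

Strain uses the infinitesimal definition ½(∇u + ∇uᵀ) on the reference
grid (Green–Lagrange ½(∇u + ∇uᵀ + ∇uᵀ∇u) behind a flag); "Lagrangian"
strain rate is computed as the symmetrized velocity gradient on the fixed
grid per frame, with values attributed to tracked material points only at
the ROI-reporting stage — the alternative (gradients evaluated at tracked
positions) is a known ambiguity and is not implemented. Eigenvector signs
are fixed (largest-magnitude component positive, ties broken toward the
first axis) so outputs are bitwise reproducible; at isotropic points the
fiber/out-plane/in-plane semantics of the sorted eigenvalues are undefined
and labels follow sort order only.

## Extraction and statistics

Strain indices are read at the frame of maximum force; strain-rate indices
at the frame of peak |SR_fiber| (ROI mean) within the contraction phase,
which precedes the force peak. The force trace (200 Hz) is cycle-averaged
and binned onto frame times. ROIs are operator-placed rectangles
(7.81 × 23.44 mm, long axis along the muscle) on the middle slice of the
first-frame magnitude image; on the phantom they default to the region
centers.

Group statistics follow the standard design for two cohorts × three effort
levels: two-way factorial ANOVA (age, %MVC, interaction; type-II sums of
squares) with Levene and Shapiro–Wilk diagnostics, Bonferroni-adjusted
pairwise t-tests across %MVC levels (family of three comparisons) run only
when the %MVC main effect is significant at α = 0.05, and univariate
regression of each index on %MVC and on absolute force. The regression
slope β is standardized (both variables z-scored), so β equals the Pearson
correlation — the interpretation consistent with published β magnitudes
≤ 0.4 at n ≈ 57. Records from repeated %MVC levels are treated as
independent, matching the independent-sample post hoc tests.

## Problem sizes and determinism

Default problem sizes are chosen so a full phantom study runs in minutes on
one core: 64×48×3 voxels, 17 frames, 8 coils, 4 encode segments, CS factor
4; the statistical calibration uses 1000 simulated null datasets of
2 groups × 3 levels × 4 records. All randomness (masks, noise, simulated
records) flows from explicit integer seeds; identical configuration and
seed reproduce byte-identical outputs, and every pipeline run writes its
resolved configuration, a config hash and a checksum manifest.

## Known limitations

* View sharing is treated as applied upstream; frames are taken as given.
* No phase unwrapping: velocities are assumed within ±VENC by design.
* No 3D (kz) undersampling; slices are reconstructed independently.
* The ANOVA treats repeated measures as independent records.
* The eigenvalue labels assume a contracting muscle (fiber strain
  negative); during relaxation frames the same sort order is reported but
  the anatomical interpretation is weaker.
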