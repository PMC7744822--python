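"""Synthetic deforming-muscle phantom with analytically known kinematics.

The phantom emulates a multi-slice lower-leg acquisition during a cyclic
isometric contraction–relaxation: two elliptical "muscle" regions (labelled
``MG`` and ``Sol``) embedded in a smooth leg-shaped object deform with a
separable space–time displacement field

    u(X, t) = g(t) · w(X) · A (X − c)

where ``g`` is a smooth ramp–plateau–release temporal envelope (zero at the
first and last frame, so the cycle closes), ``w`` is a smooth spatial
envelope that is exactly 1 over the labelled muscle and decays to zero in a
boundary-shear layer in the surrounding tissue, and ``A`` is a constant
symmetric matrix whose principal strains encode fiber shortening
(``amplitude_fiber`` < 0), transversely anisotropic cross-sectional
expansion, and incompressibility (the three principal strains sum to zero).
Because the field is analytic, every downstream stage — reconstruction,
denoising, tracking, tensor estimation — can be validated against exact
ground truth.

Velocity convention
-------------------
The per-frame velocity stored on the voxel grid is the mean material
velocity over the frame interval, attributed to the frame-start
configuration:

    v_t(x) = [g(t+1) − g(t)] / Δt · U(X_t(x)),

with ``X_t`` the inverse of the frame-``t`` deformation map (computed by
vectorized Newton iteration).  This models velocity encoding integrated over
a frame interval and makes the Eulerian field exactly consistent with
Lagrangian trajectories of material points.

K-space synthesis follows the standard phase-contrast convention: the
reference (flow-compensated) segment carries zero velocity phase and each
encoded segment carries phase π·v/VENC; each coil's k-space is the centered
2D FFT of the sensitivity-weighted complex image, undersampled along ky
with a per-frame variable-density mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "MuscleRegion",
    "DeformationModel",
    "AcquisitionParams",
    "ForceCurve",
    "PhantomTruth",
    "temporal_envelope",
    "deformation_matrix",
    "make_deformation",
    "coil_sensitivities",
    "magnitude_image",
    "encode_kspace",
    "make_force_curve",
]


# ---------------------------------------------------------------------------
# Grid and model definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid, axes ordered (y, x, z) with y the phase-encode /
    muscle long axis. Coordinates are in mm, centered on the FOV."""

    shape: tuple[int, int, int] = (64, 48, 3)
    spacing: tuple[float, float, float] = (2.0, 2.0, 5.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("grid must be three-dimensional (y, x, z)")
        if any(int(n) < 3 for n in self.shape):
            raise ValueError(
                f"degenerate grid {self.shape}: every dimension must have "
                "at least 3 samples for spatial gradients"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * d
            for n, d in zip(self.shape, self.spacing)
        )

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (ny,nx,nz) coordinate arrays in mm."""
        ay, ax, az = self.axes_mm()
        return np.meshgrid(ay, ax, az, indexing="ij")


@dataclass(frozen=True)
class MuscleRegion:
    """Elliptical muscle cross-section (in the y–x plane, full slab in z).

    The labelled muscle deforms uniformly (the spatial envelope is exactly 1
    inside the ellipse); the deformation decays to zero over a smooth taper
    in the surrounding tissue, out to ``envelope_extent`` times the muscle
    semi-axes.  The taper layer carries the boundary shear between muscle
    and surroundings, so strain inside the muscle label is spatially uniform
    and analytically exact.
    """

    name: str
    center_mm: tuple[float, float]  # (y, x)
    semi_axes_mm: tuple[float, float]  # (y, x)
    envelope_extent: float = 1.9

    def __post_init__(self) -> None:
        if self.envelope_extent <= 1.0:
            raise ValueError("envelope_extent must exceed 1")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("region semi-axes must be positive")


def _default_regions() -> tuple[MuscleRegion, ...]:
    return (
        MuscleRegion("MG", center_mm=(30.0, 5.0), semi_axes_mm=(15.0, 11.0)),
        MuscleRegion("Sol", center_mm=(-30.0, -5.0), semi_axes_mm=(15.0, 11.0)),
    )


@dataclass(frozen=True)
class DeformationModel:
    """Parameters of the cyclic contraction–relaxation deformation.

    ``amplitude_fiber`` is the peak contractile (most negative principal)
    strain reached on the plateau of the spatial envelope at peak
    contraction.  ``anisotropy_ratio`` splits the transverse expansion that
    compensates fiber shortening between the in-plane cross-sectional axis
    (fraction ``r``) and the through-plane axis (``1 − r``); the construction
    is incompressible (principal strains sum to zero).  ``fiber_angle_deg``
    tilts the contractile axis in the image plane relative to y.
    """

    amplitude_fiber: float = -0.25
    anisotropy_ratio: float = 0.95
    fiber_angle_deg: float = 15.0
    cycle_duration_s: float = 2.414
    n_frames: int = 17
    regions: tuple[MuscleRegion, ...] = field(default_factory=_default_regions)
    # normalized break points of the temporal envelope (ramp/plateau/release)
    ramp_start: float = 0.05
    ramp_end: float = 0.40
    release_start: float = 0.60

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.cycle_duration_s <= 0:
            raise ValueError("cycle_duration_s must be positive")
        if self.amplitude_fiber > 0:
            raise ValueError("amplitude_fiber is a contraction: must be <= 0")
        if not (0.0 <= self.anisotropy_ratio <= 1.0):
            raise ValueError("anisotropy_ratio must lie in [0, 1]")
        if not (0.0 <= self.ramp_start < self.ramp_end <= self.release_start < 1.0):
            raise ValueError("temporal break points must satisfy "
                             "0 <= ramp_start < ramp_end <= release_start < 1")

    @property
    def frame_interval_ms(self) -> float:
        return 1000.0 * self.cycle_duration_s / self.n_frames

    @property
    def principal_strains(self) -> tuple[float, float, float]:
        """(fiber, out-plane, in-plane) peak principal strains."""
        a_f = self.amplitude_fiber
        a_in = self.anisotropy_ratio * (-a_f)
        a_out = (1.0 - self.anisotropy_ratio) * (-a_f)
        return (a_f, a_out, a_in)


@dataclass(frozen=True)
class AcquisitionParams:
    """VE-PC acquisition parameters (phantom defaults are a scaled-down
    version of the in-vivo protocol: VENC 10 cm/s, 3 slices of 5 mm,
    8-channel coil, CS factor 4, 2 views per segment, 17 frames)."""

    venc_cm_s: float = 10.0
    matrix: tuple[int, int] = (64, 48)  # (ky = phase encode, kx = frequency)
    fov_cm: tuple[float, float] = (12.8, 9.6)
    partial_fov: float = 0.55
    n_coils: int = 8
    cs_factor: float = 4.0
    views_per_segment: int = 2
    n_averages: int = 2
    n_slices: int = 3
    slice_thickness_mm: float = 5.0
    tr_ms: float = 17.8
    n_encode_directions: int = 4  # reference + 3 velocity encodes
    n_frames: int = 17
    center_fraction: float = 0.125
    density_power: float = 2.0

    def __post_init__(self) -> None:
        if self.venc_cm_s <= 0:
            raise ValueError("venc must be positive")
        if self.cs_factor < 1:
            raise ValueError("cs_factor must be >= 1")
        if any(int(m) <= 0 for m in self.matrix):
            raise ValueError("matrix entries must be positive")
        if self.n_coils < 1:
            raise ValueError("n_coils must be >= 1")
        if self.n_slices < 3:
            raise ValueError("n_slices must be >= 3 for 3D gradients")
        if self.views_per_segment < 1:
            raise ValueError("views_per_segment must be >= 1")


@dataclass(frozen=True)
class ForceCurve:
    """Plantar-flexion force sampled at a fixed rate (200 Hz by default)."""

    time_s: np.ndarray
    force_n: np.ndarray
    target_mvc_percent: float
    sample_rate_hz: float = 200.0
    cycle_duration_s: float = 2.414
    n_cycles: int = 1

    def per_cycle_peaks(self) -> np.ndarray:
        """Peak force within each contraction cycle (N)."""
        edges = np.searchsorted(
            self.time_s, np.arange(1, self.n_cycles) * self.cycle_duration_s
        )
        return np.array([seg.max() for seg in np.split(self.force_n, edges)])


# ---------------------------------------------------------------------------
# Analytic deformation field
# ---------------------------------------------------------------------------


def temporal_envelope(
    n_frames: int,
    ramp_start: float = 0.05,
    ramp_end: float = 0.40,
    release_start: float = 0.60,
) -> np.ndarray:
    """Smooth ramp–plateau–release envelope g(t) on ``n_frames`` samples,
    with g = 0 at the first and last frame (cyclic closure)."""
    s = np.linspace(0.0, 1.0, n_frames)
    return _envelope_of_phase(s, ramp_start, ramp_end, release_start)


def _envelope_of_phase(s, ramp_start, ramp_end, release_start):
    s = np.asarray(s, dtype=float)
    g = np.zeros_like(s)
    up = (s >= ramp_start) & (s < ramp_end)
    g[up] = 0.5 * (1.0 - np.cos(np.pi * (s[up] - ramp_start) / (ramp_end - ramp_start)))
    g[(s >= ramp_end) & (s < release_start)] = 1.0
    down = s >= release_start
    g[down] = 0.5 * (1.0 + np.cos(np.pi * (s[down] - release_start) / (1.0 - release_start)))
    return g


def deformation_matrix(model: DeformationModel) -> np.ndarray:
    """Constant symmetric 3×3 matrix A of peak principal strains, with the
    contractile axis rotated by ``fiber_angle_deg`` in the (y, x) plane."""
    a_f, a_out, a_in = model.principal_strains
    th = np.deg2rad(model.fiber_angle_deg)
    e_f = np.array([np.cos(th), np.sin(th), 0.0])
    e_in = np.array([-np.sin(th), np.cos(th), 0.0])
    e_z = np.array([0.0, 0.0, 1.0])
    return (
        a_f * np.outer(e_f, e_f)
        + a_in * np.outer(e_in, e_in)
        + a_out * np.outer(e_z, e_z)
    )


def _region_envelope(region: MuscleRegion, Y, X):
    """Spatial envelope w and its in-plane gradient (dw/dy, dw/dx).

    w = 1 on the muscle ellipse (ρ ≤ 1) and decays to 0 at
    ρ = envelope_extent through a 7th-order polynomial step whose first
    three derivatives vanish at both ends, so the displacement field is C³
    and central differences of it converge at O(h²).
    """
    cy, cx = region.center_mm
    ay, ax = region.semi_axes_mm
    ry = (Y - cy) / ay
    rx = (X - cx) / ax
    rho = np.hypot(ry, rx)
    ext = region.envelope_extent
    w = np.zeros_like(rho)
    w[rho <= 1.0] = 1.0
    taper = (rho > 1.0) & (rho < ext)
    t = (rho[taper] - 1.0) / (ext - 1.0)
    # S(t) = 35t^4 - 84t^5 + 70t^6 - 20t^7, S' = 140 t^3 (1-t)^3
    w[taper] = 1.0 - (35.0 - (84.0 - (70.0 - 20.0 * t) * t) * t) * t**4
    dwdr = np.zeros_like(rho)
    dwdr[taper] = -140.0 * (t * (1.0 - t)) ** 3 / (ext - 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        drho_dy = np.where(rho > 0, ry / (ay * rho), 0.0)
        drho_dx = np.where(rho > 0, rx / (ax * rho), 0.0)
    return w, dwdr * drho_dy, dwdr * drho_dx


def _field(model: DeformationModel, A: np.ndarray, Y, X, Z):
    """Evaluate U(X) [mm] and its Jacobian J[..., i, j] = dU_j/dX_i at
    arbitrary coordinates (mm).  Works on any broadcastable shape."""
    Y, X, Z = np.broadcast_arrays(Y, X, Z)
    shp = Y.shape
    U = np.zeros(shp + (3,))
    J = np.zeros(shp + (3, 3))
    pos = np.stack([Y, X, Z], axis=-1)
    for region in model.regions:
        w, dwdy, dwdx = _region_envelope(region, Y, X)
        c = np.array([region.center_mm[0], region.center_mm[1], 0.0])
        d = np.einsum("ij,...j->...i", A, pos - c)  # A (X - c)
        U += w[..., None] * d
        gradw = np.stack([dwdy, dwdx, np.zeros_like(w)], axis=-1)
        J += w[..., None, None] * A
        J += gradw[..., :, None] * d[..., None, :]
    return U, J


def _invert_map(model, A, gval, Yg, Xg, Zg, tol_mm=1e-10, max_iter=40):
    """Solve X + g·U(X) = x for the reference coordinates X (Newton)."""
    if gval == 0.0:
        return Yg, Xg, Zg
    target = np.stack([Yg, Xg, Zg], axis=-1)
    Xc = target.copy()
    eye = np.eye(3)
    for _ in range(max_iter):
        U, J = _field(model, A, Xc[..., 0], Xc[..., 1], Xc[..., 2])
        r = Xc + gval * U - target
        if np.max(np.abs(r)) < tol_mm:
            break
        # dr_j/dX_k = delta_jk + g * J[k, j]  -> matrix Fm[j, k]
        Fm = eye + gval * np.swapaxes(J, -1, -2)
        Xc = Xc - np.linalg.solve(Fm, r[..., None])[..., 0]
    return Xc[..., 0], Xc[..., 1], Xc[..., 2]


@dataclass
class PhantomTruth:
    """Ground-truth kinematics of the phantom on the voxel grid.

    Arrays are ordered (y, x, z, frame[, component]); displacement is the
    Lagrangian field (mm, referenced to frame 1 on the reference grid),
    velocity is the per-frame Eulerian field (cm/s), strain is the analytic
    infinitesimal Lagrangian strain and strain_rate the analytic Eulerian
    strain-rate tensor (1/s).
    """

    grid: VoxelGrid
    model: DeformationModel
    labels: np.ndarray  # (ny, nx, nz) int: 0 background, 1.. regions
    plateau_mask: np.ndarray  # (ny, nx, nz) bool: flat core of the envelope
    static_mask: np.ndarray  # (ny, nx, nz) bool: envelope zero, tissue static
    envelope: np.ndarray  # g(t), (n_frames,)
    displacement_mm: np.ndarray  # (ny, nx, nz, T, 3)
    velocity_cm_s: np.ndarray  # (ny, nx, nz, T, 3)
    strain: np.ndarray  # (ny, nx, nz, T, 3, 3)
    strain_rate_per_s: np.ndarray  # (ny, nx, nz, T, 3, 3)
    magnitude: np.ndarray  # (ny, nx, nz)

    @property
    def frame_interval_ms(self) -> float:
        return self.model.frame_interval_ms

    @property
    def muscle_mask(self) -> np.ndarray:
        return self.labels > 0

    def region_mask(self, name: str) -> np.ndarray:
        for i, region in enumerate(self.model.regions, start=1):
            if region.name == name:
                return self.labels == i
        raise KeyError(f"no region named {name!r}")


def region_labels(grid: VoxelGrid, model: DeformationModel):
    """Label map (0 background, 1.. regions), the envelope-plateau mask
    (where the deformation envelope is exactly 1, i.e. the muscle proper)
    and the static mask (envelope exactly 0: genuinely motionless tissue)."""
    Y, X, _ = grid.coords_mm()
    labels = np.zeros(grid.shape, dtype=np.int8)
    plateau = np.zeros(grid.shape, dtype=bool)
    static = np.ones(grid.shape, dtype=bool)
    for i, region in enumerate(model.regions, start=1):
        cy, cx = region.center_mm
        ay, ax = region.semi_axes_mm
        rho = np.hypot((Y - cy) / ay, (X - cx) / ax)
        labels[rho <= 1.0] = i
        plateau |= rho <= 1.0
        static &= rho >= region.envelope_extent
    return labels, plateau, static


def make_deformation(model: DeformationModel, grid: VoxelGrid) -> PhantomTruth:
    """Generate the analytic ground-truth kinematic fields on ``grid``.

    Returns displacement (Lagrangian, on the reference grid), per-frame
    Eulerian velocity consistent with material-point trajectories, the
    analytic strain series g(t)·sym(∇U) and the analytic strain-rate
    series (exact chain-rule gradient of the Eulerian velocity).
    """
    A = deformation_matrix(model)
    Y, X, Z = grid.coords_mm()
    U, J = _field(model, A, Y, X, Z)
    labels, plateau, static = region_labels(grid, model)
    g = temporal_envelope(
        model.n_frames, model.ramp_start, model.ramp_end, model.release_start
    )
    T = model.n_frames
    dt_s = model.frame_interval_ms / 1000.0

    disp = g[None, None, None, :, None] * U[..., None, :]

    symJ = 0.5 * (J + np.swapaxes(J, -1, -2))
    strain = g[None, None, None, :, None, None] * symJ[..., None, :, :]

    vel = np.zeros(grid.shape + (T, 3))
    srate = np.zeros(grid.shape + (T, 3, 3))
    eye = np.eye(3)
    for t in range(T - 1):
        dg = (g[t + 1] - g[t]) / dt_s  # 1/s
        if dg == 0.0 and g[t] == 0.0:
            continue
        Yr, Xr, Zr = _invert_map(model, A, g[t], Y, X, Z)
        Ur, Jr = _field(model, A, Yr, Xr, Zr)
        vel[..., t, :] = dg * Ur / 10.0  # mm/s -> cm/s
        # Eulerian velocity gradient: dv_j/dx_i = dg * J[k,j] * dX_k/dx_i
        Fm = eye + g[t] * np.swapaxes(Jr, -1, -2)  # Fm[j, k] = dx_j/dX_k
        Fminv = np.linalg.inv(Fm)  # Fminv[k, i] = dX_k/dx_i
        G = dg * np.einsum("...ki,...kj->...ij", Fminv, Jr)
        srate[..., t, :, :] = 0.5 * (G + np.swapaxes(G, -1, -2))

    return PhantomTruth(
        grid=grid,
        model=model,
        labels=labels,
        plateau_mask=plateau,
        static_mask=static,
        envelope=g,
        displacement_mm=disp,
        velocity_cm_s=vel,
        strain=strain,
        strain_rate_per_s=srate,
        magnitude=magnitude_image(grid, labels),
    )


# ---------------------------------------------------------------------------
# Magnitude image, coil sensitivities, k-space synthesis
# ---------------------------------------------------------------------------


def magnitude_image(grid: VoxelGrid, labels: np.ndarray) -> np.ndarray:
    """Smooth leg-shaped magnitude image: elliptical object with a
    raised-cosine edge, muscle regions 20% brighter.  Smooth edges keep
    Gibbs ringing small in the synthetic k-space."""
    Y, X, _ = grid.coords_mm()
    ny, nx, _ = grid.shape
    ay = 0.47 * grid.spacing[0] * ny
    ax = 0.47 * grid.spacing[1] * nx
    rho = np.hypot(Y / ay, X / ax)
    edge0, edge1 = 0.82, 1.0
    m = np.zeros(grid.shape)
    m[rho <= edge0] = 1.0
    band = (rho > edge0) & (rho < edge1)
    m[band] = 0.5 * (1.0 + np.cos(np.pi * (rho[band] - edge0) / (edge1 - edge0)))
    m = m * (1.0 + 0.2 * (labels > 0))
    return m


def coil_sensitivities(shape_yx: tuple[int, int], n_coils: int = 8) -> np.ndarray:
    """Smooth complex coil maps: Gaussian lobes centered around the FOV
    perimeter, one per coil, with a gentle per-coil phase; normalized so the
    sum-of-squares magnitude is 1 everywhere."""
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    ny, nx = shape_yx
    yy, xx = np.meshgrid(np.arange(ny) - (ny - 1) / 2.0,
                         np.arange(nx) - (nx - 1) / 2.0, indexing="ij")
    sigma = 0.6 * max(ny, nx)
    maps = np.empty((n_coils, ny, nx), dtype=complex)
    for c in range(n_coils):
        th = 2.0 * np.pi * c / n_coils
        cy, cx = 0.6 * ny * np.cos(th), 0.6 * nx * np.sin(th)
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        phase = th + 0.2 * np.pi * (np.cos(th) * yy / ny + np.sin(th) * xx / nx)
        maps[c] = np.exp(-r2 / (2.0 * sigma**2)) * np.exp(1j * phase)
    sos = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    return maps / sos


def _cfft2(img, axes=(1, 2)):
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def encode_kspace(
    velocity_cm_s: np.ndarray,
    magnitude: np.ndarray,
    params: AcquisitionParams,
    seed: int = 0,
    noise_sd: float = 0.0,
):
    """Synthesize multi-coil undersampled VE-PC k-space from a velocity
    series and a magnitude image.

    The ideal coil-combined image of encode direction ``d`` carries phase
    π·v_d/VENC relative to the flow-compensated reference segment.  Each
    coil's k-space is the centered 2D FFT of the sensitivity-weighted
    complex image; the same per-frame ky mask is applied to every coil and
    encode segment.  Returns a :class:`~muskstrain3d.csrecon.KSpaceSet` with
    data indexed (coil, ky, kx, slice, frame, encode) and encode 0 the
    reference segment.
    """
    from .csrecon import KSpaceSet, make_mask

    if params.venc_cm_s <= 0:
        raise ValueError("venc must be positive")
    if params.n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    vel = np.asarray(velocity_cm_s, dtype=float)
    ny, nx, nz, n_frames, _ = vel.shape
    mag = np.asarray(magnitude, dtype=float)
    if mag.ndim == 3:
        mag = mag[..., None]  # broadcast over frames
    if np.any(np.abs(vel) > params.venc_cm_s):
        warnings.warn(
            "velocities exceed VENC: phase will wrap", RuntimeWarning, stacklevel=2
        )

    sens = coil_sensitivities((ny, nx), params.n_coils)
    mask = make_mask(
        n_ky=ny,
        cs_factor=params.cs_factor,
        center_fraction=params.center_fraction,
        n_frames=n_frames,
        seed=seed,
        power=params.density_power,
    )

    n_enc = 4  # reference + 3 directions
    data = np.zeros((params.n_coils, ny, nx, nz, n_frames, n_enc), dtype=complex)
    for e in range(n_enc):
        if e == 0:
            img = mag * np.ones((ny, nx, nz, n_frames))
        else:
            img = mag * np.exp(1j * np.pi * vel[..., e - 1] / params.venc_cm_s)
        # (coil, ny, nx, nz, t)
        weighted = sens[:, :, :, None, None] * img[None]
        data[..., e] = _cfft2(weighted, axes=(1, 2))
    data *= mask[None, :, None, None, :, None]

    if noise_sd > 0:
        rng = np.random.default_rng(seed + 1)
        noise = noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
        data += noise * mask[None, :, None, None, :, None]

    return KSpaceSet(data=data, mask=mask, params=params, true_sensitivities=sens)


# ---------------------------------------------------------------------------
# Force curve
# ---------------------------------------------------------------------------


def make_force_curve(
    target_mvc_percent: float,
    mvc_newtons: float,
    n_cycles: int = 26,
    noise_sd: float = 0.0,
    seed: int = 0,
    cycle_duration_s: float = 2.414,
    sample_rate_hz: float = 200.0,
    ramp_start: float = 0.05,
    ramp_end: float = 0.40,
    release_start: float = 0.60,
) -> ForceCurve:
    """Synthetic force-transducer trace for repeated isometric contractions
    at a target effort level.

    Each cycle has the same ramp–plateau–release shape as the deformation
    envelope; the noiseless per-cycle peak equals
    ``target_mvc_percent/100 × mvc_newtons``.
    """
    if not (0.0 < target_mvc_percent <= 100.0):
        raise ValueError("target_mvc_percent must lie in (0, 100]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    n = int(round(n_cycles * cycle_duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    s = np.mod(t, cycle_duration_s) / cycle_duration_s
    shape = _envelope_of_phase(s, ramp_start, ramp_end, release_start)
    peak = target_mvc_percent / 100.0 * mvc_newtons
    force = peak * shape
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        force = force + noise_sd * rng.standard_normal(n)
    force = np.clip(force, 0.0, None)
    return ForceCurve(
        time_s=t,
        force_n=force,
        target_mvc_percent=target_mvc_percent,
        sample_rate_hz=sample_rate_hz,
        cycle_duration_s=cycle_duration_s,
        n_cycles=n_cycles,
    )
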