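"""Phase-shading correction and 3D anisotropic diffusion denoising.

The diffusion filter is the classic edge-stopping scheme: an explicit
6-neighbor update in flux form,

    I ← I + δ · Σ_faces c(|∇I|) ∇I,     c(g) = 1 / (1 + (g/K)²),

iterated N times with reflecting (Neumann) boundaries.  The conductance
``c`` favors diffusion inside wide homogeneous regions and shuts it off
across strong edges.  The flux form conserves the global mean exactly, and
for δ ≤ 1/6 each update is a convex combination of neighbors so extrema are
never amplified.

Phase-shading correction fits a low-order 2D polynomial to the phase of the
reference frame over a static (non-muscle) mask and subtracts the fitted
surface from all frames of that slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiffusionParams",
    "conductance",
    "anisotropic_diffuse",
    "correct_phase_shading",
]

_MAX_STEP = 1.0 / 6.0  # explicit-scheme stability bound, 6-connected 3D


@dataclass(frozen=True)
class DiffusionParams:
    """Filter parameters: N iterations, step size δ and the edge-gradient
    sensitivity K (same units as the image gradient)."""

    n_iterations: int = 10
    step_size: float = 0.0625
    k_edge: float = 4.0

    def __post_init__(self) -> None:
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if not (0.0 < self.step_size <= _MAX_STEP):
            raise ValueError(
                f"step_size must lie in (0, {_MAX_STEP:.4f}] for stability of "
                "the explicit 6-neighbor scheme"
            )
        if self.k_edge <= 0:
            raise ValueError("k_edge must be positive")


def conductance(grad_magnitude, k_edge: float):
    """Edge-stopping conductance c(g) = 1 / (1 + (g/K)²), in (0, 1]."""
    if k_edge <= 0:
        raise ValueError("k_edge must be positive")
    g = np.asarray(grad_magnitude, dtype=float)
    if np.any(g < 0):
        raise ValueError("gradient magnitude must be non-negative")
    return 1.0 / (1.0 + (g / k_edge) ** 2)


def _diffuse_volume(vol: np.ndarray, params: DiffusionParams) -> np.ndarray:
    out = vol.astype(float, copy=True)
    for _ in range(params.n_iterations):
        update = np.zeros_like(out)
        for axis in range(3):
            d = np.diff(out, axis=axis)  # face gradients
            flux = conductance(np.abs(d), params.k_edge) * d
            # divergence of face fluxes; zero flux through the boundary
            pad = [(0, 0)] * 3
            pad[axis] = (1, 1)
            flux = np.pad(flux, pad)  # reflecting boundary: no exterior flux
            update += np.diff(flux, axis=axis)
        out += params.step_size * update
    return out


def anisotropic_diffuse(series: np.ndarray, params: DiffusionParams) -> np.ndarray:
    """Denoise a 3D volume, or a 3D(+frame)(+component) series volume by
    volume, with the 6-connected edge-stopping diffusion filter.

    Accepts arrays shaped (y, x, z), (y, x, z, t) or (y, x, z, t, d); the
    filter runs independently over the trailing axes.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim < 3 or arr.ndim > 5:
        raise ValueError("expected a (y, x, z[, t[, d]]) array")
    if any(n < 2 for n in arr.shape[:3]):
        raise ValueError("spatial dimensions must have at least 2 samples")
    if params.n_iterations == 0:
        return arr.copy()
    flat = arr.reshape(arr.shape[:3] + (-1,))
    out = np.empty_like(flat)
    for k in range(flat.shape[3]):
        out[..., k] = _diffuse_volume(flat[..., k], params)
    return out.reshape(arr.shape)


def correct_phase_shading(
    phase: np.ndarray,
    static_mask: np.ndarray,
    poly_order: int = 2,
    reference_frame: int = 0,
):
    """Remove smooth phase-shading from a (y, x, z, t) phase series.

    For each slice, a 2D polynomial of total degree ``poly_order`` is fit by
    least squares to the reference-frame phase over the static mask and
    subtracted from every frame.  Returns (corrected, fitted surfaces).
    """
    phase = np.asarray(phase, dtype=float)
    if phase.ndim != 4:
        raise ValueError("phase must be (y, x, z, t)")
    mask = np.asarray(static_mask, dtype=bool)
    if mask.shape != phase.shape[:3]:
        raise ValueError("static_mask must match the spatial shape")
    if not mask.any():
        raise ValueError("static mask is empty")
    ny, nx, nz, _ = phase.shape
    n_terms = (poly_order + 1) * (poly_order + 2) // 2
    # normalized coordinates for a well-conditioned Vandermonde matrix
    yy, xx = np.meshgrid(
        np.linspace(-1.0, 1.0, ny), np.linspace(-1.0, 1.0, nx), indexing="ij"
    )
    terms = [
        yy**i * xx**j
        for i in range(poly_order + 1)
        for j in range(poly_order + 1 - i)
    ]
    design_full = np.stack([t.ravel() for t in terms], axis=1)
    corrected = phase.copy()
    surfaces = np.zeros((ny, nx, nz))
    for z in range(nz):
        sel = mask[:, :, z].ravel()
        if sel.sum() < n_terms:
            raise ValueError(
                f"static mask of slice {z} has {int(sel.sum())} voxels but the "
                f"order-{poly_order} fit needs at least {n_terms}"
            )
        coef, *_ = np.linalg.lstsq(
            design_full[sel], phase[:, :, z, reference_frame].ravel()[sel],
            rcond=None,
        )
        surf = (design_full @ coef).reshape(ny, nx)
        surfaces[:, :, z] = surf
        corrected[:, :, z, :] -= surf[:, :, None]
    return corrected, surfaces
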