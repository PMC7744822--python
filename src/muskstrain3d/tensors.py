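"""Strain and strain-rate tensor fields, principal decomposition, invariants.

The velocity (or displacement) gradient tensor is

    F[i, j] = ∂v_j / ∂x_i

computed with central differences in the interior and one-sided differences
at the boundaries.  Symmetrizing gives the strain-rate tensor
SR = ½(F + Fᵀ) (units 1/s) or, applied to the Lagrangian displacement field
referenced to frame 1, the infinitesimal Lagrangian strain L (dimensionless;
a Green–Lagrange variant ½(F + Fᵀ + FᵀF) is available behind a flag).

Eigenvalues of the symmetric tensor are sorted ascending and labelled by the
muscle-physiology convention: the lowest (negative during contraction) is
the *fiber* strain, the highest (positive, cross-sectional expansion) is
*in-plane*, and the small intermediate one is *out-plane*.  Two rotation
invariants are computed: the maximum shear

    L_max = (2/3) √[(Lxx−Lyy)² + (Lxx−Lzz)² + (Lyy−Lzz)² + 6(Lxy²+Lxz²+Lyz²)]

and the volumetric strain L_vol = tr(L) = ∂V/V.  Strain rate is stored in
1/s; group tables conventionally report it ×10³ (milli-strain per second).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .csrecon import VelocitySeries
from .tracking import DisplacementSeries

__all__ = [
    "TensorField",
    "PrincipalDecomposition",
    "gradient_tensor",
    "symmetrize_diagonalize",
    "max_shear",
    "volumetric",
    "strain_series",
    "strain_rate_series",
    "MILLI_PER_S",
]

MILLI_PER_S = 1e3  # report strain rate ×10^3, i.e. in 10^-3 s^-1


@dataclass
class TensorField:
    """Per-voxel, per-frame symmetric 3×3 tensors, (y, x, z, t, 3, 3)."""

    tensor: np.ndarray
    kind: str  # "strain" (dimensionless) or "strain-rate" (1/s)
    spacing_mm: tuple[float, float, float]
    frame_interval_ms: float


@dataclass
class PrincipalDecomposition:
    """Sorted eigen-decomposition of a symmetric tensor field.

    ``eigenvalues[..., 0]`` is the fiber (most negative) component,
    ``[..., 1]`` out-plane, ``[..., 2]`` in-plane; ``eigenvectors[..., k]``
    is the unit eigenvector of eigenvalue k with its largest-magnitude
    component made positive.  ``max_shear``/``volumetric`` are the rotation
    invariants evaluated on the same tensors.
    """

    eigenvalues: np.ndarray  # (..., 3) ascending
    eigenvectors: np.ndarray  # (..., 3, 3), columns
    max_shear: np.ndarray  # (...)
    volumetric: np.ndarray  # (...)

    @property
    def fiber(self):
        return self.eigenvalues[..., 0]

    @property
    def out_plane(self):
        return self.eigenvalues[..., 1]

    @property
    def in_plane(self):
        return self.eigenvalues[..., 2]


def gradient_tensor(field: np.ndarray, spacing_mm) -> np.ndarray:
    """Spatial gradient tensor F[..., i, j] = ∂f_j/∂x_i of a
    (y, x, z, [t,] 3) vector field; spacing in mm per axis.

    Central differences in the interior, one-sided at boundaries (numpy
    gradient); exact for fields linear in the coordinates.
    """
    f = np.asarray(field, dtype=float)
    if f.shape[-1] != 3 or f.ndim not in (4, 5):
        raise ValueError("field must be (y, x, z, [t,] 3)")
    if any(n < 3 for n in f.shape[:3]):
        raise ValueError(
            f"need at least 3 samples along each spatial axis, got {f.shape[:3]}"
        )
    spacing = tuple(float(s) for s in spacing_mm)
    F = np.empty(f.shape[:-1] + (3, 3))
    for i in range(3):
        dfi = np.gradient(f, spacing[i], axis=i)
        F[..., i, :] = dfi
    return F


def symmetrize_diagonalize(F: np.ndarray) -> PrincipalDecomposition:
    """Symmetrize a gradient tensor field and diagonalize it.

    T = ½(F + Fᵀ) is decomposed per voxel; eigenvalues come out ascending
    (fiber, out-plane, in-plane) with deterministic eigenvector signs.
    """
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) tensors")
    if not np.isfinite(F).all():
        raise ValueError("non-finite tensor entries")
    T = 0.5 * (F + np.swapaxes(F, -1, -2))
    vals, vecs = np.linalg.eigh(T)  # ascending
    # sign convention: largest-|component| of each eigenvector positive;
    # argmax takes the first index on ties (first-axis positivity)
    comp = np.argmax(np.abs(vecs), axis=-2)
    picked = np.take_along_axis(vecs, comp[..., None, :], axis=-2)[..., 0, :]
    flip = np.where(picked < 0, -1.0, 1.0)
    vecs = vecs * flip[..., None, :]
    return PrincipalDecomposition(
        eigenvalues=vals,
        eigenvectors=vecs,
        max_shear=max_shear(T),
        volumetric=volumetric(T),
    )


def max_shear(T: np.ndarray) -> np.ndarray:
    """Maximum shear invariant of symmetric tensors (..., 3, 3):
    (2/3)·√[Σ pairwise normal differences² + 6·Σ shear components²].
    Basis independent."""
    T = np.asarray(T, dtype=float)
    d01 = T[..., 0, 0] - T[..., 1, 1]
    d02 = T[..., 0, 0] - T[..., 2, 2]
    d12 = T[..., 1, 1] - T[..., 2, 2]
    sh = T[..., 0, 1] ** 2 + T[..., 0, 2] ** 2 + T[..., 1, 2] ** 2
    return (2.0 / 3.0) * np.sqrt(d01**2 + d02**2 + d12**2 + 6.0 * sh)


def volumetric(T: np.ndarray) -> np.ndarray:
    """Volumetric invariant tr(T) = ∂V/V (sum of eigenvalues)."""
    T = np.asarray(T, dtype=float)
    return np.trace(T, axis1=-2, axis2=-1)


def strain_series(
    disp: DisplacementSeries, definition: str = "infinitesimal"
) -> TensorField:
    """Lagrangian strain tensors from tracked displacements.

    Gradients are taken on the reference (frame 1) grid, so the initial
    frame is the reference length and L(frame 1) = 0.  ``definition`` is
    ``"infinitesimal"`` (½(F + Fᵀ), the default) or ``"green-lagrange"``
    (½(F + Fᵀ + FᵀF)).
    """
    if definition not in ("infinitesimal", "green-lagrange"):
        raise ValueError("definition must be 'infinitesimal' or 'green-lagrange'")
    u = disp.displacement  # mm, (y, x, z, t, 3)
    if not np.allclose(u[..., 0, :], 0.0):
        raise ValueError("displacement must be referenced to frame 1 (zero there)")
    F = gradient_tensor(u, disp.spacing_mm)  # mm/mm
    L = 0.5 * (F + np.swapaxes(F, -1, -2))
    if definition == "green-lagrange":
        L = L + 0.5 * np.einsum("...ik,...jk->...ij", F, F)
    return TensorField(
        tensor=L,
        kind="strain",
        spacing_mm=disp.spacing_mm,
        frame_interval_ms=disp.frame_interval_ms,
    )


def strain_rate_series(vel: VelocitySeries) -> TensorField:
    """Strain-rate tensors (1/s) from per-frame velocity gradients on the
    fixed grid (values are attributed to tracked material points only at the
    ROI-reporting stage)."""
    v_mm_s = vel.velocity * 10.0  # cm/s -> mm/s
    F = gradient_tensor(v_mm_s, vel.spacing_mm)  # 1/s
    SR = 0.5 * (F + np.swapaxes(F, -1, -2))
    return TensorField(
        tensor=SR,
        kind="strain-rate",
        spacing_mm=vel.spacing_mm,
        frame_interval_ms=vel.frame_interval_ms,
    )
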