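"""Lagrangian voxel tracking through the contraction–relaxation cycle.

Every voxel of the reference (first) frame is treated as a material point
and advected through the velocity series: the position update is

    x_{t+1} = x_t + v(x_t, t) · Δt

with the velocity sampled by trilinear interpolation at the current
sub-voxel position (forward Euler; an optional midpoint/RK2 variant
resamples the same frame's field at the half step).  Displacement maps are
referenced to frame 1, so the displacement at the first frame is
identically zero.  Points that leave the field of view are clamped to the
boundary and flagged; flags propagate to downstream ROI statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .csrecon import VelocitySeries

__all__ = [
    "DisplacementSeries",
    "integrate_trajectories",
    "track",
    "cycle_closure_error",
]


@dataclass
class DisplacementSeries:
    """Material-point displacements (y, x, slice, frame, direction) in mm,
    referenced to frame 1, with tracked positions (mm) and an out-of-FOV
    flag per reference voxel."""

    displacement: np.ndarray
    positions: np.ndarray
    spacing_mm: tuple[float, float, float]
    frame_interval_ms: float
    out_of_fov: np.ndarray  # (y, x, slice) bool

    @property
    def n_frames(self) -> int:
        return self.displacement.shape[3]


def _grid_positions_mm(shape, spacing):
    axes = [np.arange(n) * d for n, d in zip(shape, spacing)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _sample_velocity(vel_frame, pos_mm, spacing):
    """Trilinear sampling of one frame's (y,x,z,3) velocity at mm positions."""
    coords = [pos_mm[..., i] / spacing[i] for i in range(3)]
    coords = np.stack([c.ravel() for c in coords], axis=0)
    out = np.empty(pos_mm.shape)
    for d in range(3):
        out[..., d] = map_coordinates(
            vel_frame[..., d], coords, order=1, mode="nearest"
        ).reshape(pos_mm.shape[:-1])
    return out


def integrate_trajectories(
    velocity_cm_s: np.ndarray,
    spacing_mm,
    frame_interval_ms: float,
    start_positions_mm: np.ndarray | None = None,
    integrator: str = "euler",
):
    """Integrate material-point trajectories through a velocity series.

    ``velocity_cm_s`` is (y, x, z, t, 3); frame t's field advances positions
    from frame t to t+1.  Returns positions (y, x, z, t, 3) in mm and the
    out-of-FOV flag.
    """
    vel = np.asarray(velocity_cm_s, dtype=float)
    if vel.ndim != 5 or vel.shape[-1] != 3:
        raise ValueError("velocity must be (y, x, z, t, 3)")
    if not np.isfinite(vel).all():
        raise ValueError("non-finite velocities")
    if frame_interval_ms <= 0:
        raise ValueError("frame interval must be positive")
    if integrator not in ("euler", "rk2"):
        raise ValueError("integrator must be 'euler' or 'rk2'")
    shape = vel.shape[:3]
    n_frames = vel.shape[3]
    spacing = tuple(float(s) for s in spacing_mm)
    # a point may wander within the extent of the boundary voxel (half a
    # voxel beyond the outermost center) before it counts as leaving the FOV
    lo = np.array([-0.5 * d for d in spacing])
    hi = np.array([(n - 0.5) * d for n, d in zip(shape, spacing)])
    dt_s = frame_interval_ms / 1000.0

    if start_positions_mm is None:
        pos = _grid_positions_mm(shape, spacing)
    else:
        pos = np.asarray(start_positions_mm, dtype=float).copy()
    positions = np.empty(shape + (n_frames, 3))
    positions[..., 0, :] = pos
    flagged = np.zeros(shape, dtype=bool)
    for t in range(n_frames - 1):
        v = _sample_velocity(vel[..., t, :], pos, spacing)  # cm/s
        step = v * 10.0 * dt_s  # mm
        if integrator == "rk2":
            v_mid = _sample_velocity(vel[..., t, :], pos + 0.5 * step, spacing)
            step = v_mid * 10.0 * dt_s
        pos = pos + step
        outside = (pos < lo) | (pos > hi)
        if outside.any():
            flagged |= outside.any(axis=-1)
            pos = np.clip(pos, lo, hi)
        positions[..., t + 1, :] = pos
    return positions, flagged


def track(vel: VelocitySeries, integrator: str = "euler") -> DisplacementSeries:
    """Track every voxel through the cycle and return Lagrangian
    displacements referenced to frame 1."""
    positions, flagged = integrate_trajectories(
        vel.velocity,
        vel.spacing_mm,
        vel.frame_interval_ms,
        integrator=integrator,
    )
    disp = positions - positions[..., :1, :]
    return DisplacementSeries(
        displacement=disp,
        positions=positions,
        spacing_mm=tuple(float(s) for s in vel.spacing_mm),
        frame_interval_ms=vel.frame_interval_ms,
        out_of_fov=flagged,
    )


def cycle_closure_error(disp: DisplacementSeries):
    """Per-voxel magnitude (mm) of the residual displacement at the final
    frame — zero for a perfectly cyclic contraction — plus summary stats."""
    err = np.linalg.norm(disp.displacement[..., -1, :], axis=-1)
    stats = {
        "median_mm": float(np.median(err)),
        "mean_mm": float(err.mean()),
        "max_mm": float(err.max()),
    }
    return err, stats
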