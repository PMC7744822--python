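"""Compressed-sensing reconstruction of undersampled multi-coil VE-PC data.

The reconstruction solves, per slice and per velocity-encode segment,

    argmin_m  ||M F S m − y||²  +  λ ||Ψ m||₁

with ``M`` the per-frame ky sampling mask, ``F`` the centered 2D Fourier
transform, ``S`` the self-calibrated coil sensitivities and ``Ψ`` a temporal
sparsifying transform.  Two stages are run: stage 1 uses the (unitary)
temporal Fourier transform, stage 2 is initialized from the stage-1 output
and uses projection onto the temporal principal components of that output.
The optimizer is nonlinear conjugate gradient (Polak–Ribière+) with a
backtracking line search and a smoothed ℓ1 penalty, the standard choice for
sparse-MRI problems of this kind.

Velocity maps are then formed by the phase-difference convention
v_d = VENC · angle(m_d · conj(m_ref)) / π.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import AcquisitionParams

__all__ = [
    "KSpaceSet",
    "CoilSensitivityMap",
    "VelocitySeries",
    "make_mask",
    "estimate_sensitivities",
    "reconstruct",
    "phase_to_velocity",
    "run_csrecon",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class KSpaceSet:
    """Multi-coil k-space, indexed (coil, ky, kx, slice, frame, encode);
    encode 0 is the flow-compensated reference segment.  ``mask`` is the
    shared per-frame ky sampling pattern (ky, frame); unsampled entries of
    ``data`` are exactly zero."""

    data: np.ndarray
    mask: np.ndarray
    params: AcquisitionParams
    true_sensitivities: np.ndarray | None = None  # phantom ground truth, if known

    def __post_init__(self) -> None:
        if self.data.ndim != 6:
            raise ValueError("k-space data must be (coil, ky, kx, slice, frame, encode)")
        if self.mask.shape != (self.data.shape[1], self.data.shape[4]):
            raise ValueError("mask must be (ky, frame)")


@dataclass
class CoilSensitivityMap:
    """Self-calibrated complex coil maps (coil, y, x, slice), sum-of-squares
    normalized on the object support and zero outside it."""

    maps: np.ndarray
    support: np.ndarray  # (y, x, slice) bool


@dataclass
class VelocitySeries:
    """Reconstructed voxel velocities (y, x, slice, frame, direction) in
    cm/s with the reference-segment magnitude image."""

    velocity: np.ndarray
    magnitude: np.ndarray
    spacing_mm: tuple[float, float, float]
    frame_interval_ms: float
    venc_cm_s: float
    wrap_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[3]


# ---------------------------------------------------------------------------
# Sampling mask
# ---------------------------------------------------------------------------


def make_mask(
    n_ky: int,
    cs_factor: float,
    center_fraction: float = 0.125,
    n_frames: int = 1,
    seed: int = 0,
    power: float = 2.0,
) -> np.ndarray:
    """Variable-density random ky undersampling mask, (n_ky, n_frames) bool.

    Each frame samples round(n_ky / cs_factor) lines: a fully sampled
    central band of round(center_fraction·n_ky) lines plus lines drawn
    without replacement with probability decaying as distance^(-power) from
    the k-space center, re-randomized per frame.
    """
    if not (1 <= cs_factor <= n_ky):
        raise ValueError("cs_factor must lie in [1, n_ky]")
    if not (0.0 < center_fraction < 1.0):
        raise ValueError("center_fraction must lie in (0, 1)")
    budget = int(round(n_ky / cs_factor))
    if cs_factor == 1:
        return np.ones((n_ky, n_frames), dtype=bool)
    n_center = max(2, int(round(center_fraction * n_ky)))
    if n_center > budget:
        raise ValueError(
            f"central band ({n_center} lines) exceeds the per-frame budget "
            f"({budget} lines) at cs_factor={cs_factor}"
        )
    center = n_ky // 2
    lo = center - n_center // 2
    hi = lo + n_center
    dist = np.abs(np.arange(n_ky) - center).astype(float)
    outer = np.ones(n_ky, dtype=bool)
    outer[lo:hi] = False
    prob = np.where(outer, np.maximum(dist, 1.0) ** (-power), 0.0)
    prob /= prob.sum()
    rng = np.random.default_rng(seed)
    mask = np.zeros((n_ky, n_frames), dtype=bool)
    mask[lo:hi, :] = True
    n_rand = budget - n_center
    idx_all = np.arange(n_ky)
    for t in range(n_frames):
        picks = rng.choice(idx_all, size=n_rand, replace=False, p=prob)
        mask[picks, t] = True
    return mask


# ---------------------------------------------------------------------------
# Self-calibrated coil sensitivities
# ---------------------------------------------------------------------------


def _cfft2(img, axes):
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def _cifft2(ksp, axes):
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def estimate_sensitivities(
    kspace: KSpaceSet, support_threshold: float = 0.1
) -> CoilSensitivityMap:
    """Self-calibrated coil maps from the densely sampled k-space center.

    The reference-segment k-space is averaged over frames (weighted by how
    often each line was sampled), restricted to the ky band sampled in every
    frame with a Hamming taper, and inverse transformed to low-resolution
    coil images; maps are the coil images normalized by their root
    sum-of-squares on the object support.
    """
    data = kspace.data
    mask = kspace.mask
    n_coil, n_ky, n_kx, n_z, n_t, _ = data.shape
    counts = mask.sum(axis=1).astype(float)  # (ky,)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(
            counts[None, :, None, None] > 0,
            data[..., 0].sum(axis=4) / counts[None, :, None, None],
            0.0,
        )  # (coil, ky, kx, z)
    always = mask.all(axis=1)
    if not always.any():
        raise ValueError("empty central band: no ky line is sampled in every frame")
    rows = np.where(always)[0]
    band = np.zeros(n_ky)
    band[rows] = np.hamming(rows.size)
    lowres = _cifft2(avg * band[None, :, None, None], axes=(1, 2))
    sos = np.sqrt((np.abs(lowres) ** 2).sum(axis=0))  # (ky->y, x, z)
    if sos.max() == 0:
        raise ValueError("all-zero object: cannot calibrate sensitivities")
    support = sos > support_threshold * sos.max()
    if not support.any():
        raise ValueError("empty object support")
    maps = np.where(support[None], lowres / np.where(sos > 0, sos, 1.0)[None], 0.0)
    return CoilSensitivityMap(maps=maps, support=support)


# ---------------------------------------------------------------------------
# Two-stage nonlinear iterative reconstruction
# ---------------------------------------------------------------------------


def _temporal_fft(m):
    return np.fft.fft(m, axis=-1, norm="ortho")


def _temporal_ifft(c):
    return np.fft.ifft(c, axis=-1, norm="ortho")


class _Objective:
    """Smoothed-ℓ1 regularized least squares for one slice/segment."""

    def __init__(self, y, mask, sens, lam, eps, basis=None):
        # y: (coil, ky, kx, t); sens: (coil, y, x); mask: (ky, t)
        self.y = y
        self.mask = mask[None, :, None, :]
        self.sens = sens[:, :, :, None]
        self.lam = lam
        self.eps = eps
        self.basis = basis  # temporal PCA basis (t, t), columns orthonormal

    def E(self, m):
        return self.mask * _cfft2(self.sens * m[None], axes=(1, 2))

    def EH(self, k):
        return (np.conj(self.sens) * _cifft2(self.mask * k, axes=(1, 2))).sum(axis=0)

    def psi(self, m):
        if self.basis is None:
            return _temporal_fft(m)
        return m @ self.basis

    def psiH(self, c):
        if self.basis is None:
            return _temporal_ifft(c)
        return c @ np.conj(self.basis.T)

    def value_parts(self, resid_k, coeffs):
        dc = float(np.vdot(resid_k, resid_k).real)
        l1 = float(np.sqrt(np.abs(coeffs) ** 2 + self.eps**2).sum())
        return dc, l1

    def grad(self, m, resid_k, coeffs):
        g = 2.0 * self.EH(resid_k)
        if self.lam > 0:
            g = g + self.lam * self.psiH(
                coeffs / np.sqrt(np.abs(coeffs) ** 2 + self.eps**2)
            )
        return g


def _nlcg(obj, m0, n_outer, n_inner, grad_tol=1e-12):
    """Polak–Ribière+ NLCG with an exact-expansion backtracking line search.

    The line search is data-consistency safeguarded: along a direction d the
    sampled-entry residual is the exact quadratic dc(t) = dc0 + b·t + a·t²,
    so steps are capped at −b/a (where dc returns to its starting value) and
    directions that would increase the residual for any positive step are
    refused.  The data-consistency residual is therefore non-increasing
    across iterations by construction, while the Armijo condition still
    guarantees descent of the full objective.

    Returns the solution and the residual ||Em − y||² recorded after each
    outer iteration.
    """
    m = m0.copy()
    Em = obj.E(m)
    resid = Em - obj.y
    coeffs = obj.psi(m)
    dc, l1 = obj.value_parts(resid, coeffs)
    f = dc + obj.lam * l1
    g = obj.grad(m, resid, coeffs)
    d = -g
    dc_history = []
    for outer in range(n_outer):
        for _ in range(n_inner):
            gnorm2 = float(np.vdot(g, g).real)
            if gnorm2 < grad_tol:
                break
            Ed = obj.E(d)
            Pd = obj.psi(d)
            # f(m + t d) = ||resid + t Ed||^2 + lam * l1(coeffs + t Pd)
            a = float(np.vdot(Ed, Ed).real)
            b = 2.0 * float(np.vdot(resid, Ed).real)
            slope0 = float(np.vdot(g, d).real)
            if slope0 >= 0 or b >= 0:
                # not a descent direction, or one that would inflate the
                # data-consistency residual: restart on the gradient
                d = -g
                Ed = obj.E(d)
                Pd = obj.psi(d)
                a = float(np.vdot(Ed, Ed).real)
                b = 2.0 * float(np.vdot(resid, Ed).real)
                slope0 = float(np.vdot(g, d).real)
                if slope0 >= 0 or b >= 0:
                    break
            # start from the exact minimizer of the quadratic part, capped
            # where dc(t) would exceed dc(0); backtrack for the l1 term
            t = -slope0 / (2.0 * a) if a > 0 else 1.0
            if a > 0:
                t = min(t, -b / a)
            accepted = False
            for _bt in range(30):
                c_new = coeffs + t * Pd
                dc_new = dc + t * b + t * t * a
                l1_new = float(np.sqrt(np.abs(c_new) ** 2 + obj.eps**2).sum())
                f_new = dc_new + obj.lam * l1_new
                if f_new <= f + 1e-4 * t * slope0:
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                break
            m = m + t * d
            resid = resid + t * Ed
            coeffs = c_new
            dc, l1, f = dc_new, l1_new, f_new
            g_new = obj.grad(m, resid, coeffs)
            beta = max(
                0.0,
                float(np.vdot(g_new, g_new - g).real) / max(float(np.vdot(g, g).real), 1e-30),
            )
            d = -g_new + beta * d
            g = g_new
        dc_history.append(dc)
    return m, np.array(dc_history)


def reconstruct(
    kspace: KSpaceSet,
    sens: CoilSensitivityMap,
    lambda1: float = 0.01,
    lambda2: float = 0.01,
    n_outer: int = 8,
    n_inner: int = 20,
    eps: float = 1e-6,
):
    """Two-stage nonlinear iterative reconstruction.

    ``lambda1``/``lambda2`` are the stage-1 (temporal FFT) and stage-2
    (temporal PCA) ℓ1 weights, relative to the peak magnitude of the
    zero-filled coil-combined image.  Returns complex images
    (y, x, slice, frame, encode) and a dict of per-stage data-consistency
    residual histories (one entry per outer iteration).
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("regularization weights must be non-negative")
    if not np.isfinite(kspace.data).all():
        raise ValueError("non-finite k-space entries")
    data = kspace.data
    n_coil, n_ky, n_kx, n_z, n_t, n_e = data.shape
    out = np.zeros((n_ky, n_kx, n_z, n_t, n_e), dtype=complex)
    history = {"stage1": [], "stage2": []}
    for z in range(n_z):
        smap = sens.maps[:, :, :, z]
        for e in range(n_e):
            y = data[:, :, :, z, :, e]
            obj = _Objective(y, kspace.mask, smap, 0.0, eps)
            scale = np.abs(obj.EH(y)).max()
            if scale == 0:
                continue
            yn = y / scale
            # stage 1: temporal FFT sparsity, from a zero estimate so the
            # early iterations are purely data-driven
            obj1 = _Objective(yn, kspace.mask, smap, lambda1, eps, basis=None)
            m1, h1 = _nlcg(obj1, np.zeros((n_ky, n_kx, n_t), dtype=complex),
                           n_outer, n_inner)
            # stage 2: temporal PCA of the stage-1 result
            profiles = m1.reshape(-1, n_t)
            _, _, vh = np.linalg.svd(profiles, full_matrices=False)
            basis = vh.conj().T  # (t, n_comp) orthonormal columns
            obj2 = _Objective(yn, kspace.mask, smap, lambda2, eps, basis=basis)
            m2, h2 = _nlcg(obj2, m1, n_outer, n_inner)
            out[:, :, z, :, e] = m2 * scale
            history["stage1"].append(h1 * scale**2)
            history["stage2"].append(h2 * scale**2)
    return out, history


# ---------------------------------------------------------------------------
# Phase-difference velocimetry
# ---------------------------------------------------------------------------


def phase_to_velocity(
    images: np.ndarray,
    venc_cm_s: float,
    spacing_mm: tuple[float, float, float],
    frame_interval_ms: float,
) -> VelocitySeries:
    """Form velocity maps from reconstructed encode-segment images.

    ``images`` is (y, x, slice, frame, encode) with encode 0 the reference;
    v_d = VENC · angle(m_d · conj(m_ref)) / π and the magnitude image is
    |m_ref|.  Voxels at the ±VENC phase limit are flagged as potential
    wraps.
    """
    images = np.asarray(images)
    if images.ndim != 5 or images.shape[-1] < 2:
        raise ValueError("images must be (y, x, slice, frame, encode) with a "
                         "reference segment plus at least one encoded segment")
    ref = images[..., 0]
    n_dir = images.shape[-1] - 1
    vel = np.empty(images.shape[:4] + (n_dir,))
    for d in range(n_dir):
        vel[..., d] = venc_cm_s * np.angle(images[..., d + 1] * np.conj(ref)) / np.pi
    wraps = np.abs(vel) >= venc_cm_s * (1.0 - 1e-9)
    return VelocitySeries(
        velocity=vel,
        magnitude=np.abs(ref),
        spacing_mm=spacing_mm,
        frame_interval_ms=frame_interval_ms,
        venc_cm_s=venc_cm_s,
        wrap_flags=wraps,
    )


def run_csrecon(
    kspace: KSpaceSet,
    spacing_mm: tuple[float, float, float],
    frame_interval_ms: float,
    lambda1: float = 0.01,
    lambda2: float = 0.01,
    n_outer: int = 8,
    n_inner: int = 20,
) -> tuple[VelocitySeries, CoilSensitivityMap, dict]:
    """Sensitivity calibration → two-stage reconstruction → velocity maps."""
    sens = estimate_sensitivities(kspace)
    images, history = reconstruct(
        kspace, sens, lambda1=lambda1, lambda2=lambda2,
        n_outer=n_outer, n_inner=n_inner,
    )
    series = phase_to_velocity(
        images, kspace.params.venc_cm_s, spacing_mm, frame_interval_ms
    )
    return series, sens, history
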