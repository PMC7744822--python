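"""End-to-end pipeline: phantom → reconstruction → preprocessing →
tracking → tensors → ROI records, with YAML configuration, HDF5/NIfTI I/O
and provenance capture (resolved config, config hash, output checksums,
structured log)."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import analysis as ana
from . import phantom as ph
from . import preprocess as pre
from . import tensors as tn
from . import tracking as tr
from .csrecon import KSpaceSet, VelocitySeries, run_csrecon

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "acquisition_arithmetic",
    "run_pipeline",
    "write_phantom_h5",
    "read_phantom_h5",
    "save_velocity_nifti",
    "load_velocity_nifti",
]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Stage parameter blocks mirror the stage modules; ``stages`` toggles
    which stages run.  ``from_yaml`` enforces the schema: unknown keys and
    missing required fields raise :class:`ConfigError` naming the field.
    """

    seed: int = 0
    stages: tuple[str, ...] = (
        "phantom", "csrecon", "preprocess", "track", "tensors", "analyze",
    )
    grid: ph.VoxelGrid = field(default_factory=ph.VoxelGrid)
    deformation: ph.DeformationModel = field(default_factory=ph.DeformationModel)
    acquisition: ph.AcquisitionParams = field(default_factory=ph.AcquisitionParams)
    diffusion: pre.DiffusionParams = field(default_factory=pre.DiffusionParams)
    shading_poly_order: int = 2
    noise_sd: float = 0.0
    lambda1: float = 0.01
    lambda2: float = 0.01
    n_outer: int = 8
    n_inner: int = 20
    integrator: str = "euler"
    strain_definition: str = "infinitesimal"
    # analysis metadata for the records this run produces
    subject: str = "phantom01"
    group: str = "young"
    target_mvc_percent: float = 60.0
    mvc_newtons: float = 330.0
    force_noise_sd: float = 0.0

    _ALLOWED = {
        "seed", "stages", "grid", "deformation", "acquisition", "diffusion",
        "shading_poly_order", "noise_sd", "lambda1", "lambda2", "n_outer",
        "n_inner", "integrator", "strain_definition", "subject", "group",
        "target_mvc_percent", "mvc_newtons", "force_noise_sd",
    }
    _REQUIRED_NESTED = (("acquisition", "venc_cm_s"),)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - cls._ALLOWED
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        for section, key in cls._REQUIRED_NESTED:
            if section in raw and key not in raw[section]:
                raise ConfigError(f"missing required field: {section}.{key}")
        kwargs = dict(raw)
        try:
            if "grid" in kwargs:
                g = kwargs["grid"]
                g = {k: tuple(v) if isinstance(v, list) else v for k, v in g.items()}
                kwargs["grid"] = ph.VoxelGrid(**g)
            if "deformation" in kwargs:
                d = dict(kwargs["deformation"])
                if "regions" in d:
                    d["regions"] = tuple(
                        ph.MuscleRegion(
                            name=r["name"],
                            center_mm=tuple(r["center_mm"]),
                            semi_axes_mm=tuple(r["semi_axes_mm"]),
                            envelope_extent=r.get("envelope_extent", 1.9),
                        )
                        for r in d["regions"]
                    )
                kwargs["deformation"] = ph.DeformationModel(**d)
            if "acquisition" in kwargs:
                a = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in kwargs["acquisition"].items()
                }
                kwargs["acquisition"] = ph.AcquisitionParams(**a)
            if "diffusion" in kwargs:
                kwargs["diffusion"] = pre.DiffusionParams(**kwargs["diffusion"])
            if "stages" in kwargs:
                kwargs["stages"] = tuple(kwargs["stages"])
        except (TypeError, ValueError) as err:
            raise ConfigError(str(err)) from err
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def resolved(self) -> dict:
        out = asdict(self)
        out["stages"] = list(self.stages)
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Acquisition arithmetic
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def acquisition_arithmetic(params: ph.AcquisitionParams) -> dict:
    """Repetitions per slice, temporal resolution and cycle duration implied
    by the acquisition parameters.

    repetitions = phase_encodes / cs_factor × partial_fov × averages
                  / views_per_segment (rounded half-up);
    temporal resolution = TR × views_per_segment × encode directions
    (rounded half-up to integer ms); cycle duration = frames × resolution.
    """
    if params.views_per_segment <= 0:
        raise ValueError("views_per_segment must be positive")
    reps = (
        params.matrix[0]
        / params.cs_factor
        * params.partial_fov
        * params.n_averages
        / params.views_per_segment
    )
    tres = params.tr_ms * params.views_per_segment * params.n_encode_directions
    tres_ms = _round_half_up(tres)
    return {
        "repetitions_per_slice": _round_half_up(reps),
        "temporal_resolution_ms": tres_ms,
        "cycle_duration_s": params.n_frames * tres_ms / 1000.0,
    }


# ---------------------------------------------------------------------------
# HDF5 / NIfTI I/O
# ---------------------------------------------------------------------------


def write_phantom_h5(path, truth: ph.PhantomTruth, kspace: KSpaceSet,
                     force: ph.ForceCurve) -> None:
    """Phantom dataset layout: /kspace (coil, ky, kx, slice, frame, encode),
    /mask (ky, frame), /truth/{velocity,displacement,strain,strain_rate,
    labels,magnitude}, /force/{time,force}."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kspace.data)
        f.create_dataset("mask", data=kspace.mask)
        g = f.create_group("truth")
        g.create_dataset("velocity", data=truth.velocity_cm_s)
        g.create_dataset("displacement", data=truth.displacement_mm)
        g.create_dataset("strain", data=truth.strain)
        g.create_dataset("strain_rate", data=truth.strain_rate_per_s)
        g.create_dataset("labels", data=truth.labels)
        g.create_dataset("plateau_mask", data=truth.plateau_mask)
        g.create_dataset("static_mask", data=truth.static_mask)
        g.create_dataset("magnitude", data=truth.magnitude)
        fg = f.create_group("force")
        fg.create_dataset("time", data=force.time_s)
        fg.create_dataset("force", data=force.force_n)
        fg.attrs["target_mvc_percent"] = force.target_mvc_percent
        fg.attrs["sample_rate_hz"] = force.sample_rate_hz
        fg.attrs["cycle_duration_s"] = force.cycle_duration_s
        fg.attrs["n_cycles"] = force.n_cycles
        f.attrs["venc_cm_s"] = kspace.params.venc_cm_s
        f.attrs["spacing_mm"] = truth.grid.spacing
        f.attrs["frame_interval_ms"] = truth.frame_interval_ms
        f.attrs["cs_factor"] = kspace.params.cs_factor
        f.attrs["n_coils"] = kspace.params.n_coils


def read_phantom_h5(path):
    """Read back a phantom dataset; returns (kspace_set, truth_arrays,
    force_curve, attrs)."""
    with h5py.File(path, "r") as f:
        attrs = dict(f.attrs)
        params = ph.AcquisitionParams(
            venc_cm_s=float(attrs["venc_cm_s"]),
            cs_factor=float(attrs["cs_factor"]),
            n_coils=int(attrs["n_coils"]),
        )
        kset = KSpaceSet(data=f["kspace"][()], mask=f["mask"][()], params=params)
        truth = {k: f["truth"][k][()] for k in f["truth"]}
        fg = f["force"]
        force = ph.ForceCurve(
            time_s=fg["time"][()],
            force_n=fg["force"][()],
            target_mvc_percent=float(fg.attrs["target_mvc_percent"]),
            sample_rate_hz=float(fg.attrs["sample_rate_hz"]),
            cycle_duration_s=float(fg.attrs["cycle_duration_s"]),
            n_cycles=int(fg.attrs["n_cycles"]),
        )
    return kset, truth, force, attrs


def _affine(spacing_mm):
    return np.diag(list(spacing_mm) + [1.0])


def save_velocity_nifti(series: VelocitySeries, out_dir) -> list:
    """One 4D NIfTI per encode direction plus the magnitude series."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(series.spacing_mm)
    written = []
    for d, name in enumerate(("vy", "vx", "vz")):
        img = nib.Nifti1Image(series.velocity[..., d], aff)
        img.header.set_xyzt_units("mm", "msec")
        img.header["pixdim"][4] = series.frame_interval_ms
        p = out_dir / f"velocity_{name}.nii"
        nib.save(img, p)
        written.append(p)
    mag = nib.Nifti1Image(series.magnitude, aff)
    p = out_dir / "magnitude.nii"
    nib.save(mag, p)
    written.append(p)
    return written


def load_velocity_nifti(in_dir, venc_cm_s: float,
                        frame_interval_ms: float) -> VelocitySeries:
    in_dir = Path(in_dir)
    vols = []
    for name in ("vy", "vx", "vz"):
        img = nib.load(in_dir / f"velocity_{name}.nii")
        vols.append(np.asarray(img.dataobj))
        spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    mag = np.asarray(nib.load(in_dir / "magnitude.nii").dataobj)
    return VelocitySeries(
        velocity=np.stack(vols, axis=-1),
        magnitude=mag,
        spacing_mm=spacing,
        frame_interval_ms=frame_interval_ms,
        venc_cm_s=venc_cm_s,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage '{stage}' failed: {err}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the configured stages, writing all artifacts under ``out_dir``.

    Returns a dict of in-memory results keyed by stage.  Identical config
    and seed produce identical outputs; the resolved config (with its hash)
    and a checksum manifest are written alongside.
    """
    order = ("phantom", "csrecon", "preprocess", "track", "tensors", "analyze")
    enabled = [s for s in order if s in config.stages]
    unknown = set(config.stages) - set(order)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    # each stage consumes its predecessor's in-memory outputs
    if enabled != list(order[: len(enabled)]):
        raise ConfigError("enabled stages must form a prefix of the pipeline: "
                          f"{order}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = []
    results: dict = {}

    def _log(stage, msg):
        line = f"[{stage}] {msg}"
        log_lines.append(line)

    cfg_hash = config.config_hash()
    with open(out_dir / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump({"config_hash": cfg_hash, **config.resolved()}, fh)
    _log("config", f"hash={cfg_hash}")

    def _run(stage, fn):
        if stage not in config.stages:
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as err:  # pragma: no cover - error path
            (out_dir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
            raise StageError(stage, err) from err
        _log(stage, f"done in {time.perf_counter() - t0:.2f}s")

    def _phantom():
        truth = ph.make_deformation(config.deformation, config.grid)
        kset = ph.encode_kspace(
            truth.velocity_cm_s, truth.magnitude, config.acquisition,
            seed=config.seed, noise_sd=config.noise_sd,
        )
        force = ph.make_force_curve(
            config.target_mvc_percent, config.mvc_newtons,
            n_cycles=26, noise_sd=config.force_noise_sd, seed=config.seed,
            cycle_duration_s=config.deformation.cycle_duration_s,
        )
        write_phantom_h5(out_dir / "phantom.h5", truth, kset, force)
        results["phantom"] = {"truth": truth, "kspace": kset, "force": force}

    def _csrecon():
        kset = results["phantom"]["kspace"]
        truth = results["phantom"]["truth"]
        series, sens, history = run_csrecon(
            kset, truth.grid.spacing, truth.frame_interval_ms,
            lambda1=config.lambda1, lambda2=config.lambda2,
            n_outer=config.n_outer, n_inner=config.n_inner,
        )
        save_velocity_nifti(series, out_dir / "velocity")
        results["csrecon"] = {"series": series, "sens": sens, "history": history}

    def _preprocess():
        series = results["csrecon"]["series"]
        truth = results["phantom"]["truth"]
        sens = results["csrecon"]["sens"]
        # static tissue: solid object voxels (phase is only meaningful where
        # the magnitude is substantial) outside every deformation envelope
        # (muscle + its boundary-shear layer)
        mag0 = series.magnitude[..., 0]
        static = (
            sens.support & truth.static_mask & (mag0 > 0.5 * mag0.max())
        )
        vel = series.velocity.copy()
        if static.sum() >= (config.shading_poly_order + 1) * (config.shading_poly_order + 2) // 2:
            for d in range(3):
                vel[..., d], _ = pre.correct_phase_shading(
                    vel[..., d], static, config.shading_poly_order
                )
        vel = pre.anisotropic_diffuse(vel, config.diffusion)
        denoised = VelocitySeries(
            velocity=vel, magnitude=series.magnitude,
            spacing_mm=series.spacing_mm,
            frame_interval_ms=series.frame_interval_ms,
            venc_cm_s=series.venc_cm_s,
        )
        save_velocity_nifti(denoised, out_dir / "velocity_denoised")
        results["preprocess"] = {"series": denoised}

    def _track():
        series = results["preprocess"]["series"]
        disp = tr.track(series, integrator=config.integrator)
        closure, stats = tr.cycle_closure_error(disp)
        aff = _affine(disp.spacing_mm)
        nib.save(nib.Nifti1Image(closure, aff), out_dir / "closure_error.nii")
        _log("track", f"closure median {stats['median_mm']:.4f} mm")
        results["track"] = {"displacement": disp, "closure_stats": stats}

    def _tensors():
        series = results["preprocess"]["series"]
        disp = results["track"]["displacement"]
        L = tn.strain_series(disp, definition=config.strain_definition)
        SR = tn.strain_rate_series(series)
        pd_L = tn.symmetrize_diagonalize(L.tensor)
        pd_SR = tn.symmetrize_diagonalize(SR.tensor)
        aff = _affine(series.spacing_mm)
        for name, arr in (
            ("L_fiber", pd_L.fiber), ("L_out_plane", pd_L.out_plane),
            ("L_in_plane", pd_L.in_plane), ("L_max", pd_L.max_shear),
            ("L_vol", pd_L.volumetric),
            ("SR_fiber", pd_SR.fiber), ("SR_out_plane", pd_SR.out_plane),
            ("SR_in_plane", pd_SR.in_plane), ("SR_max", pd_SR.max_shear),
        ):
            nib.save(nib.Nifti1Image(arr, aff), out_dir / f"{name}.nii")
        with h5py.File(out_dir / "tensors.h5", "w") as f:
            f.create_dataset("strain", data=L.tensor)
            f.create_dataset("strain_rate", data=SR.tensor)
        results["tensors"] = {"strain": L, "strain_rate": SR,
                              "pd_strain": pd_L, "pd_strain_rate": pd_SR}

    def _analyze():
        truth = results["phantom"]["truth"]
        force = results["phantom"]["force"]
        disp = results["track"]["displacement"]
        pd_L = results["tensors"]["pd_strain"]
        pd_SR = results["tensors"]["pd_strain_rate"]
        n_frames = config.deformation.n_frames
        force_frames = ana.resample_force_to_frames(
            force, n_frames, truth.frame_interval_ms
        )
        grid = config.grid
        offsets = [(n - 1) / 2.0 * d for n, d in zip(grid.shape[:2], grid.spacing[:2])]
        rows = []
        for region in config.deformation.regions:
            roi = ana.ROISpec(
                muscle=region.name,
                center_mm=(region.center_mm[0] + offsets[0],
                           region.center_mm[1] + offsets[1]),
            )
            sr_course = np.array([
                ana.roi_extract(pd_SR.fiber[..., t], roi, grid.spacing,
                                exclude_mask=disp.out_of_fov)[0]
                for t in range(n_frames)
            ])
            sr_frame, strain_frame = ana.peak_frames(force_frames, sr_course)
            record = {
                "subject": config.subject,
                "group": config.group,
                "mvc_percent": config.target_mvc_percent,
                "muscle": region.name,
                "force_n": float(force_frames.max()),
                "sr_peak_frame": sr_frame,
                "strain_peak_frame": strain_frame,
            }
            maps = {
                "SR_fiber": pd_SR.fiber[..., sr_frame] * tn.MILLI_PER_S,
                "SR_out_plane": pd_SR.out_plane[..., sr_frame] * tn.MILLI_PER_S,
                "SR_in_plane": pd_SR.in_plane[..., sr_frame] * tn.MILLI_PER_S,
                "SR_max": pd_SR.max_shear[..., sr_frame] * tn.MILLI_PER_S,
                "L_fiber": pd_L.fiber[..., strain_frame],
                "L_out_plane": pd_L.out_plane[..., strain_frame],
                "L_in_plane": pd_L.in_plane[..., strain_frame],
                "L_max": pd_L.max_shear[..., strain_frame],
                "L_vol": pd_L.volumetric[..., strain_frame],
            }
            for name, arr in maps.items():
                mean, sd, n = ana.roi_extract(
                    arr, roi, grid.spacing, exclude_mask=disp.out_of_fov
                )
                record[name] = mean
                record[name + "_sd"] = sd
                record["n_voxels"] = n
            rows.append(record)
        records = pd.DataFrame(rows)
        records.to_csv(out_dir / "records.csv", index=False)
        results["analyze"] = {"records": records}

    _run("phantom", _phantom)
    _run("csrecon", _csrecon)
    _run("preprocess", _preprocess)
    _run("track", _track)
    _run("tensors", _tensors)
    _run("analyze", _analyze)

    manifest = {
        "config_hash": cfg_hash,
        "files": {
            p.name: _sha256(p)
            for p in sorted(out_dir.rglob("*"))
            if p.is_file() and p.suffix in {".h5", ".nii", ".csv"}
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    (out_dir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    results["manifest"] = manifest
    return results
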