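"""NIfTI + JSON-sidecar layout for series and derived fields.

A phase-contrast series is stored as four 4D NIfTI files (magnitude plus one
phase volume per encoding direction) with a JSON sidecar carrying VENC,
heart rate, gating and voxel geometry; a velocity or derived field is a
single 5D NIfTI (x, y, z, t, component) with its own sidecar. Affines are
diagonal in the voxel spacing — phantom space has no anatomical orientation.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .fields import DerivedField4D, PhaseContrastSeries, VelocityField4D

__all__ = [
    "write_series", "read_series", "write_velocity", "read_velocity",
    "write_derived", "read_derived",
]

_DIRS = ("x", "y", "z")


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def _save(path: Path, data: np.ndarray, voxel_size: float) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), _affine(voxel_size)), str(path))


def write_series(directory: str | Path, series: PhaseContrastSeries, extra: dict | None = None) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _save(d / "magnitude.nii", series.magnitude, series.voxel_size)
    for i, ax in enumerate(_DIRS):
        _save(d / f"phase_{ax}.nii", series.phase[..., i], series.voxel_size)
    sidecar = {
        "venc_cm_s": series.venc.tolist(),
        "heart_rate_bpm": series.heart_rate,
        "n_phases": series.n_phases,
        "voxel_size_mm": series.voxel_size,
    }
    if extra:
        sidecar.update(extra)
    (d / "series.json").write_text(json.dumps(sidecar, indent=2))
    return d


def read_series(directory: str | Path) -> PhaseContrastSeries:
    d = Path(directory)
    meta = json.loads((d / "series.json").read_text())
    magnitude = np.asarray(nib.load(str(d / "magnitude.nii")).dataobj, dtype=float)
    phase = np.stack(
        [np.asarray(nib.load(str(d / f"phase_{ax}.nii")).dataobj, dtype=float) for ax in _DIRS],
        axis=-1,
    )
    return PhaseContrastSeries(
        magnitude=magnitude, phase=phase,
        venc=np.asarray(meta["venc_cm_s"], dtype=float),
        voxel_size=float(meta["voxel_size_mm"]),
        heart_rate=float(meta["heart_rate_bpm"]),
    )


def write_velocity(path: str | Path, vf: VelocityField4D, extra: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _save(path, vf.v, vf.voxel_size)
    sidecar = {
        "units": "cm/s",
        "voxel_size_mm": vf.voxel_size,
        "phase_duration_s": vf.phase_duration,
    }
    if vf.mask is not None:
        _save(path.with_name(path.stem + "_mask.nii"), vf.mask.astype(np.uint8), vf.voxel_size)
        sidecar["mask"] = path.stem + "_mask.nii"
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_velocity(path: str | Path) -> VelocityField4D:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    v = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    mask = None
    if "mask" in meta:
        mask = np.asarray(
            nib.load(str(path.with_name(meta["mask"]))).dataobj
        ).astype(bool)
    return VelocityField4D(
        v=v, voxel_size=float(meta["voxel_size_mm"]),
        phase_duration=float(meta["phase_duration_s"]), mask=mask,
    )


def write_derived(path: str | Path, fld: DerivedField4D, extra: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _save(path, fld.values, fld.voxel_size)
    _save(path.with_name(path.stem + "_valid.nii"), fld.valid.astype(np.uint8), fld.voxel_size)
    sidecar = {
        "units": fld.units,
        "voxel_size_mm": fld.voxel_size,
        "phase_duration_s": fld.phase_duration,
        "valid": path.stem + "_valid.nii",
    }
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_derived(path: str | Path) -> DerivedField4D:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    values = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    valid = np.asarray(nib.load(str(path.with_name(meta["valid"]))).dataobj).astype(bool)
    return DerivedField4D(
        values=values, units=meta["units"],
        voxel_size=float(meta["voxel_size_mm"]),
        phase_duration=float(meta["phase_duration_s"]), valid=valid,
    )
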