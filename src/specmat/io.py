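"""Persistence: NIfTI volumes with structured-text sidecars.

Volumes (labels, concentration maps, per-bin HU images, predicted material
maps) are written as NIfTI-1 files; everything non-voxel (seeds, insert
specs, protocol constants, fitted models) goes into JSON sidecars so a run
directory is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .isonoise import NoiseModel
from .linear import SensitivityModel
from .phantoms import InsertSpec, MaterialVolume
from .simulate import SpectralAcquisition

__all__ = [
    "save_material_volume",
    "load_material_volume",
    "save_acquisition",
    "load_acquisition",
    "save_noise_model",
    "load_noise_model",
    "save_sensitivity_model",
    "load_sensitivity_model",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"__insert__": dataclasses.asdict(obj)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _affine(pixel_cm: float, slice_mm: float) -> np.ndarray:
    # voxel axes (z, y, x) -> mm world spacing
    return np.diag([pixel_cm * 10.0, pixel_cm * 10.0, slice_mm, 1.0])


def _save_nifti(path: Path, array: np.ndarray, pixel_cm: float, slice_mm: float):
    # store as (x, y, z) for NIfTI convention
    data = np.ascontiguousarray(np.moveaxis(array, 0, -1))
    nib.save(nib.Nifti1Image(data, _affine(pixel_cm, slice_mm)), str(path))


def _load_nifti(path: Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.moveaxis(np.asarray(img.dataobj), -1, 0)


def save_material_volume(volume: MaterialVolume, prefix: str | Path) -> None:
    """Write ``<prefix>_labels.nii``, per-material maps and a JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    px, sm = volume.pixel_cm, volume.slice_mm
    _save_nifti(prefix.with_name(prefix.name + "_labels.nii"),
                volume.labels.astype(np.int16), px, sm)
    for mat, arr in volume.concentrations.items():
        _save_nifti(prefix.with_name(f"{prefix.name}_{mat}.nii"), arr, px, sm)
    sidecar = {
        "fov_cm": volume.fov_cm,
        "slice_mm": volume.slice_mm,
        "uniform_z": volume.uniform_z,
        "materials": sorted(volume.concentrations),
        "meta": volume.meta,
    }
    prefix.with_name(prefix.name + "_meta.json").write_text(
        json.dumps(sidecar, default=_jsonable, indent=1)
    )


def load_material_volume(prefix: str | Path) -> MaterialVolume:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_name(prefix.name + "_meta.json").read_text())
    labels = _load_nifti(prefix.with_name(prefix.name + "_labels.nii")).astype(np.int8)
    conc = {
        mat: _load_nifti(prefix.with_name(f"{prefix.name}_{mat}.nii")).astype(
            np.float32
        )
        for mat in sidecar["materials"]
    }
    meta = sidecar["meta"]
    if "inserts" in meta:
        meta["inserts"] = [
            InsertSpec(**{**d["__insert__"],
                          "center_cm": tuple(d["__insert__"]["center_cm"])})
            for d in meta["inserts"]
        ]
    return MaterialVolume(
        labels=labels,
        concentrations=conc,
        fov_cm=sidecar["fov_cm"],
        slice_mm=sidecar["slice_mm"],
        meta=meta,
        uniform_z=sidecar["uniform_z"],
    )


def save_acquisition(acq: SpectralAcquisition, prefix: str | Path) -> None:
    """Write ``<prefix>_binlow.nii`` / ``_binhigh.nii`` + metadata sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for name, arr in acq.hu.items():
        _save_nifti(prefix.with_name(f"{prefix.name}_bin{name}.nii"),
                    arr, acq.pixel_cm, acq.slice_mm)
    sidecar = {
        "recon_fov_cm": acq.recon_fov_cm,
        "slice_mm": acq.slice_mm,
        "bins": sorted(acq.hu),
        "meta": acq.meta,
    }
    prefix.with_name(prefix.name + "_meta.json").write_text(
        json.dumps(sidecar, default=_jsonable, indent=1)
    )


def load_acquisition(prefix: str | Path) -> SpectralAcquisition:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_name(prefix.name + "_meta.json").read_text())
    hu = {
        name: _load_nifti(prefix.with_name(f"{prefix.name}_bin{name}.nii")).astype(
            np.float32
        )
        for name in sidecar["bins"]
    }
    return SpectralAcquisition(
        hu=hu,
        recon_fov_cm=sidecar["recon_fov_cm"],
        slice_mm=sidecar["slice_mm"],
        meta=sidecar["meta"],
    )


def save_noise_model(model: NoiseModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "coeffs": {k: list(v) for k, v in model.coeffs.items()},
                "diagnostics": model.diagnostics,
                "provenance": model.provenance,
            },
            default=_jsonable,
            indent=1,
        )
    )


def load_noise_model(path: str | Path) -> NoiseModel:
    d = json.loads(Path(path).read_text())
    return NoiseModel(
        coeffs={k: tuple(v) for k, v in d["coeffs"].items()},
        diagnostics=d["diagnostics"],
        provenance=d["provenance"],
    )


def save_sensitivity_model(model: SensitivityModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "gamma": model.gamma.tolist(),
                "materials": list(model.materials),
                "bins": list(model.bins),
                "residual_rms": model.residual_rms,
                "condition_number": model.condition_number,
                "calibration": model.calibration,
            },
            default=_jsonable,
            indent=1,
        )
    )


def load_sensitivity_model(path: str | Path) -> SensitivityModel:
    d = json.loads(Path(path).read_text())
    return SensitivityModel(
        gamma=np.asarray(d["gamma"], dtype=float),
        materials=tuple(d["materials"]),
        bins=tuple(d["bins"]),
        residual_rms=d["residual_rms"],
        condition_number=d["condition_number"],
        calibration=d["calibration"],
    )
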