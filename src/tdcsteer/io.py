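"""File formats: NIfTI label/angle/norm volumes, HDF5 basis sets, JSON results.

Conventions stamped into every output: voxel indices are 0-based with axis
order (x, y, z), world units mm, current densities mA/cm^2, weights mA.
Label volumes round-trip losslessly; tissue names travel in a JSON sidecar
(``<stem>.labels.json``) next to the NIfTI file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from . import __version__
from .errors import ConfigurationError, TdcsteerError
from .field_ops import CurrentDensityField
from .forward import BasisSet
from .head_model import AnisotropyField, TissueLabelVolume
from .montage import Montage
from .units import A_m2_to_mA_cm2

__all__ = [
    "read_label_volume",
    "write_label_volume",
    "read_angle_volume",
    "write_angle_volume",
    "save_basis",
    "load_basis",
    "write_norm_nifti",
    "write_current_density_nifti",
    "write_result_json",
    "file_sha256",
]

_CONVENTIONS = "0-based (x,y,z) voxels; mm; mA; mA/cm^2"


class FormatError(TdcsteerError, ValueError):
    """A file's contents do not match the expected format."""


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _sidecar(path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return p.with_name(name + ".labels.json")


def write_label_volume(volume: TissueLabelVolume, path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.labels.astype(np.int16), affine)
    img.header["descrip"] = _CONVENTIONS.encode()[:79]
    nib.save(img, str(path))
    with open(_sidecar(path), "w") as fh:
        json.dump({str(k): v for k, v in volume.label_names.items()}, fh, indent=1)


def read_label_volume(path, label_names=None) -> TissueLabelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label volume not found: {path}")
    img = nib.load(str(path))
    if not np.issubdtype(img.get_data_dtype(), np.integer):
        raise FormatError(
            f"label volume must have integer data, got {img.get_data_dtype()}"
        )
    data = np.asarray(img.dataobj).astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if label_names is None:
        sidecar = _sidecar(path)
        if sidecar.exists():
            with open(sidecar) as fh:
                label_names = {int(k): v for k, v in json.load(fh).items()}
        else:
            label_names = {int(l): f"label_{int(l)}" for l in np.unique(data) if l != 0}
    return TissueLabelVolume(labels=data, spacing=spacing, label_names=label_names)


def write_angle_volume(aniso: AnisotropyField, spacing, path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(aniso.angles.astype(np.float32), affine), str(path))


def read_angle_volume(path) -> AnisotropyField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError("angle volume must be 4D with 3 components")
    return AnisotropyField(angles=data)


def save_basis(basis: BasisSet, path, metadata: dict | None = None) -> None:
    """Persist a basis set (fields + montage + provenance) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("potentials", data=basis.potentials, compression="gzip")
        f.attrs["node_shape"] = basis.node_shape
        f.attrs["spacing_mm"] = basis.spacing_mm
        f.attrs["injected_current_A"] = basis.injected_current_A
        f.attrs["solver_tol"] = basis.solver_tol
        f.attrs["montage_json"] = json.dumps(basis.montage.to_dict())
        f.attrs["tool_version"] = __version__
        f.attrs["conventions"] = _CONVENTIONS
        for k, v in (metadata or {}).items():
            f.attrs[f"meta_{k}"] = v


def load_basis(path, volume: TissueLabelVolume) -> BasisSet:
    """Load a basis set; the montage is rebound to ``volume``'s surface."""
    with h5py.File(path, "r") as f:
        potentials = f["potentials"][...]
        node_shape = tuple(int(x) for x in f.attrs["node_shape"])
        spacing = tuple(float(x) for x in f.attrs["spacing_mm"])
        injected = float(f.attrs["injected_current_A"])
        tol = float(f.attrs["solver_tol"])
        montage = Montage.from_dict(json.loads(f.attrs["montage_json"]), volume)
    if node_shape != tuple(s + 1 for s in volume.shape):
        raise ConfigurationError("basis node grid does not match the supplied volume")
    return BasisSet(
        potentials=potentials,
        montage=montage,
        node_shape=node_shape,
        spacing_mm=spacing,
        injected_current_A=injected,
        solver_tol=tol,
    )


def write_norm_nifti(field: CurrentDensityField, path) -> None:
    """Scalar current-density-norm volume, mA/cm^2."""
    affine = np.diag(list(field.spacing_mm) + [1.0])
    img = nib.Nifti1Image(A_m2_to_mA_cm2(field.norm).astype(np.float32), affine)
    img.header["descrip"] = b"|J| in mA/cm^2"
    nib.save(img, str(path))


def write_current_density_nifti(field: CurrentDensityField, path) -> None:
    """4D (x, y, z, component) current-density volume, mA/cm^2."""
    affine = np.diag(list(field.spacing_mm) + [1.0])
    img = nib.Nifti1Image(A_m2_to_mA_cm2(field.J).astype(np.float32), affine)
    img.header["descrip"] = b"J components in mA/cm^2"
    nib.save(img, str(path))


def write_result_json(result, path, metadata: dict | None = None) -> None:
    payload = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    payload["provenance"] = {
        "tool_version": __version__,
        "conventions": _CONVENTIONS,
        **(metadata or {}),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
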