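"""Segmented head representation and conductivity tensor construction.

The head is a labeled voxel volume (label 0 = air/exterior) with physical
spacing, plus a table mapping tissue labels to conductivities.  Isotropic
tissues get a scalar sigma; anisotropic tissues (white matter) carry a
longitudinal/transverse pair and a per-voxel orientation given as Euler
rotation angles.  The per-voxel conductivity tensor is

    D = A^T D* A,   D* = diag(sigma_l, sigma_t, sigma_t),   A = Rz @ Ry @ Rx,

so the local longitudinal axis is the x-axis before rotation.  Conductivities
are S/m, spacing is mm (converted to metres only inside the solver).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy import ndimage

from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "TissueLabelVolume",
    "ConductivityTable",
    "AnisotropyField",
    "ConductivityTensorField",
    "BoundaryFaces",
    "build_tensor",
    "rotation_matrix",
    "assemble_tensor_field",
    "validate_model",
    "boundary_faces",
    "default_conductivity_table",
]

AIR_LABEL = 0


@dataclass
class TissueLabelVolume:
    """3D integer tissue-label grid with physical voxel spacing (mm)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    label_names: Mapping[int, str]

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels)
        if self.labels.ndim != 3:
            raise InvalidParameterError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InvalidParameterError("labels must have an integer dtype")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError("spacing must be three positive mm values")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.label_names) - {AIR_LABEL}
        if missing:
            raise ConfigurationError(f"labels {sorted(missing)} missing from label_names")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def air_mask(self) -> np.ndarray:
        return self.labels == AIR_LABEL

    @property
    def nonair_mask(self) -> np.ndarray:
        return self.labels != AIR_LABEL

    def base_plane_index(self) -> int:
        """Index of the lowest z-slice containing non-air voxels (the caudal base)."""
        nz = self.nonair_mask.any(axis=(0, 1))
        if not nz.any():
            raise ConfigurationError("volume contains no non-air voxels")
        return int(np.argmax(nz))

    def voxel_centers_mm(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Physical centers (mm) of voxels selected by ``mask`` (default: all)."""
        if mask is None:
            mask = np.ones(self.shape, dtype=bool)
        idx = np.argwhere(mask)
        return (idx + 0.5) * np.asarray(self.spacing)

    def centroid_mm(self) -> np.ndarray:
        return self.voxel_centers_mm(self.nonair_mask).mean(axis=0)

    def region_mask(self, labels) -> np.ndarray:
        labels = np.atleast_1d(labels)
        return np.isin(self.labels, labels)


@dataclass(frozen=True)
class ConductivityEntry:
    """Conductivity of one tissue: scalar, or longitudinal/transverse pair."""

    sigma_longitudinal: float
    sigma_transverse: float
    anisotropic: bool = False

    def __post_init__(self):
        sl, st = self.sigma_longitudinal, self.sigma_transverse
        if not (np.isfinite(sl) and np.isfinite(st)):
            raise InvalidParameterError("conductivities must be finite")
        if sl < 0 or st < 0:
            raise InvalidParameterError("conductivities must be non-negative")
        if self.anisotropic:
            if not sl >= st > 0:
                raise InvalidParameterError(
                    "anisotropic entries require sigma_l >= sigma_t > 0"
                )

    @property
    def isotropic_sigma(self) -> float:
        if self.anisotropic:
            raise ConfigurationError("entry is anisotropic; no single sigma")
        return self.sigma_longitudinal

    @classmethod
    def isotropic(cls, sigma: float) -> "ConductivityEntry":
        return cls(float(sigma), float(sigma), anisotropic=False)


class ConductivityTable:
    """Tissue-name keyed conductivity table (S/m)."""

    def __init__(self, entries: Mapping[str, ConductivityEntry]):
        self.entries = dict(entries)
        if "air" in self.entries and self.entries["air"].sigma_longitudinal != 0.0:
            raise InvalidParameterError("air conductivity must be exactly 0")

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> ConductivityEntry:
        return self.entries[name]

    def entry_for_label(self, label: int, label_names: Mapping[int, str]) -> ConductivityEntry:
        if label == AIR_LABEL:
            return ConductivityEntry(0.0, 0.0, anisotropic=False)
        name = label_names.get(label)
        if name is None or name not in self.entries:
            raise ConfigurationError(f"label {label} ({name!r}) not in conductivity table")
        return self.entries[name]

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Mapping]) -> "ConductivityTable":
        entries = {}
        for name, spec in raw.items():
            if "sigma" in spec:
                entries[name] = ConductivityEntry.isotropic(float(spec["sigma"]))
            else:
                entries[name] = ConductivityEntry(
                    float(spec["sigma_longitudinal"]),
                    float(spec["sigma_transverse"]),
                    anisotropic=bool(spec.get("anisotropic", True)),
                )
        return cls(entries)

    @classmethod
    def from_yaml(cls, path) -> "ConductivityTable":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_mapping(self) -> dict:
        out = {}
        for name, e in self.entries.items():
            if e.anisotropic:
                out[name] = {
                    "sigma_longitudinal": e.sigma_longitudinal,
                    "sigma_transverse": e.sigma_transverse,
                    "anisotropic": True,
                }
            else:
                out[name] = {"sigma": e.sigma_longitudinal}
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=True)


def default_conductivity_table() -> ConductivityTable:
    """The package's shipped low-frequency tissue conductivity defaults."""
    with resources.files("tdcsteer.data").joinpath("conductivities.yaml").open() as fh:
        return ConductivityTable.from_mapping(yaml.safe_load(fh))


@dataclass
class AnisotropyField:
    """Per-voxel Euler angles (radians, about x, y, z) for anisotropic tissue."""

    angles: np.ndarray  # (nx, ny, nz, 3)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 4 or self.angles.shape[-1] != 3:
            raise InvalidParameterError("angles must have shape (nx, ny, nz, 3)")
        if not np.isfinite(self.angles).all():
            raise InvalidParameterError("angles must be finite")


@dataclass
class ConductivityTensorField:
    """Per-voxel symmetric 3x3 conductivity tensors (S/m)."""

    tensors: np.ndarray  # (nx, ny, nz, 3, 3)
    spacing: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def components(self, mask: np.ndarray) -> np.ndarray:
        """Unique components (xx, yy, zz, xy, xz, yz) for voxels in ``mask``."""
        t = self.tensors[mask]
        return np.stack(
            [t[:, 0, 0], t[:, 1, 1], t[:, 2, 2], t[:, 0, 1], t[:, 0, 2], t[:, 1, 2]],
            axis=1,
        )


def rotation_matrix(angles) -> np.ndarray:
    """Composite rotation A = Rz @ Ry @ Rx for Euler angles (ax, ay, az)."""
    ax, ay, az = (float(a) for a in angles)
    if not all(np.isfinite([ax, ay, az])):
        raise InvalidParameterError("rotation angles must be finite")
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def build_tensor(sigma_l: float, sigma_t: float, angles=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Anisotropic conductivity tensor A^T diag(sigma_l, sigma_t, sigma_t) A.

    The longitudinal conductivity sits on the local x-axis before rotation.
    Eigenvalues of the result are exactly {sigma_l, sigma_t, sigma_t}.
    """
    if not (np.isfinite(sigma_l) and np.isfinite(sigma_t)):
        raise InvalidParameterError("conductivities must be finite")
    if not sigma_l >= sigma_t:
        raise InvalidParameterError("require sigma_l >= sigma_t")
    if sigma_t < 0:
        raise InvalidParameterError("conductivities must be non-negative")
    A = rotation_matrix(angles)
    Dstar = np.diag([sigma_l, sigma_t, sigma_t])
    D = A.T @ Dstar @ A
    return 0.5 * (D + D.T)  # exact symmetry


def _rotation_matrices(angles: np.ndarray) -> np.ndarray:
    """Vectorised Rz@Ry@Rx for an (n, 3) angle array."""
    ax, ay, az = angles[:, 0], angles[:, 1], angles[:, 2]
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    n = len(angles)
    A = np.empty((n, 3, 3))
    # Rz @ Ry @ Rx written out
    A[:, 0, 0] = cz * cy
    A[:, 0, 1] = cz * sy * sx - sz * cx
    A[:, 0, 2] = cz * sy * cx + sz * sx
    A[:, 1, 0] = sz * cy
    A[:, 1, 1] = sz * sy * sx + cz * cx
    A[:, 1, 2] = sz * sy * cx - cz * sx
    A[:, 2, 0] = -sy
    A[:, 2, 1] = cy * sx
    A[:, 2, 2] = cy * cx
    return A


def assemble_tensor_field(
    volume: TissueLabelVolume,
    table: ConductivityTable,
    aniso: AnisotropyField | None = None,
    default_angles: tuple[float, float, float] | None = None,
) -> ConductivityTensorField:
    """Build the per-voxel conductivity tensor field for a labeled volume.

    Isotropic voxels get sigma * I; anisotropic voxels get the rotated tensor
    from their Euler angles (``aniso``), or ``default_angles`` if no angle
    volume is supplied.  Air voxels get the exact zero tensor.
    """
    shape = volume.shape
    tensors = np.zeros(shape + (3, 3))
    eye = np.eye(3)
    for label in np.unique(volume.labels):
        if label == AIR_LABEL:
            continue
        entry = table.entry_for_label(int(label), volume.label_names)
        mask = volume.labels == label
        if not entry.anisotropic:
            tensors[mask] = entry.isotropic_sigma * eye
            continue
        if aniso is not None:
            if aniso.angles.shape[:3] != shape:
                raise ConfigurationError("anisotropy field grid does not match volume")
            ang = aniso.angles[mask]
        elif default_angles is not None:
            ang = np.broadcast_to(np.asarray(default_angles, float), (int(mask.sum()), 3))
        else:
            raise ConfigurationError(
                f"anisotropic label {label} has no angle volume and no default angles"
            )
        A = _rotation_matrices(np.asarray(ang, dtype=float))
        Dstar = np.diag([entry.sigma_longitudinal, entry.sigma_transverse, entry.sigma_transverse])
        D = np.einsum("nji,jk,nkl->nil", A, Dstar, A)
        tensors[mask] = 0.5 * (D + np.swapaxes(D, -1, -2))
    return ConductivityTensorField(tensors=tensors, spacing=volume.spacing)


@dataclass
class ValidationReport:
    problems: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.problems

    def __str__(self) -> str:
        return "OK" if self.passed else "; ".join(self.problems)


def validate_model(volume: TissueLabelVolume, table: ConductivityTable) -> ValidationReport:
    """Report-only structural checks: unknown labels, connectivity, base plane."""
    report = ValidationReport()
    for label in np.unique(volume.labels):
        if label == AIR_LABEL:
            continue
        name = volume.label_names.get(int(label))
        if name is None or name not in table:
            report.problems.append(f"label {int(label)} ({name!r}) not in conductivity table")
    nonair = volume.nonair_mask
    if not nonair.any():
        report.problems.append("volume contains no non-air voxels")
        return report
    _, ncomp = ndimage.label(nonair)
    if ncomp > 1:
        report.problems.append(f"non-air region has {ncomp} disconnected components")
    # Convention: the grounded caudal base plane is the lowest grid slice; a head
    # floating above z = 0 has no identifiable Dirichlet plane.
    if not nonair[:, :, 0].any():
        report.problems.append("no non-air voxel on the lowest slice: base plane missing")
    return report


@dataclass
class BoundaryFaces:
    """All exterior faces of the non-air domain on the voxel grid.

    Each face separates a non-air voxel from air (or the grid edge).  Arrays
    are parallel over faces: owning voxel index, axis (0/1/2), orientation
    sign (+1/-1), physical center (mm), area (mm^2), outward unit normal, and
    the four corner node ids on the (nx+1, ny+1, nz+1) node grid.
    """

    voxels: np.ndarray      # (nf, 3) int
    axes: np.ndarray        # (nf,) int in {0,1,2}
    signs: np.ndarray       # (nf,) int in {+1,-1}
    centers_mm: np.ndarray  # (nf, 3)
    areas_mm2: np.ndarray   # (nf,)
    normals: np.ndarray     # (nf, 3)
    node_ids: np.ndarray    # (nf, 4) raveled node-grid indices
    node_shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.axes)


def _face_nodes(vox: np.ndarray, axis: int, sign: int, node_shape) -> np.ndarray:
    """Corner node ids of the faces of voxels ``vox`` on side (axis, sign)."""
    i, j, k = vox[:, 0], vox[:, 1], vox[:, 2]
    off = 1 if sign > 0 else 0
    if axis == 0:
        corners = [(off, 0, 0), (off, 1, 0), (off, 0, 1), (off, 1, 1)]
    elif axis == 1:
        corners = [(0, off, 0), (1, off, 0), (0, off, 1), (1, off, 1)]
    else:
        corners = [(0, 0, off), (1, 0, off), (0, 1, off), (1, 1, off)]
    ids = np.empty((len(vox), 4), dtype=np.int64)
    for c, (di, dj, dk) in enumerate(corners):
        ids[:, c] = np.ravel_multi_index((i + di, j + dj, k + dk), node_shape)
    return ids


def boundary_faces(volume: TissueLabelVolume) -> BoundaryFaces:
    """Extract every air/non-air interface face of the volume."""
    nonair = volume.nonair_mask
    padded = np.pad(nonair, 1, constant_values=False)
    sp = np.asarray(volume.spacing)
    node_shape = tuple(s + 1 for s in volume.shape)

    vox_list, axes_list, signs_list = [], [], []
    for axis in range(3):
        for sign in (+1, -1):
            shift = np.roll(padded, -sign, axis=axis)
            expose = nonair & ~shift[1:-1, 1:-1, 1:-1]
            vox = np.argwhere(expose)
            if len(vox):
                vox_list.append(vox)
                axes_list.append(np.full(len(vox), axis, dtype=np.int8))
                signs_list.append(np.full(len(vox), sign, dtype=np.int8))
    if not vox_list:
        raise ConfigurationError("volume has no boundary faces (no non-air voxels)")
    voxels = np.concatenate(vox_list)
    axes = np.concatenate(axes_list)
    signs = np.concatenate(signs_list)

    centers = (voxels + 0.5) * sp
    for axis in range(3):
        sel = axes == axis
        centers[sel, axis] += 0.5 * sp[axis] * signs[sel]
    area_by_axis = np.array(
        [sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1]]
    )
    areas = area_by_axis[axes]
    normals = np.zeros((len(axes), 3))
    normals[np.arange(len(axes)), axes] = signs

    node_ids = np.empty((len(axes), 4), dtype=np.int64)
    for axis in range(3):
        for sign in (+1, -1):
            sel = (axes == axis) & (signs == sign)
            if sel.any():
                node_ids[sel] = _face_nodes(voxels[sel], axis, sign, node_shape)

    return BoundaryFaces(
        voxels=voxels,
        axes=axes.astype(int),
        signs=signs.astype(int),
        centers_mm=centers,
        areas_mm2=areas,
        normals=normals,
        node_ids=node_ids,
        node_shape=node_shape,
    )
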