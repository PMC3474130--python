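"""Surface electrodes as patches of boundary faces, and montage placement.

An electrode is a connected set of exterior voxel faces whose cumulative area
approximates the requested contact area (within 10%).  The contact model is a
uniform normal current density over the patch: each face carries current
proportional to its area.  The default 19-electrode montage mimics the 10-20
EEG layout on a sphere: vertex (Cz), a 45-degree ring (Fz, Pz, C3, C4), the
10% equatorial ring (Fp1/2, F7/8, T3/4, T5/6, O1/2), and F3/F4/P3/P4 placed on
the great-circle midpoints of their neighbours.  Coordinates: +x anterior,
+y left, +z superior.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, PlacementError
from .head_model import BoundaryFaces, TissueLabelVolume, boundary_faces

__all__ = [
    "Electrode",
    "Montage",
    "place_electrode",
    "standard_montage",
    "standard_1020_directions",
]


@dataclass
class Electrode:
    """Named patch of boundary faces forming one contact."""

    name: str
    face_indices: np.ndarray  # indices into the montage's BoundaryFaces
    faces: BoundaryFaces

    def __post_init__(self):
        self.face_indices = np.asarray(self.face_indices, dtype=int)
        if self.face_indices.size == 0:
            raise ConfigurationError(f"electrode {self.name!r} has no faces")

    @property
    def area_cm2(self) -> float:
        return float(self.faces.areas_mm2[self.face_indices].sum()) / 100.0

    @property
    def face_areas_mm2(self) -> np.ndarray:
        return self.faces.areas_mm2[self.face_indices]

    @property
    def normals(self) -> np.ndarray:
        return self.faces.normals[self.face_indices]

    @property
    def node_ids(self) -> np.ndarray:
        return np.unique(self.faces.node_ids[self.face_indices])

    @property
    def center_mm(self) -> np.ndarray:
        c = self.faces.centers_mm[self.face_indices]
        a = self.faces.areas_mm2[self.face_indices][:, None]
        return (c * a).sum(axis=0) / a.sum()


@dataclass
class Montage:
    """Ordered set of pairwise-disjoint electrodes on one head surface."""

    electrodes: list[Electrode]
    faces: BoundaryFaces

    def __post_init__(self):
        names = [e.name for e in self.electrodes]
        if len(set(names)) != len(names):
            raise ConfigurationError("electrode names must be unique")
        seen: set[int] = set()
        for e in self.electrodes:
            idx = set(e.face_indices.tolist())
            if seen & idx:
                raise ConfigurationError("electrode patches must be pairwise disjoint")
            seen |= idx

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.electrodes]

    def __iter__(self):
        return iter(self.electrodes)

    def __getitem__(self, i: int) -> Electrode:
        return self.electrodes[i]

    def index(self, name: str) -> int:
        return self.names.index(name)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        out = {"electrodes": []}
        for e in self.electrodes:
            fv = self.faces.voxels[e.face_indices]
            fa = self.faces.axes[e.face_indices]
            fs = self.faces.signs[e.face_indices]
            out["electrodes"].append(
                {
                    "name": e.name,
                    "area_cm2": e.area_cm2,
                    "faces": np.column_stack([fv, fa, fs]).tolist(),
                }
            )
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, data: dict, volume: TissueLabelVolume) -> "Montage":
        faces = boundary_faces(volume)
        key = {}
        for i in range(len(faces)):
            key[(*faces.voxels[i], faces.axes[i], faces.signs[i])] = i
        electrodes = []
        for espec in data["electrodes"]:
            idx = []
            for i, j, k, axis, sign in espec["faces"]:
                fkey = (i, j, k, axis, sign)
                if fkey not in key:
                    raise ConfigurationError(
                        f"face {fkey} of electrode {espec['name']!r} is not on this head's surface"
                    )
                idx.append(key[fkey])
            electrodes.append(Electrode(espec["name"], np.array(idx), faces))
        return cls(electrodes=electrodes, faces=faces)

    @classmethod
    def from_json(cls, path, volume: TissueLabelVolume) -> "Montage":
        with open(path) as fh:
            return cls.from_dict(json.load(fh), volume)


def _base_plane_node_z(volume: TissueLabelVolume) -> int:
    return volume.base_plane_index()


def _eligible_face_mask(faces: BoundaryFaces, volume: TissueLabelVolume) -> np.ndarray:
    """Faces available for electrodes: not touching the grounded base plane."""
    base_z = _base_plane_node_z(volume)
    node_z = np.unravel_index(faces.node_ids, faces.node_shape)[2]
    return (node_z > base_z).all(axis=1)


def _face_adjacency(faces: BoundaryFaces):
    """Map node id -> face indices, for connected patch growth."""
    from collections import defaultdict

    node_to_faces = defaultdict(list)
    for fi, nodes in enumerate(faces.node_ids):
        for n in nodes:
            node_to_faces[int(n)].append(fi)
    return node_to_faces


def place_electrode(
    volume: TissueLabelVolume,
    center_direction,
    area_cm2: float,
    faces: BoundaryFaces | None = None,
    origin_mm=None,
    name: str = "E",
    taken: np.ndarray | None = None,
    area_tolerance: float = 0.10,
) -> Electrode:
    """Grow a connected patch of boundary faces around a surface point.

    The seed is the eligible boundary face whose direction from ``origin_mm``
    (default: center of the head's bounding box) best matches
    ``center_direction``; faces are then added in order of distance from the
    seed, restricted to faces edge/vertex-connected to the patch, until the
    cumulative area reaches ``area_cm2``.  The final area must lie within
    ``area_tolerance`` (default 10%) of the request.
    """
    if area_cm2 <= 0:
        raise PlacementError("electrode area must be positive")
    if faces is None:
        faces = boundary_faces(volume)
    direction = np.asarray(center_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    if origin_mm is None:
        idx = np.argwhere(volume.nonair_mask)
        lo = idx.min(axis=0)
        hi = idx.max(axis=0) + 1
        origin_mm = (lo + hi) / 2.0 * np.asarray(volume.spacing)
    origin_mm = np.asarray(origin_mm, dtype=float)

    above_base = _eligible_face_mask(faces, volume)
    if not above_base.any():
        raise PlacementError("no eligible boundary faces above the base plane")

    rel = faces.centers_mm - origin_mm
    rel_norm = np.linalg.norm(rel, axis=1)
    cosine = np.where(above_base, (rel @ direction) / np.maximum(rel_norm, 1e-12), -np.inf)
    seed = int(np.argmax(cosine))
    if not np.isfinite(cosine[seed]) or cosine[seed] <= 0:
        raise PlacementError("center direction does not intersect the head surface above the base plane")
    if taken is not None and taken[seed]:
        raise PlacementError("placement overlaps an existing electrode")
    eligible = above_base if taken is None else above_base & ~taken

    area_target_mm2 = area_cm2 * 100.0
    node_to_faces = _face_adjacency(faces)
    seed_center = faces.centers_mm[seed]

    chosen: list[int] = []
    area = 0.0
    visited = {seed}
    heap = [(0.0, seed)]
    while heap and area < area_target_mm2:
        _, fi = heapq.heappop(heap)
        if not eligible[fi]:
            continue
        chosen.append(fi)
        area += float(faces.areas_mm2[fi])
        for n in faces.node_ids[fi]:
            for fj in node_to_faces[int(n)]:
                if fj not in visited:
                    visited.add(fj)
                    d = float(np.linalg.norm(faces.centers_mm[fj] - seed_center))
                    heapq.heappush(heap, (d, fj))
    if area < area_target_mm2 * (1 - area_tolerance):
        raise PlacementError(
            f"requested area {area_cm2} cm^2 exceeds the available connected surface "
            f"(got {area / 100.0:.2f} cm^2)"
        )
    if area > area_target_mm2 * (1 + area_tolerance):
        raise PlacementError(
            f"cannot match area {area_cm2} cm^2 within {area_tolerance:.0%} "
            f"(got {area / 100.0:.2f} cm^2); faces too coarse"
        )
    return Electrode(name=name, face_indices=np.array(sorted(chosen)), faces=faces)


def standard_1020_directions() -> dict[str, np.ndarray]:
    """Unit direction vectors of the default 19-name 10-20-style layout."""

    def sph(incl_deg: float, az_deg: float) -> np.ndarray:
        th, ph = np.deg2rad(incl_deg), np.deg2rad(az_deg)
        return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])

    dirs = {
        "Cz": sph(0, 0),
        "Fz": sph(45, 0),
        "Pz": sph(45, 180),
        "C3": sph(45, 90),
        "C4": sph(45, -90),
        "Fp1": sph(90, 18),
        "Fp2": sph(90, -18),
        "F7": sph(90, 54),
        "F8": sph(90, -54),
        "T3": sph(90, 90),
        "T4": sph(90, -90),
        "T5": sph(90, 126),
        "T6": sph(90, -126),
        "O1": sph(90, 162),
        "O2": sph(90, -162),
    }

    def mid(a: str, b: str) -> np.ndarray:
        v = dirs[a] + dirs[b]
        return v / np.linalg.norm(v)

    dirs["F3"] = mid("Fz", "F7")
    dirs["F4"] = mid("Fz", "F8")
    dirs["P3"] = mid("Pz", "T5")
    dirs["P4"] = mid("Pz", "T6")
    order = [
        "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
        "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
    ]
    return {k: dirs[k] for k in order}


def _fibonacci_directions(n: int) -> list[np.ndarray]:
    """Deterministic quasi-uniform directions over the upper surface."""
    golden = (1 + 5**0.5) / 2
    out = []
    for i in range(n):
        z = 0.95 - 0.80 * (i + 0.5) / n  # inclinations within the upper cap
        az = 2 * np.pi * i / golden
        s = np.sqrt(1 - z * z)
        out.append(np.array([s * np.cos(az), s * np.sin(az), z]))
    return out


def standard_montage(
    volume: TissueLabelVolume,
    n: int = 19,
    area_cm2: float = 22.0,
    origin_mm=None,
    faces: BoundaryFaces | None = None,
) -> Montage:
    """Place ``n`` disjoint electrodes at deterministic positions.

    ``n = 19`` uses the named 10-20-style layout; other counts use a
    deterministic quasi-uniform spiral over the upper surface with generic
    names E01, E02, ...
    """
    if n < 2:
        raise ConfigurationError("a montage needs at least 2 electrodes")
    if faces is None:
        faces = boundary_faces(volume)
    if n == 19:
        named = standard_1020_directions()
        items = list(named.items())
    else:
        items = [(f"E{i + 1:02d}", d) for i, d in enumerate(_fibonacci_directions(n))]

    taken = np.zeros(len(faces), dtype=bool)
    electrodes = []
    for name, direction in items:
        e = place_electrode(
            volume,
            direction,
            area_cm2,
            faces=faces,
            origin_mm=origin_mm,
            name=name,
            taken=taken,
        )
        taken[e.face_indices] = True
        electrodes.append(e)
    return Montage(electrodes=electrodes, faces=faces)
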