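"""Synthetic head phantoms and closed-form validation oracles.

Two phantom families are generated on a regular voxel grid:

* a multi-shell truncated sphere (scalp / skull / CSF / gray matter, optionally
  an anisotropic white-matter core) with embedded target and avoid blobs.  The
  sphere is cut by a flat plane at ``-truncation_fraction * R`` below its
  center, and the grid is laid out so that this cut is exactly the lowest grid
  slice: that slice is the grounded caudal base plane.
* a rectangular slab of a single tissue whose bottom face is the base plane
  and whose top face serves as a full-face electrode, giving a 1D current flow
  with an exact solution.

The analytic oracles are the uniform-slab field (Ohm's law) and the Legendre
series for a pair of point current electrodes on a homogeneous sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ConfigurationError, InvalidParameterError
from .head_model import (
    AnisotropyField,
    ConductivityTable,
    TissueLabelVolume,
    default_conductivity_table,
)

__all__ = [
    "Blob",
    "PhantomSpec",
    "AnalyticSolution",
    "build_phantom",
    "phantom_center_mm",
    "analytic_slab_field",
    "analytic_sphere_potential",
    "truncated_shell_volume_mm3",
]

#: default outer-to-inner shells: (outer radius mm, tissue name)
DEFAULT_SHELLS = (
    (80.0, "skin"),
    (74.0, "cortical_bone"),
    (70.0, "cerebrospinal_fluid"),
    (66.0, "gray_matter"),
)


@dataclass(frozen=True)
class Blob:
    """Spherical region embedded in the innermost shell.

    ``center_mm`` is relative to the sphere center; ``name`` becomes the
    region's tissue/label name.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    name: str
    sigma: float = 0.1  # gray-matter-like by default

    def __post_init__(self):
        if not self.radius_mm > 0:
            raise ConfigurationError(f"blob {self.name!r} must have positive radius")


@dataclass
class PhantomSpec:
    """Specification of a synthetic phantom; deterministic for a fixed seed."""

    kind: str = "sphere"  # "sphere" | "slab"
    shells: tuple = DEFAULT_SHELLS
    voxel_mm: float = 2.0
    target_blobs: tuple[Blob, ...] = ()
    avoid_blobs: tuple[Blob, ...] = ()
    anisotropic_core: bool = False
    core_radius_mm: float = 40.0      # white-matter core inside innermost shell
    truncation_fraction: float = 0.9  # base plane at -f*R below center
    slab_size_mm: tuple[float, float, float] = (40.0, 40.0, 80.0)
    slab_tissue: str = "gray_matter"
    extra_tissues: dict | None = None  # name -> sigma (S/m), for non-default shells
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("sphere", "slab"):
            raise ConfigurationError(f"unknown phantom kind {self.kind!r}")
        if self.voxel_mm <= 0:
            raise ConfigurationError("voxel size must be positive")
        radii = [r for r, _ in self.shells]
        if any(r2 >= r1 for r1, r2 in zip(radii, radii[1:])):
            raise ConfigurationError("shell radii must be strictly decreasing")
        if self.kind == "sphere":
            if not 0 < self.truncation_fraction < 1:
                raise ConfigurationError("truncation fraction must lie in (0, 1)")
            inner = self.core_radius_mm if self.anisotropic_core else radii[-1]
            for blob in self.target_blobs + self.avoid_blobs:
                c = np.asarray(blob.center_mm, float)
                if np.linalg.norm(c) + blob.radius_mm >= inner:
                    raise ConfigurationError(
                        f"blob {blob.name!r} is not strictly inside the innermost shell"
                    )
            for t in self.target_blobs:
                for a in self.avoid_blobs:
                    d = np.linalg.norm(np.asarray(t.center_mm) - np.asarray(a.center_mm))
                    if d <= t.radius_mm + a.radius_mm:
                        raise ConfigurationError(
                            f"target blob {t.name!r} and avoid blob {a.name!r} overlap"
                        )


def phantom_center_mm(spec: PhantomSpec) -> np.ndarray:
    """Physical position (mm) of the sphere center in the phantom grid."""
    if spec.kind != "sphere":
        raise ConfigurationError("center is defined for sphere phantoms only")
    h = spec.voxel_mm
    R = spec.shells[0][0]
    n_side = int(np.ceil(2 * R / h)) + 2  # one-voxel air margin in x and y
    cx = n_side * h / 2.0
    cz = spec.truncation_fraction * R
    return np.array([cx, cx, cz])


def _sphere_phantom(spec: PhantomSpec):
    h = spec.voxel_mm
    R = spec.shells[0][0]
    f = spec.truncation_fraction
    n_side = int(np.ceil(2 * R / h)) + 2
    nz = int(np.ceil((f * R + R) / h)) + 1  # air margin on top only
    center = phantom_center_mm(spec)

    xs = (np.arange(n_side) + 0.5) * h - center[0]
    zs = (np.arange(nz) + 0.5) * h - center[2]
    X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")
    r2 = X**2 + Y**2 + Z**2

    labels = np.zeros((n_side, n_side, nz), dtype=np.int16)
    label_names: dict[int, str] = {}
    table = default_conductivity_table()
    entries = dict(table.entries)
    if spec.extra_tissues:
        from .head_model import ConductivityEntry

        for name, sigma in spec.extra_tissues.items():
            entries[name] = ConductivityEntry.isotropic(float(sigma))

    next_label = 1
    for radius, name in spec.shells:
        labels[r2 <= radius**2] = next_label
        label_names[next_label] = name
        next_label += 1
    if spec.anisotropic_core:
        labels[r2 <= spec.core_radius_mm**2] = next_label
        label_names[next_label] = "white_matter"
        core_label = next_label
        next_label += 1
    else:
        core_label = None

    for blob in spec.target_blobs + spec.avoid_blobs:
        c = np.asarray(blob.center_mm, float)
        d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        labels[d2 <= blob.radius_mm**2] = next_label
        label_names[next_label] = blob.name
        if blob.name not in entries:
            from .head_model import ConductivityEntry

            entries[blob.name] = ConductivityEntry.isotropic(blob.sigma)
        next_label += 1

    volume = TissueLabelVolume(labels=labels, spacing=(h, h, h), label_names=label_names)

    aniso = None
    if core_label is not None:
        rng = np.random.default_rng(spec.seed)
        angles = np.zeros(labels.shape + (3,))
        core_mask = labels == core_label
        angles[core_mask] = rng.uniform(-np.pi, np.pi, size=(int(core_mask.sum()), 3))
        aniso = AnisotropyField(angles=angles)

    return volume, ConductivityTable(entries), aniso


def _slab_phantom(spec: PhantomSpec):
    h = spec.voxel_mm
    lx, ly, lz = spec.slab_size_mm
    nx = int(round(lx / h)) + 2  # air margin in x and y
    ny = int(round(ly / h)) + 2
    nz = int(round(lz / h)) + 1  # air above; base plane at the bottom slice
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    labels[1:-1, 1:-1, : int(round(lz / h))] = 1
    label_names = {1: spec.slab_tissue}
    volume = TissueLabelVolume(labels=labels, spacing=(h, h, h), label_names=label_names)
    return volume, default_conductivity_table(), None


def build_phantom(spec: PhantomSpec):
    """Build (TissueLabelVolume, ConductivityTable, AnisotropyField | None)."""
    if spec.kind == "sphere":
        return _sphere_phantom(spec)
    return _slab_phantom(spec)


def truncated_shell_volume_mm3(r_outer: float, r_inner: float, cut_below: float) -> float:
    """Exact volume of a spherical shell with everything below z = -cut_below removed."""

    def cap_volume(r: float, cut: float) -> float:
        # volume of the part of a radius-r ball below plane z = -cut
        if cut >= r:
            return 0.0
        height = r - cut
        return np.pi * height**2 * (3 * r - height) / 3.0

    def ball(r: float) -> float:
        return 4.0 / 3.0 * np.pi * r**3

    vo = ball(r_outer) - cap_volume(r_outer, cut_below)
    vi = ball(r_inner) - cap_volume(r_inner, cut_below) if r_inner > 0 else 0.0
    return vo - vi


def analytic_slab_field(cross_section_area: float, current: float, sigma: float, length: float):
    """Uniform-conduction slab: J = I/A and end-to-end voltage IL/(sigma A).

    SI units throughout (m^2, A, S/m, m) -> (A/m^2, V).
    """
    for name, v in (
        ("cross_section_area", cross_section_area),
        ("current", current),
        ("sigma", sigma),
        ("length", length),
    ):
        if not (np.isfinite(v) and v > 0):
            raise InvalidParameterError(f"{name} must be positive and finite")
    J = current / cross_section_area
    dV = current * length / (sigma * cross_section_area)
    return J, dV


@dataclass
class AnalyticSolution:
    """Potential samples of an analytic Laplace solution.

    Values are defined up to an additive constant; the series convention fixes
    the sphere-average of the potential to zero.
    """

    points: np.ndarray
    values: np.ndarray
    config: dict = dc_field(default_factory=dict)


def _electrode_unit_vectors(electrode_angles) -> np.ndarray:
    arr = np.asarray(electrode_angles, dtype=float)
    if arr.shape == (2, 2):  # (inclination from +z, azimuth from +x) pairs
        theta, phi = arr[:, 0], arr[:, 1]
        return np.stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
            axis=1,
        )
    if arr.shape == (2, 3):
        return arr / np.linalg.norm(arr, axis=1, keepdims=True)
    raise InvalidParameterError("electrode_angles must be (2, 2) angles or (2, 3) vectors")


def _pair_potential_closed(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Closed-form sum of (2n+1)/n t^n P_n(x) via Legendre generating functions."""
    s = np.sqrt(np.maximum(1.0 - 2.0 * t * x + t**2, 0.0))
    with np.errstate(divide="ignore"):
        return 2.0 / s - 2.0 + np.log(2.0 / (1.0 - t * x + s))


def _pair_potential_series(t: np.ndarray, x: np.ndarray, order: int) -> np.ndarray:
    """Truncated series sum_{n=1}^{order} (2n+1)/n t^n P_n(x), by upward recurrence."""
    p_nm1 = np.ones_like(x)   # P_0
    p_n = x.copy()            # P_1
    tn = t.copy()             # t^1
    total = 3.0 * tn * p_n
    for n in range(2, order + 1):
        p_np1 = ((2 * n - 1) * x * p_n - (n - 1) * p_nm1) / n
        p_nm1, p_n = p_n, p_np1
        tn = tn * t
        total += (2 * n + 1) / n * tn * p_n
    return total


def analytic_sphere_potential(
    radius: float,
    sigma: float,
    electrode_angles,
    current: float,
    obs_points,
    order: int | None = None,
    tail_tolerance: float = 1e-6,
) -> AnalyticSolution:
    """Potential of a point source/sink pair on a homogeneous sphere.

    The interior solution for a surface point electrode injecting ``current``
    is  u(r, gamma) = I / (4 pi sigma R) * sum_{n>=1} (2n+1)/n (r/R)^n P_n(cos gamma);
    source and sink contributions are subtracted.  With ``order=None`` the
    series is summed exactly in closed form; an integer ``order`` truncates it
    (a warning is issued if the estimated tail exceeds ``tail_tolerance``).

    ``obs_points`` are Cartesian coordinates relative to the sphere center and
    must lie on or inside the sphere.
    """
    if not (radius > 0 and sigma > 0):
        raise InvalidParameterError("radius and sigma must be positive")
    pts = np.atleast_2d(np.asarray(obs_points, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    if (r > radius * (1 + 1e-9)).any():
        raise InvalidParameterError("observation points must lie on or inside the sphere")
    src, snk = _electrode_unit_vectors(electrode_angles)

    t = np.minimum(r / radius, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[:, None] > 0, pts / np.where(r[:, None] > 0, r[:, None], 1.0), 0.0)
    x_src = unit @ src
    x_snk = unit @ snk

    scale = current / (4.0 * np.pi * sigma * radius)
    if order is None:
        vals = scale * (_pair_potential_closed(t, x_src) - _pair_potential_closed(t, x_snk))
    else:
        if order < 1:
            raise InvalidParameterError("series order must be >= 1")
        vals = scale * (
            _pair_potential_series(t, x_src, order) - _pair_potential_series(t, x_snk, order)
        )
        # Tail estimate: terms behave like 2 t^n P_n; bound |P_n| <= 1 and sum
        # the geometric tail, falling back to the last-term size on the surface.
        tmax = float(t.max(initial=0.0))
        if tmax >= 1.0 - 1e-12:
            tail = 3.0 / max(order, 1) ** 0.5
        else:
            tail = 3.0 * tmax ** (order + 1) / (1.0 - tmax)
        if tail > tail_tolerance:
            warnings.warn(
                f"Legendre series of order {order} may not have converged "
                f"(estimated tail {tail:.2e} > {tail_tolerance:.0e})",
                RuntimeWarning,
                stacklevel=2,
            )
    return AnalyticSolution(
        points=pts,
        values=vals,
        config={
            "radius": radius,
            "sigma": sigma,
            "source": src.tolist(),
            "sink": snk.tolist(),
            "current": current,
            "order": order,
        },
    )
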