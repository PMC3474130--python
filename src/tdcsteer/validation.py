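"""Built-in validation harness: solver-vs-oracle comparisons.

These routines exercise the whole forward chain against the closed-form
oracles (uniform slab, homogeneous-sphere Legendre series) and quantify the
agreement.  They are used by the test suite and the reproduction script, and
are available to users who want to re-certify the solver at other
resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_ops import current_density
from .forward import assemble, solve
from .head_model import assemble_tensor_field, boundary_faces
from .montage import Montage, place_electrode
from .phantoms import (
    PhantomSpec,
    analytic_slab_field,
    analytic_sphere_potential,
    build_phantom,
    phantom_center_mm,
)

__all__ = ["SphereComparison", "sphere_oracle_comparison", "slab_oracle_errors"]


@dataclass
class SphereComparison:
    """FEM-vs-analytic surface-potential agreement on a homogeneous sphere."""

    relative_rms: float
    n_points: int
    n_voxels: int
    voxel_mm: float
    radius_mm: float


def sphere_oracle_comparison(
    radius_mm: float = 80.0,
    voxel_mm: float = 2.0,
    sigma: float = 0.33,
    electrode_area_cm2: float = 1.5,
    electrode_inclination_deg: float = 30.0,
    exclusion_deg: float = 15.0,
    base_exclusion_zfrac: float = -0.5,
    tol: float = 1e-8,
) -> SphereComparison:
    """Solve a two-electrode pattern on a homogeneous truncated sphere and
    compare the surface potential with the point-electrode Legendre-series
    solution of the full sphere.

    Two small electrodes sit 60 degrees apart across the vertex and carry
    +1/-1 mA.  The comparison covers boundary-face centers projected onto the
    sphere, excluding points within ``exclusion_deg`` of either electrode
    center (the point-source singularity and the finite-patch difference live
    there) and points below ``base_exclusion_zfrac * R`` (the grounded
    truncation plane is not part of the analytic configuration).  Both fields
    are mean-referenced over the comparison set; the relative RMS of their
    difference is returned.
    """
    spec = PhantomSpec(
        kind="sphere",
        shells=((radius_mm, "brain_avg"),),
        voxel_mm=voxel_mm,
        extra_tissues={"brain_avg": sigma},
    )
    volume, table, _ = build_phantom(spec)
    center = phantom_center_mm(spec)
    faces = boundary_faces(volume)

    def direction(incl_deg, az_deg):
        th, ph = np.deg2rad(incl_deg), np.deg2rad(az_deg)
        return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])

    e_a = place_electrode(
        volume, direction(electrode_inclination_deg, 0.0), electrode_area_cm2,
        faces=faces, origin_mm=center, name="A",
    )
    e_b = place_electrode(
        volume, direction(electrode_inclination_deg, 180.0), electrode_area_cm2,
        faces=faces, origin_mm=center, name="B",
    )
    montage = Montage([e_a, e_b], faces)
    tensors = assemble_tensor_field(volume, table)
    system = assemble(volume, tensors, montage)
    phi = solve(system, system.loads[0] - system.loads[1], tol=tol)

    pts = faces.centers_mm - center
    r = np.linalg.norm(pts, axis=1)
    unit = pts / r[:, None]
    c_a = e_a.center_mm - center
    c_a /= np.linalg.norm(c_a)
    c_b = e_b.center_mm - center
    c_b /= np.linalg.norm(c_b)
    ang_a = np.degrees(np.arccos(np.clip(unit @ c_a, -1.0, 1.0)))
    ang_b = np.degrees(np.arccos(np.clip(unit @ c_b, -1.0, 1.0)))
    sel = (
        (ang_a > exclusion_deg)
        & (ang_b > exclusion_deg)
        & (pts[:, 2] / radius_mm > base_exclusion_zfrac)
    )

    oracle = analytic_sphere_potential(
        radius_mm / 1000.0, sigma, np.stack([c_a, c_b]), 1e-3,
        unit[sel] * radius_mm / 1000.0,
    )
    fem = phi.values[faces.node_ids[sel]].mean(axis=1)
    a = oracle.values - oracle.values.mean()
    f = fem - fem.mean()
    rms = float(np.linalg.norm(f - a) / np.linalg.norm(a))
    return SphereComparison(
        relative_rms=rms,
        n_points=int(sel.sum()),
        n_voxels=int(volume.nonair_mask.sum()),
        voxel_mm=voxel_mm,
        radius_mm=radius_mm,
    )


def slab_oracle_errors(
    slab_mm: tuple[float, float, float] = (40.0, 40.0, 80.0),
    voxel_mm: float = 4.0,
    tissue: str = "gray_matter",
    current_A: float = 1e-3,
    tol: float = 1e-10,
) -> dict:
    """Relative errors of the slab solve against J = I/A and dV = IL/(sigma A).

    The slab's full top face carries the current; the bottom face is the
    grounded base.  Returns relative errors of the interior current-density
    norm (max over interior voxels) and of the mean top-face potential.
    """
    spec = PhantomSpec(kind="slab", slab_size_mm=slab_mm, voxel_mm=voxel_mm,
                       slab_tissue=tissue)
    volume, table, _ = build_phantom(spec)
    faces = boundary_faces(volume)
    nz_slab = int(round(slab_mm[2] / voxel_mm))
    top = np.flatnonzero(
        (faces.axes == 2) & (faces.signs == 1) & (faces.voxels[:, 2] == nz_slab - 1)
    )
    from .montage import Electrode

    electrode = Electrode("top", top, faces)
    montage = Montage([electrode], faces)
    tensors = assemble_tensor_field(volume, table)
    system = assemble(volume, tensors, montage, injected_current_A=current_A)
    phi = solve(system, 0, tol=tol)
    field = current_density(phi, tensors)

    sigma = table[tissue].isotropic_sigma
    area_m2 = (slab_mm[0] / 1000.0) * (slab_mm[1] / 1000.0)
    J_exact, dV_exact = analytic_slab_field(area_m2, current_A, sigma, slab_mm[2] / 1000.0)

    interior = volume.nonair_mask
    J_err = float(np.abs(field.norm[interior] - J_exact).max() / J_exact)
    dV_fem = float(phi.values[electrode.node_ids].mean())
    dV_err = float(abs(dV_fem - dV_exact) / dV_exact)
    return {
        "J_rel_err": J_err,
        "dV_rel_err": dV_err,
        "J_exact_A_m2": J_exact,
        "dV_exact_V": dV_exact,
        "n_voxels": int(interior.sum()),
    }
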