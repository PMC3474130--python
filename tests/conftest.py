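"""Shared fixtures: coarse phantoms, montages, and solved basis sets.

Everything is generated at test time; heavy objects are session-scoped so the
forward solves run once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from tdcsteer.field_ops import current_density
from tdcsteer.forward import BasisSet, DiscreteSystem, assemble, compute_basis
from tdcsteer.head_model import (
    ConductivityTable,
    ConductivityTensorField,
    TissueLabelVolume,
    assemble_tensor_field,
)
from tdcsteer.montage import Montage, standard_montage
from tdcsteer.optimize import CurrentSteeringModel, ProblemSpec
from tdcsteer.phantoms import Blob, PhantomSpec, build_phantom, phantom_center_mm


@dataclass
class PhantomBundle:
    """A built phantom with its solved electrode basis."""

    spec: PhantomSpec
    volume: TissueLabelVolume
    table: ConductivityTable
    tensors: ConductivityTensorField
    montage: Montage
    system: DiscreteSystem
    basis: BasisSet
    center_mm: np.ndarray


def steering_phantom_spec(seed: int = 1) -> PhantomSpec:
    """Problem-1-style study phantom: 4-shell truncated sphere at 4 mm with a
    superficial target blob under the frontal-left surface and a deep central
    avoid blob."""
    return PhantomSpec(
        kind="sphere",
        voxel_mm=4.0,
        target_blobs=(Blob(center_mm=(30.0, 18.0, 30.0), radius_mm=10.0, name="target"),),
        avoid_blobs=(Blob(center_mm=(0.0, 0.0, -10.0), radius_mm=10.0, name="avoid"),),
        seed=seed,
    )


def build_bundle(spec: PhantomSpec, n_electrodes: int, area_cm2: float,
                 tol: float = 1e-10) -> PhantomBundle:
    volume, table, aniso = build_phantom(spec)
    center = phantom_center_mm(spec) if spec.kind == "sphere" else None
    montage = standard_montage(volume, n=n_electrodes, area_cm2=area_cm2, origin_mm=center)
    tensors = assemble_tensor_field(volume, table, aniso, default_angles=(0.0, 0.0, 0.0))
    system = assemble(volume, tensors, montage)
    basis = compute_basis(system, tol=tol)
    return PhantomBundle(
        spec=spec, volume=volume, table=table, tensors=tensors,
        montage=montage, system=system, basis=basis,
        center_mm=center if center is not None else np.zeros(3),
    )


def steering_problem() -> ProblemSpec:
    """The Problem-1-style spec: avoid-region cap 0.5 uA/cm^2, C in [0.5, 2] mA,
    target mean at least twice the avoid mean."""
    return ProblemSpec(
        target=("target",), avoid=("avoid",),
        J_max=5e-4, C_min=0.5, C_max=2.0, r=2.0,
    )


@pytest.fixture(scope="session")
def steering_bundle() -> PhantomBundle:
    """6-electrode coarse steering phantom with solved basis (shared)."""
    return build_bundle(steering_phantom_spec(), n_electrodes=6, area_cm2=16.0)


@pytest.fixture(scope="session")
def steering_model(steering_bundle) -> CurrentSteeringModel:
    return CurrentSteeringModel(
        steering_bundle.basis, steering_bundle.tensors, steering_bundle.volume,
        steering_problem(),
    )


@pytest.fixture(scope="session")
def basis_current_fields(steering_bundle):
    """Current-density fields of each basis potential (shared)."""
    return [
        current_density(steering_bundle.basis.field(i), steering_bundle.tensors)
        for i in range(steering_bundle.basis.n_electrodes)
    ]


@pytest.fixture(scope="session")
def slab_bundle() -> PhantomBundle:
    """Small uniform slab with a full-face top electrode (shared)."""
    spec = PhantomSpec(kind="slab", slab_size_mm=(40.0, 40.0, 80.0), voxel_mm=4.0)
    volume, table, _ = build_phantom(spec)
    import numpy as np

    from tdcsteer.head_model import boundary_faces
    from tdcsteer.montage import Electrode

    faces = boundary_faces(volume)
    nz_slab = int(round(80.0 / 4.0))
    top = np.flatnonzero(
        (faces.axes == 2) & (faces.signs == 1) & (faces.voxels[:, 2] == nz_slab - 1)
    )
    montage = Montage([Electrode("top", top, faces)], faces)
    tensors = assemble_tensor_field(volume, table)
    system = assemble(volume, tensors, montage)
    basis = compute_basis(system, tol=1e-10)
    return PhantomBundle(
        spec=spec, volume=volume, table=table, tensors=tensors,
        montage=montage, system=system, basis=basis, center_mm=np.zeros(3),
    )
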