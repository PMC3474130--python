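"""Voxel finite-element Laplace solver with electrode currents.

The head is discretised with one trilinear hexahedral element per non-air
voxel, the conductivity tensor taken constant per element.  The discrete
problem is

    K phi = f,    phi = 0 on the base plane (lowest non-air slice),

where K is the stiffness operator assembled from per-voxel tensors and f the
consistent load of the uniform electrode current density (each electrode's
injected current split over its boundary faces proportional to face area, and
each face's share split equally over its four corner nodes).  Dirichlet nodes
are removed by row/column elimination so superposition identities hold to
machine precision.

Systems are solved by Jacobi-preconditioned conjugate gradients; the achieved
relative residual is reported in the resulting fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import product

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .errors import (
    AssemblyError,
    DimensionError,
    IllPosedProblemError,
    SolverError,
)
from .head_model import ConductivityTensorField, TissueLabelVolume
from .montage import Montage
from .units import mm_to_m

__all__ = [
    "DiscreteSystem",
    "PotentialField",
    "BasisSet",
    "element_mode_matrices",
    "assemble",
    "solve",
    "compute_basis",
]

_CORNERS = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
            (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]


def element_mode_matrices(spacing_m) -> np.ndarray:
    """Per-tensor-component 8x8 element stiffness modes for a voxel element.

    Returns M with shape (6, 8, 8), ordered (xx, yy, zz, xy, xz, yz), such
    that the element stiffness for a constant tensor D is
    sum_c d_c M_c with d = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz); the off-diagonal
    modes already include both symmetric contributions.  Uses 2x2x2 Gauss
    quadrature (exact for trilinear shape-function products).
    """
    h = np.asarray(spacing_m, dtype=float)
    signs = np.array(_CORNERS) * 2 - 1  # (8, 3) in {-1, +1}
    g = 1.0 / np.sqrt(3.0)
    detJ = h[0] * h[1] * h[2] / 8.0
    M = np.zeros((6, 8, 8))
    for gp in product((-g, g), repeat=3):
        gp = np.asarray(gp)
        # dN_a/dxi_d = s_ad/2 * prod_{e != d} (1 + s_ae * gp_e)/2 ; to physical: * 2/h_d
        B = np.empty((3, 8))
        for d in range(3):
            terms = np.ones(8)
            for e in range(3):
                if e != d:
                    terms *= (1 + signs[:, e] * gp[e]) / 2.0
            B[d] = signs[:, d] / 2.0 * terms * (2.0 / h[d])
        M[0] += detJ * np.outer(B[0], B[0])
        M[1] += detJ * np.outer(B[1], B[1])
        M[2] += detJ * np.outer(B[2], B[2])
        M[3] += detJ * (np.outer(B[0], B[1]) + np.outer(B[1], B[0]))
        M[4] += detJ * (np.outer(B[0], B[2]) + np.outer(B[2], B[0]))
        M[5] += detJ * (np.outer(B[1], B[2]) + np.outer(B[2], B[1]))
    return M


@dataclass
class DiscreteSystem:
    """Assembled stiffness operator, ground plane, and electrode loads."""

    volume: TissueLabelVolume
    tensors: ConductivityTensorField
    montage: Montage | None
    node_shape: tuple[int, int, int]
    K: sparse.csr_matrix            # full operator over all grid nodes
    active_nodes: np.ndarray        # bool over grid nodes
    dirichlet_nodes: np.ndarray     # int ids (subset of active)
    free_nodes: np.ndarray          # int ids
    loads: np.ndarray | None        # (NE, n_nodes) consistent loads, amperes
    injected_current_A: float
    _K_ff: sparse.csr_matrix | None = dc_field(default=None, repr=False)
    _jacobi: np.ndarray | None = dc_field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.node_shape))

    @property
    def n_free(self) -> int:
        return len(self.free_nodes)

    def K_ff(self) -> sparse.csr_matrix:
        if self._K_ff is None:
            self._K_ff = self.K[self.free_nodes][:, self.free_nodes].tocsr()
        return self._K_ff


@dataclass
class PotentialField:
    """Nodal potential (V), zero by construction on the grounded base plane."""

    values: np.ndarray  # flat over the (nx+1, ny+1, nz+1) node grid
    node_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    solver_tol: float
    relative_residual: float = 0.0

    def grid(self) -> np.ndarray:
        return self.values.reshape(self.node_shape)


@dataclass
class BasisSet:
    """One potential field per electrode, each at unit injected current."""

    potentials: np.ndarray  # (NE, n_nodes)
    montage: Montage
    node_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    injected_current_A: float
    solver_tol: float

    @property
    def n_electrodes(self) -> int:
        return self.potentials.shape[0]

    def field(self, i: int) -> PotentialField:
        return PotentialField(
            values=self.potentials[i],
            node_shape=self.node_shape,
            spacing_mm=self.spacing_mm,
            solver_tol=self.solver_tol,
        )


def _element_nodes(vox: np.ndarray, node_shape) -> np.ndarray:
    """(nv, 8) raveled corner node ids for voxels ``vox`` (nv, 3)."""
    strides = np.array(
        [node_shape[1] * node_shape[2], node_shape[2], 1], dtype=np.int64
    )
    base = vox @ strides
    offsets = np.array([c @ strides for c in np.asarray(_CORNERS)], dtype=np.int64)
    return base[:, None] + offsets[None, :]


def electrode_load_vector(electrode, n_nodes: int, current_A: float) -> np.ndarray:
    """Consistent nodal load for a uniform current over an electrode patch."""
    f = np.zeros(n_nodes)
    areas = electrode.face_areas_mm2
    per_face = current_A * areas / areas.sum()
    nodes = electrode.faces.node_ids[electrode.face_indices]  # (nf, 4)
    np.add.at(f, nodes.ravel(), np.repeat(per_face / 4.0, 4))
    return f


def assemble(
    volume: TissueLabelVolume,
    tensors: ConductivityTensorField,
    montage: Montage | None = None,
    injected_current_A: float = 1e-3,
    chunk_voxels: int = 400_000,
) -> DiscreteSystem:
    """Assemble the stiffness operator, ground plane, and electrode loads."""
    if tensors.shape != volume.shape:
        raise DimensionError("tensor field grid does not match the label volume")
    node_shape = tuple(s + 1 for s in volume.shape)
    n_nodes = int(np.prod(node_shape))
    spacing_m = mm_to_m(np.asarray(volume.spacing))
    M = element_mode_matrices(spacing_m)  # (6, 8, 8)
    Mflat = M.reshape(6, 64)

    nonair = volume.nonair_mask
    if not nonair.any():
        raise IllPosedProblemError("volume contains no conductive voxels")
    vox = np.argwhere(nonair)
    dcomp = tensors.components(nonair)  # (nv, 6)
    nodes8 = _element_nodes(vox, node_shape)

    K = sparse.csr_matrix((n_nodes, n_nodes))
    for start in range(0, len(vox), chunk_voxels):
        sl = slice(start, start + chunk_voxels)
        k_all = dcomp[sl] @ Mflat  # (chunk, 64)
        nn = nodes8[sl]
        rows = np.repeat(nn, 8, axis=1).ravel()
        cols = np.tile(nn, (1, 8)).ravel()
        K = K + sparse.coo_matrix(
            (k_all.ravel(), (rows, cols)), shape=(n_nodes, n_nodes)
        ).tocsr()
    K.sum_duplicates()

    active = np.zeros(n_nodes, dtype=bool)
    active[nodes8.ravel()] = True

    base_k = volume.base_plane_index()
    node_z = np.unravel_index(np.arange(n_nodes), node_shape)[2]
    dirichlet = np.flatnonzero(active & (node_z == base_k))
    if len(dirichlet) == 0:
        raise IllPosedProblemError("no grounded base plane: empty Dirichlet set")
    free = np.flatnonzero(active)
    free = free[~np.isin(free, dirichlet)]

    loads = None
    if montage is not None:
        loads = np.stack(
            [electrode_load_vector(e, n_nodes, injected_current_A) for e in montage]
        )
        if np.abs(loads[:, dirichlet]).sum() > 0:
            raise AssemblyError("electrode loads touch the grounded base plane")

    sym_err = abs(K - K.T).max()
    if sym_err > 1e-10 * max(abs(K).max(), 1e-300):
        raise AssemblyError(f"stiffness operator not symmetric (error {sym_err:.2e})")

    return DiscreteSystem(
        volume=volume,
        tensors=tensors,
        montage=montage,
        node_shape=node_shape,
        K=K,
        active_nodes=active,
        dirichlet_nodes=dirichlet,
        free_nodes=free,
        loads=loads,
        injected_current_A=injected_current_A,
    )


def _solve_free(system: DiscreteSystem, b_f: np.ndarray, tol: float, maxiter: int):
    K_ff = system.K_ff()
    bnorm = np.linalg.norm(b_f)
    if bnorm == 0.0:
        return np.zeros_like(b_f), 0.0
    if system._jacobi is None:
        system._jacobi = sparse.diags(1.0 / K_ff.diagonal())
    x, info = cg(K_ff, b_f, rtol=tol * 1e-2, atol=0.0, maxiter=maxiter,
                 M=system._jacobi)
    res = np.linalg.norm(K_ff @ x - b_f) / bnorm
    if res > tol:
        raise SolverError(
            f"PCG did not converge in {maxiter} iterations "
            f"(relative residual {res:.2e} > {tol:.0e})"
        )
    return x, res


def solve(
    system: DiscreteSystem,
    load,
    tol: float = 1e-8,
    maxiter: int = 20_000,
) -> PotentialField:
    """Solve for the potential given an electrode index or a full load vector.

    ``load`` may be an integer electrode index (using the montage's 1 mA
    consistent loads) or a length-n_nodes load vector in amperes.  Dirichlet
    nodes are exactly zero in the result.
    """
    if tol <= 0:
        raise SolverError("tolerance must be positive")
    if np.isscalar(load):
        if system.loads is None:
            raise DimensionError("system was assembled without a montage")
        f = system.loads[int(load)]
    else:
        f = np.asarray(load, dtype=float)
        if f.shape != (system.n_nodes,):
            raise DimensionError(
                f"load vector must have length {system.n_nodes}, got {f.shape}"
            )
    x, res = _solve_free(system, f[system.free_nodes], tol, maxiter)
    values = np.zeros(system.n_nodes)
    values[system.free_nodes] = x
    return PotentialField(
        values=values,
        node_shape=system.node_shape,
        spacing_mm=system.volume.spacing,
        solver_tol=tol,
        relative_residual=res,
    )


def compute_basis(system: DiscreteSystem, tol: float = 1e-8, maxiter: int = 20_000) -> BasisSet:
    """Solve one potential field per electrode at the system's unit current."""
    if system.montage is None or system.loads is None:
        raise DimensionError("system was assembled without a montage")
    fields = []
    for i, e in enumerate(system.montage):
        try:
            fields.append(solve(system, i, tol=tol, maxiter=maxiter).values)
        except SolverError as err:
            raise SolverError(f"basis solve failed for electrode {e.name!r}: {err}") from err
    return BasisSet(
        potentials=np.stack(fields),
        montage=system.montage,
        node_shape=system.node_shape,
        spacing_mm=system.volume.spacing,
        injected_current_A=system.injected_current_A,
        solver_tol=tol,
    )
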