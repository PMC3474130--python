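"""Constrained maximization of target-region current density.

The optimization variable is the electrode weight vector X (mA, one entry per
electrode of the montage).  The problem solved is

    max_X   mean |J|  over the target region
    s.t.    (1)  sum_i X_i = 0                      (no extracranial return)
            (2)  mean |J| over the avoid region < J_max
            (3)  total_current(X) > C_min
            (4)  total_current(X) < C_max
            (5)  mean target |J| >= r * mean avoid |J|

with total_current(X) = 0.5 sum |X_i|.  Each constraint can be toggled; with
(1) disabled the residual  -sum_i X_i  is reported as the current carried by
an implicit extracranial electrode.

Because region means of |J| are not linear in X, the objective gradient is by
default the surrogate built from the per-electrode single-pattern means
m_i = mean target |J_i|  (the weighted sum of these bounds the true mean from
above; the surrogate gradient is m_i * sign(X_i)).  The exact gradient and a
finite-difference fallback are available for cross-checking.  The solver is
an interior-point-family NLP method (scipy's trust-constr), followed by an
exact feasibility polish that exploits the degree-1 homogeneity of every
quantity in X: project onto sum(X) = 0, then rescale to the tightest upper
bound, which also maximizes the objective along the ray.

The whole problem is sign-degenerate — X and -X produce identical current
densities — which can be resolved by restricting one electrode's weight to a
half-line (``fix_sign``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, NonlinearConstraint, minimize

from .errors import (
    ConfigurationError,
    DimensionError,
    EmptyRegionError,
    InfeasibleProblemError,
    InvalidParameterError,
)
from .field_ops import WeightVector, as_weights, current_density, superpose, total_current
from .forward import BasisSet
from .head_model import ConductivityTensorField, TissueLabelVolume
from .roi_stats import RegionSummary, region_summary
from .units import A_m2_to_mA_cm2

__all__ = [
    "ProblemSpec",
    "OptimizerSettings",
    "ConstraintValue",
    "SteeringResult",
    "BruteForceResult",
    "CurrentSteeringModel",
    "precompute_region_means",
    "optimize",
    "brute_force_search",
    "fix_sign",
    "reduce_pattern",
    "scale_pattern",
]


@dataclass
class ProblemSpec:
    """Target/avoid regions, dose limits, and constraint toggles.

    Regions are given as label names or integer labels of the head volume.
    ``J_max`` is mA/cm^2; ``C_min``/``C_max`` are mA; ``r`` is dimensionless.
    ``constraints`` toggles constraints 1-5 in order.
    """

    target: tuple = ("target",)
    avoid: tuple = ()
    J_max: float | None = None
    C_min: float = 0.5
    C_max: float = 2.0
    r: float | None = None
    constraints: tuple[bool, bool, bool, bool, bool] = (True, True, True, True, True)
    sign_fix: tuple[int, int] | None = None  # (electrode index, +1 or -1)
    initial_X: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self):
        self.target = tuple(np.atleast_1d(self.target).tolist())
        self.avoid = tuple(np.atleast_1d(self.avoid).tolist()) if len(self.avoid) else ()
        if not self.target:
            raise ConfigurationError("target region must be non-empty")
        if len(self.constraints) != 5:
            raise ConfigurationError("constraints must be 5 toggles")
        self.constraints = tuple(bool(c) for c in self.constraints)
        if self.C_min > self.C_max:
            raise ConfigurationError(f"C_min {self.C_min} > C_max {self.C_max}")
        if self.constraints[1]:
            if self.J_max is None or not self.J_max > 0:
                raise ConfigurationError("constraint 2 enabled requires J_max > 0")
            if not self.avoid:
                raise ConfigurationError("constraint 2 enabled requires an avoid region")
        if self.constraints[4]:
            if self.r is None or not self.r > 0:
                raise ConfigurationError("constraint 5 enabled requires r > 0")
            if not self.avoid:
                raise ConfigurationError("constraint 5 enabled requires an avoid region")
        if self.sign_fix is not None:
            idx, sign = self.sign_fix
            if sign not in (-1, 1):
                raise ConfigurationError("sign_fix sign must be +1 or -1")
            if idx < 0:
                raise ConfigurationError("sign_fix electrode index must be >= 0")


@dataclass
class OptimizerSettings:
    """Iteration limits and tolerances of the NLP solve."""

    max_iter: int = 100
    step_tol: float = 1e-10        # relative step termination
    gradient_tol: float = 1e-3     # relative first-order optimality termination
    feasibility_tol: float = 1e-10
    gradient_mode: str = "exact"  # exact | surrogate | fd
    backend: str = "trust-constr"
    n_restarts: int = 8            # interior-point restart chain length

    def __post_init__(self):
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        for name in ("step_tol", "gradient_tol", "feasibility_tol"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.gradient_mode not in ("surrogate", "exact", "fd"):
            raise ConfigurationError(f"unknown gradient mode {self.gradient_mode!r}")
        if self.n_restarts < 0:
            raise ConfigurationError("n_restarts must be >= 0")


@dataclass(frozen=True)
class ConstraintValue:
    """Evaluated state of one constraint at a given X."""

    cid: str
    name: str
    enabled: bool
    value: float
    violation: float


@dataclass
class BruteForceResult:
    X: WeightVector
    objective: float
    n_feasible: int
    n_samples: int
    seed: int


def _resolve_labels(volume: TissueLabelVolume, region) -> list[int]:
    labels: list[int] = []
    for item in np.atleast_1d(region):
        if isinstance(item, (str, np.str_)):
            match = [l for l, n in volume.label_names.items() if n == item]
            if not match:
                raise EmptyRegionError(f"no label named {item!r} in the volume")
            labels.extend(int(l) for l in match)
        else:
            labels.append(int(item))
    return labels


class CurrentSteeringModel:
    """Montage current-steering problem bound to a basis set and a head.

    Construct from the per-electrode basis potentials, the conductivity
    tensor field and label volume they were computed on, and a
    :class:`ProblemSpec`; then call :meth:`fit`.  Per-region basis
    current-density vectors are precomputed once, so objective/constraint
    evaluations during optimization are cheap.
    """

    def __init__(
        self,
        basis: BasisSet,
        tensors: ConductivityTensorField,
        volume: TissueLabelVolume,
        problem: ProblemSpec,
    ):
        if tensors.shape != volume.shape:
            raise DimensionError("tensor field and volume grids differ")
        self.basis = basis
        self.tensors = tensors
        self.volume = volume
        self.problem = problem
        self.n_electrodes = basis.n_electrodes

        self.target_labels = _resolve_labels(volume, problem.target)
        self.avoid_labels = _resolve_labels(volume, problem.avoid) if problem.avoid else []
        self._region_basis: dict[str, np.ndarray] = {}
        masks = {"target": volume.region_mask(self.target_labels)}
        if self.avoid_labels:
            masks["avoid"] = volume.region_mask(self.avoid_labels)
        for key, mask in masks.items():
            if not mask.any():
                raise EmptyRegionError(f"{key} region contains no voxels")
        # J of each basis field restricted to each region: (n_vox, 3, NE), A/m^2 per mA
        stacks = {k: [] for k in masks}
        for i in range(self.n_electrodes):
            Jfield = current_density(basis.field(i), tensors)
            for k, mask in masks.items():
                stacks[k].append(Jfield.J[mask])
        for k in masks:
            self._region_basis[k] = np.stack(stacks[k], axis=-1)

    # -- region quantities -------------------------------------------------
    def region_basis(self, which: str) -> np.ndarray:
        return self._region_basis[which]

    def mean_norm(self, X, which: str) -> float:
        """Mean |J| (mA/cm^2) of the superposed pattern over a region."""
        B = self._region_basis[which]
        J = B @ np.asarray(as_weights(X))
        return float(A_m2_to_mA_cm2(np.linalg.norm(J, axis=1).mean()))

    def mean_norm_grad(self, X, which: str) -> np.ndarray:
        """Exact gradient of :meth:`mean_norm` with respect to X."""
        B = self._region_basis[which]
        J = B @ np.asarray(as_weights(X))
        n = np.linalg.norm(J, axis=1)
        unit = np.where(n[:, None] > 0, J / np.maximum(n[:, None], 1e-300), 0.0)
        return A_m2_to_mA_cm2(np.einsum("vc,vce->e", unit, B) / B.shape[0])

    def electrode_region_means(self) -> np.ndarray:
        """m[i, g]: mean |J_i| per electrode i and region g (target[, avoid])."""
        regions = ["target"] + (["avoid"] if "avoid" in self._region_basis else [])
        m = np.empty((self.n_electrodes, len(regions)))
        for g, key in enumerate(regions):
            B = self._region_basis[key]
            m[:, g] = A_m2_to_mA_cm2(np.linalg.norm(B, axis=1).mean(axis=0))
        return m

    # -- objective and constraints -----------------------------------------
    def objective(self, X) -> float:
        """Mean target-region |J| (mA/cm^2) of the superposed pattern."""
        return self.mean_norm(X, "target")

    def objective_gradient(self, X, mode: str = "exact") -> np.ndarray:
        if mode == "exact":
            return self.mean_norm_grad(X, "target")
        if mode == "surrogate":
            m_t = self.electrode_region_means()[:, 0]
            s = np.sign(np.asarray(as_weights(X)))
            s[s == 0] = 1.0
            return m_t * s
        raise ConfigurationError(f"unknown gradient mode {mode!r}")

    def constraint_values(self, X) -> list[ConstraintValue]:
        """Evaluate constraints 1-5 (and any sign fix) at X."""
        p = self.problem
        X = np.asarray(as_weights(X))
        c1, c2, c3, c4, c5 = p.constraints
        out = []
        sX = float(X.sum())
        out.append(
            ConstraintValue("1", "net_current_zero", c1, sX, abs(sX) if c1 else 0.0)
        )
        ma = self.mean_norm(X, "avoid") if "avoid" in self._region_basis else np.nan
        out.append(
            ConstraintValue(
                "2", "avoid_mean_below_J_max", c2, ma,
                max(0.0, ma - p.J_max) if c2 else 0.0,
            )
        )
        tc = total_current(X)
        out.append(
            ConstraintValue(
                "3", "total_current_above_C_min", c3, tc,
                max(0.0, p.C_min - tc) if c3 else 0.0,
            )
        )
        out.append(
            ConstraintValue(
                "4", "total_current_below_C_max", c4, tc,
                max(0.0, tc - p.C_max) if c4 else 0.0,
            )
        )
        mt = self.objective(X)
        margin = mt - (p.r or 0.0) * (ma if np.isfinite(ma) else 0.0)
        out.append(
            ConstraintValue(
                "5", "target_at_least_r_times_avoid", c5, margin,
                max(0.0, -margin) if c5 else 0.0,
            )
        )
        if p.sign_fix is not None:
            idx, sign = p.sign_fix
            v = sign * X[idx]
            out.append(ConstraintValue("sign", f"sign_fix_electrode_{idx}", True, v, max(0.0, -v)))
        return out

    def max_violation(self, X) -> float:
        return max(c.violation for c in self.constraint_values(X))

    def extracranial_remainder(self, X) -> float:
        """Current (mA) carried by the implicit extracranial electrode."""
        return -float(np.asarray(as_weights(X)).sum())

    # -- feasibility polish --------------------------------------------------
    def polish(self, X) -> np.ndarray:
        """Exact feasibility repair using degree-1 homogeneity in X.

        Projects onto sum(X) = 0 (if constraint 1 is on), then rescales the
        pattern to the tightest enabled upper bound (C_max and/or the avoid
        J_max), which is also the objective-maximizing scale along the ray.
        """
        p = self.problem
        X = np.array(as_weights(X), dtype=float)
        c1, c2, c3, c4, _ = p.constraints
        if c1:
            X = X - X.mean()
        if p.sign_fix is not None:
            idx, sign = p.sign_fix
            if sign * X[idx] < 0 and c1:
                X = -X  # magnitude-equivalent mirror satisfying the half-line
        tc = total_current(X)
        if tc <= 0:
            return X
        lo = (p.C_min / tc) if c3 else 0.0
        uppers = []
        if c4:
            uppers.append(p.C_max / tc)
        if c2:
            ma = self.mean_norm(X, "avoid")
            if ma > 0:
                uppers.append(p.J_max / ma)
        if uppers:
            s = min(uppers)
            if s >= lo:
                X = s * X
            # else: scale window empty; leave X for honest violation reporting
        elif c3 and tc < p.C_min:
            X = lo * X
        return X

    def _refine(self, X: np.ndarray, feas_tol: float, max_passes: int = 200,
                min_step: float = 1e-7) -> np.ndarray:
        """Deterministic pattern-search polish of a feasible pattern.

        Moves along all electrode-pair directions e_i - e_j (which span the
        zero-sum subspace; lone-electrode moves are added when constraint 1 is
        off), re-polishing each trial point, keeping the best feasible
        improvement per pass and halving the step when a pass stalls.  Cheap
        because region means are evaluated from the precomputed basis.
        """
        best = np.array(X, dtype=float)
        best_obj = self.objective(best)
        ne = self.n_electrodes
        dirs = []
        for i in range(ne):
            for j in range(ne):
                if i != j:
                    d = np.zeros(ne)
                    d[i], d[j] = 1.0, -1.0
                    dirs.append(d)
            if not self.problem.constraints[0]:
                d = np.zeros(ne)
                d[i] = 1.0
                dirs.append(d)
        step = 0.25 * max(float(np.abs(best).max()), 1e-3)
        for _ in range(max_passes):
            if step < min_step:
                break
            cand_best, cand_obj = None, best_obj
            for d in dirs:
                for s in (step, -step):
                    Xc = self.polish(best + s * d)
                    if self.max_violation(Xc) <= feas_tol:
                        obj = self.objective(Xc)
                        if obj > cand_obj * (1 + 1e-12):
                            cand_best, cand_obj = Xc, obj
            if cand_best is None:
                step *= 0.5
            else:
                best, best_obj = cand_best, cand_obj
        return best

    # -- fitting ------------------------------------------------------------
    def default_initial_X(self) -> np.ndarray:
        """Zero pattern nudged by 1e-3 mA on the electrode nearest the target."""
        centroid = self.volume.voxel_centers_mm(
            self.volume.region_mask(self.target_labels)
        ).mean(axis=0)
        centers = np.stack([e.center_mm for e in self.basis.montage])
        nearest = int(np.argmin(np.linalg.norm(centers - centroid, axis=1)))
        x0 = np.zeros(self.n_electrodes)
        x0[nearest] = 1e-3
        return x0

    def fit(self, settings: OptimizerSettings | None = None) -> "SteeringResult":
        settings = settings or OptimizerSettings()
        p = self.problem
        ne = self.n_electrodes
        if p.sign_fix is not None and p.sign_fix[0] >= ne:
            raise ConfigurationError(
                f"sign_fix electrode index {p.sign_fix[0]} out of range (NE={ne})"
            )
        x0 = (
            np.asarray(p.initial_X, dtype=float)
            if p.initial_X is not None
            else self.default_initial_X()
        )
        if x0.shape != (ne,) or not np.isfinite(x0).all():
            raise ConfigurationError("initial X must be a finite vector of length NE")

        c1, c2, c3, c4, c5 = p.constraints
        eps = 1e-12  # smoothing of |x| kinks in total-current gradients

        def tc_smooth(X):
            return 0.5 * np.sqrt(X**2 + eps).sum()

        def tc_grad(X):
            return 0.5 * X / np.sqrt(X**2 + eps)

        cons = []
        if c1:
            cons.append(LinearConstraint(np.ones((1, ne)), 0.0, 0.0))
        if c2:
            cons.append(
                NonlinearConstraint(
                    lambda X: self.mean_norm(X, "avoid"),
                    -np.inf,
                    p.J_max,
                    jac=lambda X: self.mean_norm_grad(X, "avoid").reshape(1, -1),
                )
            )
        if c3 or c4:
            cons.append(
                NonlinearConstraint(
                    tc_smooth,
                    p.C_min if c3 else -np.inf,
                    p.C_max if c4 else np.inf,
                    jac=lambda X: tc_grad(X).reshape(1, -1),
                )
            )
        if c5:
            cons.append(
                NonlinearConstraint(
                    lambda X: self.mean_norm(X, "target") - p.r * self.mean_norm(X, "avoid"),
                    0.0,
                    np.inf,
                    jac=lambda X: (
                        self.mean_norm_grad(X, "target") - p.r * self.mean_norm_grad(X, "avoid")
                    ).reshape(1, -1),
                )
            )
        bounds = None
        if p.sign_fix is not None:
            idx, sign = p.sign_fix
            lob = np.full(ne, -np.inf)
            upb = np.full(ne, np.inf)
            if sign > 0:
                lob[idx] = 0.0
            else:
                upb[idx] = 0.0
            bounds = Bounds(lob, upb)

        if settings.gradient_mode == "fd":
            jac = "2-point"
        else:
            mode = settings.gradient_mode

            def jac(X, _mode=mode):
                return -self.objective_gradient(X, mode=_mode)

        # "1 part in 10^3" on the gradient is relative to the problem's own
        # gradient scale, which the per-electrode target means set.
        grad_scale = float(np.abs(self.electrode_region_means()[:, 0]).max())
        gtol_abs = settings.gradient_tol * max(grad_scale, 1e-300)

        iterates: list[np.ndarray] = [x0.copy()]

        def callback(xk, state=None):
            iterates.append(np.array(xk, dtype=float))

        def run_nlp(start):
            return minimize(
                lambda X: -self.objective(X),
                start,
                jac=jac,
                method="trust-constr",
                constraints=cons,
                bounds=bounds,
                callback=callback,
                options={
                    "maxiter": settings.max_iter,
                    "xtol": settings.step_tol,
                    "gtol": gtol_abs,
                    "verbose": 0,
                },
            )

        # The NLP chain: one interior-point run from the nominal start, then
        # deterministic restarts from the polished output (the barrier
        # machinery re-centers, which escapes premature stalls), plus one
        # chain seeded from the best feasible two-electrode pair.  All
        # iterates ever visited are polished and the best feasible one wins.
        pair_best, pair_obj = None, -np.inf
        for i in range(ne):
            for j in range(ne):
                if i == j:
                    continue
                d = np.zeros(ne)
                d[i], d[j] = 1.0, -1.0
                Xp = self.polish(d)
                if self.max_violation(Xp) <= settings.feasibility_tol:
                    obj = self.objective(Xp)
                    if obj > pair_obj:
                        pair_best, pair_obj = Xp, obj

        total_iter = 0
        last = None
        for start in ([x0, pair_best] if pair_best is not None else [x0]):
            x = np.array(start, dtype=float)
            for _ in range(1 + settings.n_restarts):
                res = run_nlp(x)
                total_iter += int(res.nit)
                x = self.polish(res.x)
                iterates.append(np.array(res.x, dtype=float))
                last = res

        best_X, best_obj = None, -np.inf
        for cand in iterates:
            Xp = self.polish(cand)
            if self.max_violation(Xp) <= settings.feasibility_tol:
                obj = self.objective(Xp)
                if obj > best_obj:
                    best_X, best_obj = Xp, obj
        if best_X is not None:
            best_X = self._refine(best_X, settings.feasibility_tol)
            best_obj = self.objective(best_X)

        termination ={0: "iterations", 1: "gradient", 2: "step", 3: "step", 4: "step"}.get(
            last.status, "converged"
        )
        if best_X is None:
            # no feasible iterate even after polishing: report honestly
            Xp = self.polish(last.x)
            cv = self.constraint_values(Xp)
            worst = max(cv, key=lambda c: c.violation)
            raise InfeasibleProblemError(
                f"no feasible pattern found; most violated constraint "
                f"{worst.name} (violation {worst.violation:.3e})",
                most_violated=worst.name,
                violation=worst.violation,
            )
        return SteeringResult(
            model=self,
            X=WeightVector(best_X, self.basis.montage),
            objective=best_obj,
            constraint_state=self.constraint_values(best_X),
            feasible=True,
            termination_reason=termination,
            n_iter=total_iter,
            settings=settings,
            solver_status=int(last.status),
            solver_message=str(last.message),
        )


@dataclass
class SteeringResult:
    """Fitted electrode pattern with diagnostics (statsmodels-style results)."""

    model: CurrentSteeringModel
    X: WeightVector
    objective: float  # mean target |J|, mA/cm^2
    constraint_state: list[ConstraintValue]
    feasible: bool
    termination_reason: str
    n_iter: int
    settings: OptimizerSettings
    solver_status: int = 0
    solver_message: str = ""

    @property
    def total_current_mA(self) -> float:
        return total_current(self.X)

    @property
    def extracranial_mA(self) -> float:
        return self.model.extracranial_remainder(self.X)

    @property
    def max_violation(self) -> float:
        return max(c.violation for c in self.constraint_state)

    def field(self):
        """Current-density field of the fitted pattern on the full head."""
        pot = superpose(self.model.basis, self.X)
        return current_density(pot, self.model.tensors)

    def region_summaries(self, extra_regions: dict | None = None) -> list[RegionSummary]:
        field = self.field()
        out = [
            region_summary(field, self.model.volume, self.model.target_labels,
                           region_name="target", pattern="optimized"),
        ]
        if self.model.avoid_labels:
            out.append(
                region_summary(field, self.model.volume, self.model.avoid_labels,
                               region_name="avoid", pattern="optimized")
            )
        for name, labels in (extra_regions or {}).items():
            out.append(
                region_summary(field, self.model.volume,
                               _resolve_labels(self.model.volume, labels),
                               region_name=name, pattern="optimized")
            )
        return out

    def summary(self) -> str:
        lines = [
            "Current steering optimization results",
            "=" * 53,
            f"{'Electrodes':<28}{self.model.n_electrodes:>25}",
            f"{'Objective: mean target |J|':<28}{self.objective:>17.6g} mA/cm^2",
            f"{'Total injected current':<28}{self.total_current_mA:>22.4g} mA",
            f"{'Extracranial remainder':<28}{self.extracranial_mA:>22.4g} mA",
            f"{'Termination':<28}{self.termination_reason:>25}",
            f"{'Iterations':<28}{self.n_iter:>25}",
            f"{'Max constraint violation':<28}{self.max_violation:>25.3e}",
            "-" * 53,
            f"{'electrode':<12}{'weight (mA)':>15}",
        ]
        for name, w in zip(self.model.basis.montage.names, self.X.values):
            lines.append(f"{name:<12}{w:>15.5f}")
        lines.append("-" * 53)
        lines.append(f"{'constraint':<34}{'value':>9}{'viol.':>10}")
        for c in self.constraint_state:
            flag = "on " if c.enabled else "off"
            lines.append(f"[{flag}] {c.name:<29}{c.value:>9.4g}{c.violation:>10.2e}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "weights_mA": self.X.values.tolist(),
            "electrodes": self.model.basis.montage.names,
            "objective_mA_per_cm2": self.objective,
            "total_current_mA": self.total_current_mA,
            "extracranial_mA": self.extracranial_mA,
            "feasible": self.feasible,
            "termination_reason": self.termination_reason,
            "n_iter": self.n_iter,
            "constraints": [
                {
                    "cid": c.cid,
                    "name": c.name,
                    "enabled": c.enabled,
                    "value": None if not np.isfinite(c.value) else c.value,
                    "violation": c.violation,
                }
                for c in self.constraint_state
            ],
        }


# -- functional surface -----------------------------------------------------

def precompute_region_means(
    basis: BasisSet,
    tensors: ConductivityTensorField,
    volume: TissueLabelVolume,
    regions: dict,
) -> np.ndarray:
    """m[i, g]: mean |J| (mA/cm^2) of basis field i over region g.

    ``regions`` maps region names to label names/ids; column order follows
    the mapping's order.
    """
    masks = {}
    for name, labels in regions.items():
        mask = volume.region_mask(_resolve_labels(volume, labels))
        if not mask.any():
            raise EmptyRegionError(f"region {name!r} contains no voxels")
        masks[name] = mask
    m = np.empty((basis.n_electrodes, len(masks)))
    for i in range(basis.n_electrodes):
        Jf = current_density(basis.field(i), tensors)
        for g, mask in enumerate(masks.values()):
            m[i, g] = A_m2_to_mA_cm2(np.linalg.norm(Jf.J[mask], axis=1).mean())
    return m


def optimize(
    problem: ProblemSpec,
    basis: BasisSet,
    tensors: ConductivityTensorField,
    volume: TissueLabelVolume,
    settings: OptimizerSettings | None = None,
) -> SteeringResult:
    """Build a :class:`CurrentSteeringModel` and fit it."""
    return CurrentSteeringModel(basis, tensors, volume, problem).fit(settings)


def brute_force_search(
    model: CurrentSteeringModel,
    n_samples: int,
    seed: int,
    chunk: int = 5_000,
) -> BruteForceResult:
    """Random-search oracle: sample X in [-1, 1]^NE, project onto the zero-sum
    plane (if constraint 1 is on), rescale each sample to its tightest upper
    bound inside [C_min, C_max], filter by feasibility, return the best.

    Deterministic for a fixed seed; the sample stream is consumed sequentially
    so increasing ``n_samples`` extends (never replaces) the search.
    """
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    p = model.problem
    c1, c2, c3, c4, c5 = p.constraints
    ne = model.n_electrodes
    Bt = model.region_basis("target")
    Ba = model.region_basis("avoid") if "avoid" in model._region_basis else None
    rng = np.random.default_rng(seed)

    best_obj = -np.inf
    best_X = None
    n_feasible = 0
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        S = rng.uniform(-1.0, 1.0, size=(m, ne))
        if c1:
            S = S - S.mean(axis=1, keepdims=True)
        if p.sign_fix is not None:
            idx, sign = p.sign_fix
            flip = sign * S[:, idx] < 0
            if c1:
                S[flip] *= -1.0
            else:
                S = S[~flip]
                if not len(S):
                    continue
        tc = 0.5 * np.abs(S).sum(axis=1)
        ok = tc > 0
        mt = A_m2_to_mA_cm2(
            np.linalg.norm(np.einsum("vce,se->svc", Bt, S), axis=2).mean(axis=1)
        )
        if Ba is not None:
            ma = A_m2_to_mA_cm2(
                np.linalg.norm(np.einsum("vce,se->svc", Ba, S), axis=2).mean(axis=1)
            )
        else:
            ma = np.zeros(len(S))
        lo = np.where(ok, p.C_min / np.maximum(tc, 1e-300), np.inf) if c3 else np.zeros(len(S))
        hi = np.full(len(S), np.inf)
        if c4:
            hi = np.minimum(hi, np.where(ok, p.C_max / np.maximum(tc, 1e-300), 0.0))
        if c2:
            with np.errstate(divide="ignore"):
                hi = np.minimum(hi, np.where(ma > 0, p.J_max / np.where(ma > 0, ma, 1.0), np.inf))
        s = np.where(np.isfinite(hi), hi, np.maximum(lo, 1.0))
        feasible = ok & (s >= lo) & np.isfinite(s)
        if c5:
            feasible &= mt >= p.r * ma
        n_feasible += int(feasible.sum())
        if feasible.any():
            objs = np.where(feasible, s * mt, -np.inf)
            j = int(np.argmax(objs))
            if objs[j] > best_obj:
                best_obj = float(objs[j])
                best_X = s[j] * S[j]
    if best_X is None:
        raise InfeasibleProblemError(
            f"brute-force search found no feasible sample in {n_samples} draws"
        )
    return BruteForceResult(
        X=WeightVector(best_X, model.basis.montage),
        objective=best_obj,
        n_feasible=n_feasible,
        n_samples=n_samples,
        seed=seed,
    )


def fix_sign(problem: ProblemSpec, electrode_index: int, sign: int,
             n_electrodes: int | None = None) -> ProblemSpec:
    """Return a copy of the problem with one electrode's weight sign fixed."""
    if sign not in (-1, 1):
        raise ConfigurationError("sign must be +1 or -1")
    if electrode_index < 0 or (n_electrodes is not None and electrode_index >= n_electrodes):
        raise ConfigurationError(f"invalid electrode index {electrode_index}")
    if problem.sign_fix is not None and problem.sign_fix != (electrode_index, sign):
        raise ConfigurationError(
            f"conflicting sign fix: already {problem.sign_fix}, requested "
            f"({electrode_index}, {sign})"
        )
    return replace(problem, sign_fix=(electrode_index, sign))


def reduce_pattern(X, k: int):
    """Keep the k largest-|X_i| electrodes; the rest of the current goes to an
    implicit extracranial electrode.

    Returns ``(reduced, remainder_mA)`` with ``remainder = -sum(kept)`` so the
    kept weights plus the remainder sum to zero exactly.  Ties at the k-th
    magnitude are broken toward the lowest electrode index.
    """
    w = as_weights(X)
    ne = len(w)
    if not 1 <= k <= ne:
        raise InvalidParameterError(f"k must be in [1, {ne}], got {k}")
    order = np.argsort(-np.abs(w.values), kind="stable")
    keep = np.zeros(ne, dtype=bool)
    keep[order[:k]] = True
    reduced = np.where(keep, w.values, 0.0)
    remainder = -float(reduced.sum())
    return WeightVector(reduced, w.montage), remainder


def scale_pattern(X, C_target: float) -> WeightVector:
    """Rescale X so its total injected current equals ``C_target`` (mA)."""
    w = as_weights(X)
    tc = total_current(w)
    if tc <= 0:
        raise InvalidParameterError("cannot scale a zero pattern")
    if not C_target > 0:
        raise InvalidParameterError("target total current must be positive")
    return WeightVector(w.values * (C_target / tc), w.montage)
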