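# Methods

## The physical model

At DC, current flow in the head is governed by the conduction equation
`∇·(D(x) ∇φ) = 0` on the head domain, where `D` is the (possibly
anisotropic) conductivity tensor field and `φ` the electric potential.
Boundary conditions: a prescribed normal current density `j` on electrode
patches (`D∇φ·n = j`, uniform over each patch), insulation (`j = 0`)
elsewhere on the skin, and a grounded caudal base plane `φ = 0` — the lowest
slice of the model, standing in for the current path through the neck and
body. Capacitive, inductive and frequency-dependent effects are ignored
(quasi-static DC).

Tissue conductivities (S/m) are the package defaults in
`src/tdcsteer/data/conductivities.yaml`: skin 0.43, CSF 1.8, sclera 0.5,
cortical bone 5.52e-3, cancelous bone 2.14e-2, muscle 0.16, fat 0.025, blood
0.67, gray matter 0.1, and anisotropic white matter with longitudinal 1.2 /
transverse 0.12 — low-frequency literature values. White-matter anisotropy
is expressed per voxel as `D = Aᵀ diag(σ_l, σ_t, σ_t) A` with
`A = R_z R_y R_x`; the Euler angles are *inputs* (deriving them from
diffusion imaging is out of scope). The longitudinal axis is the local
x-axis before rotation. `σ_l = σ_t` degenerates gracefully to isotropy;
negative conductivities are rejected; air is exactly zero.

## Discretisation

One trilinear hexahedral element per non-air voxel, the tensor constant per
element. Element stiffness matrices are assembled from six precomputed
8×8 "mode" matrices (one per unique tensor component, with 2×2×2 Gauss
quadrature, exact for this element) contracted against the per-voxel tensor
components — a vectorised assembly that handles ~10⁶-voxel models in
seconds. The electrode load is the consistent form of a uniform patch
current: each electrode's current is split over its boundary faces
proportional to face area, each face's share equally over its four corner
nodes, so every load vector sums to the injected current exactly.

Dirichlet (base-plane) nodes are removed by row/column elimination, keeping
the reduced operator symmetric positive definite and making superposition
identities hold to machine precision. Linear systems are solved with
Jacobi-preconditioned conjugate gradients; the default relative-residual
tolerance is 1e-8 (1e-10 for basis sets used in optimization). A direct
factorisation was evaluated and rejected: on these 3-D operators SuperLU
fill-in made it orders of magnitude slower than PCG even at 4 mm
resolution, while PCG converges fast even through the ~300× skull/CSF
conductivity contrast.

Per-voxel current density is `J = −D ∇φ` with the gradient evaluated at the
voxel center from the trilinear shape functions (equivalently, the mean of
the four parallel edge differences per axis) — consistent with the element,
not a cross-voxel finite difference. Net electrode flux is computed
variationally (the sum of `Kφ` over patch nodes), the discrete counterpart
of `∮ J·n dS`; this is what makes charge conservation exact to solver
tolerance instead of staircase-quadrature accuracy.

Units are SI internally (S/m, A, m, V, A/m²). Electrode weights are
exposed in mA and current densities in mA/cm² (1 A/m² = 0.1 mA/cm²), the
units of the tDCS literature. Voxel indices are 0-based, axis order
(x, y, z), spacing in mm.

## Montage and basis fields

An electrode is a connected patch of exterior voxel faces grown around a
surface point until its area is within 10% of the request; patches never
touch the base plane. The default 19-electrode montage mimics the 10–20 EEG
layout on a sphere (vertex, a 45° ring, the 10% equatorial ring, and
F3/F4/P3/P4 on great-circle midpoints); the exact 10–20 subset and its
spherical coordinates are a package choice, overridable via montage JSON.
Other electrode counts use a deterministic quasi-uniform spiral over the
upper surface. The contact model is uniform current over the patch — no
electrode–gel impedance (complete-electrode) model.

The *basis set* contains one potential field per electrode at 1 mA injected
against the grounded base. Because the problem is linear, the field of any
weight vector `X` (mA) is `V_X = Σ Xᵢ Vᵢ`, and its per-electrode flux is
exactly `Xᵢ`. Currents that do not sum to zero return through the base
plane, which is read as an implicit extracranial electrode; the remainder
`−Σ Xᵢ` is reported with every result.

## The steering problem

With `J(X)` the per-voxel current-density norm of the superposed field:

```
max_X  mean J_target(X)
s.t.   (1) Σᵢ Xᵢ = 0
       (2) mean J_avoid(X) < J_max
       (3) total(X) > C_min        total(X) = ½ Σᵢ |Xᵢ|
       (4) total(X) < C_max
       (5) mean J_target(X) ≥ r · mean J_avoid(X)
```

Every constraint is toggleable; only the upper current bound is essential.
The total injected current is the 1-norm convention `½Σ|Xᵢ|` (each unit of
current leaves through one electrode and enters through another, so the
half counts it once). Constraints use region *means* — their gradients are
computable — while reports also give medians, the conventional summary for
the roughly log-normal current-density distributions in tissue.

Region means of `J` are evaluated from precomputed per-region basis
current-density vectors (`n_voxels × 3 × NE` arrays), making objective and
constraint evaluations microsecond-cheap during optimization. Three
objective-gradient modes exist:

- `exact` (default): `∂/∂Xᵢ mean|J| = mean( (J·Jᵢ)/|J| )`, closed-form from
  the stored basis vectors;
- `surrogate`: the constant upper-bound gradient `mᵢ·sign(Xᵢ)`, where
  `mᵢ` is the mean target norm of basis field `i` alone — by the triangle
  inequality `mean J(X) ≤ Σ|Xᵢ| mᵢ`, historically used when the exact
  gradient was unaffordable; kept, and cross-validated against finite
  differences and the bound itself in the tests. It is piecewise constant,
  which degrades quasi-Newton steps — measured on the validation phantom it
  leaves 1–3% of objective on the table, hence not the default;
- `fd`: scipy's 2-point finite differences.

### Algorithm

1. **Interior-point NLP** (scipy `trust-constr`) with analytic Jacobians
   for all constraints; the `|Xᵢ|` kinks in the total-current constraint are
   smoothed with `√(x²+ε)`, ε = 1e-12. Default start: the zero vector
   nudged by 1e-3 mA on the electrode nearest the target centroid.
2. **Restart chain**: the NLP is re-run (default 8 restarts) from the
   polished output of the previous run; re-initialising the barrier escapes
   premature stalls. A second chain starts from the best feasible
   two-electrode pair. All visited iterates are retained as candidates.
3. **Feasibility polish**: every quantity is positively homogeneous of
   degree 1 in X, so any candidate is projected onto `ΣX = 0` and rescaled
   to the tightest enabled upper bound (`C_max` and/or `J_max`), which is
   simultaneously the objective-maximizing scale along its ray. This yields
   *exact* feasibility (violations at rounding level, well below the 1e-10
   acceptance threshold) rather than solver-tolerance feasibility.
4. **Pattern-search refinement**: deterministic best-improvement search
   along all electrode-pair directions (they span the zero-sum subspace)
   with step halving, each trial re-polished. This is what makes the result
   reproducible across warm starts and robust against the NLP's local
   stalls.

The best feasible candidate wins. Termination bookkeeping follows the
classical rules: iteration cap (default 100 per NLP run), relative step
below 1e-10, or first-order optimality below 1 part in 10³ — read as
*relative*, implemented as `gradient_tol × maxᵢ mᵢ`, since an absolute 1e-3
threshold is meaningless across problem scales. Feasibility is declared iff
the max violation, independently re-evaluated, is ≤ 1e-10. If no candidate
is feasible the fit raises with the most-violated constraint named.

The problem is sign-degenerate — `X` and `−X` give identical norms — which
`fix_sign` resolves by bounding one electrode's weight to a half-line; the
mirrored problems then produce exactly negated optima. `reduce_pattern`
keeps the k largest-|X| electrodes and routes the (exact) remainder to the
extracranial electrode, ties broken toward the lowest electrode index;
`scale_pattern` rescales a pattern to a prescribed total current.

A brute-force oracle (`brute_force_search`) samples X uniformly in
[−1, 1]^NE, projects onto the zero-sum plane, rescales each sample to its
tightest upper bound, filters by feasibility and returns the best — a lower
bound on the attainable objective that the fit must dominate. It consumes
its seeded stream sequentially, so enlarging the sample extends the search.

## Phantoms and oracles

The sphere phantom nests shells (defaults: skin 80 mm / cortical bone 74 /
CSF 70 / gray matter 66, 10–20-head-sized) and embeds target/avoid blobs;
a voxel takes the label of the shell containing its center. The sphere is
truncated by a flat plane at −0.9 R so the grounded base plane exists, and
the grid is laid out with that cut exactly at the lowest slice. An optional
white-matter core carries seeded random Euler angles, exercising the
anisotropic assembly path. The slab phantom gives 1-D flow with the exact
solution `J = I/A`, `ΔV = IL/(σA)` — linear in the element space, so the
solver reproduces it to ~1e-12.

The sphere oracle is the interior potential of a point current source on a
homogeneous sphere, `u = I/(4πσR) Σ_{n≥1} (2n+1)/n (r/R)ⁿ Pₙ(cos γ)`,
summed for a source/sink pair. Besides the truncated series (any order),
the package evaluates the *exact* sum via the Legendre generating
functions, `u = I/(4πσR)[2/s − 2 + ln(2/(1 − tx + s))]` with
`s = √(1−2tx+t²)`, so no truncation error enters solver comparisons.
FEM-vs-oracle comparisons exclude surface points within 15° of either
electrode center (point-source singularity vs finite patch) and below
−0.5 R (the grounded truncation plane is absent from the analytic
configuration), and mean-reference both fields over the comparison set;
these exclusions were fixed as part of the comparison design. Measured
agreement: 1.5% relative RMS at R = 80 mm / 2 mm voxels, with a monotone
6.8% → 2.5% → 1.7% ladder at R = 50 mm for 4 → 2 → 1 mm voxels (the floor
is set by the staircase surface and the ground-plane perturbation, not by
the solver tolerance).

### The validation study fixture

Tests and the reproduction script use one canonical steering study: the
4-shell sphere at 4 mm voxels, six 16 cm² electrodes, a 10 mm superficial
target blob under the frontal-left surface and a 10 mm deep central avoid
blob; dose limits `J_max = 5×10⁻⁴ mA/cm²` (0.5 µA/cm²), `C ∈ [0.5, 2] mA`,
contrast `r = 2`. Blob conductivity equals gray matter, so the blobs are
statistical regions, not electrical inhomogeneities. Electrode areas are
16 cm² (not the 22 cm² of full-head montages) because 19 electrode patches
of 22 cm² cannot sit disjointly on an 80 mm sphere — a real head is larger.
Problem sizes throughout (4–5 mm optimization phantoms, 2 mm validation
sphere, 10⁵ oracle samples) were chosen so the full chain runs on a single
CPU in minutes.

What the phantoms do *not* emulate: cortical folding, the skull's
three-layer structure, real 10–20 geometry on a non-spherical scalp,
tissue-conductivity uncertainty, and anatomically plausible white-matter
fibre orientations (the core's angles are random). Passing tests certify
the numerics — discretisation, superposition, conservation, optimization —
on known-truth geometry; they do not certify dosimetric accuracy for any
real head.

## Known limitations

- Voxel (staircase) surfaces bound the achievable surface-potential
  accuracy at a given resolution; there is no conforming surface mesh.
- The uniform-current electrode model ignores contact impedance; current
  crowding at patch edges is therefore not represented.
- The optimizer guarantees feasibility and oracle dominance, not global
  optimality; the objective is non-convex and mirrored/alternative optima
  exist by construction.
- Means, not medians, enter the constraints (medians have no usable
  gradient); the two can diverge for highly skewed distributions.
- The pipeline is deterministic for a fixed configuration and seed;
  BLAS-level reduction order may still perturb results at the 1e-12 level
  across platforms.
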