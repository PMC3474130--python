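# tdcsteer

Current steering for multi-electrode transcranial direct current stimulation
(tDCS) on voxel head models.

Conventional tDCS drives a weak direct current between one electrode pair,
which spreads current broadly through the head. With a montage of many small
scalp electrodes, the injected current per electrode becomes a design
variable: the current pattern can be *steered* to concentrate current density
in a chosen brain region while limiting it in regions to be spared (deep
structures, the eyes, the skin). `tdcsteer` implements the full computational
chain for this design problem:

- **Head model** — a labeled voxel volume (NIfTI) with a tissue conductivity
  table (S/m); white matter is anisotropic, with per-voxel tensors
  `D = Aᵀ diag(σ_l, σ_t, σ_t) A`, `A = R_z R_y R_x` built from Euler angles.
- **Forward solver** — the DC conduction (Laplace) problem
  `∇·(D∇φ) = 0` with uniform electrode current injection (`D∇φ·n = j` on
  electrode patches) and a grounded caudal base plane (`φ = 0`), discretised
  with trilinear hexahedral voxel elements and solved by preconditioned
  conjugate gradients.
- **Basis fields** — one potential field per electrode at 1 mA against the
  grounded base. Any montage pattern `X` (mA per electrode) is the weighted
  sum `V_X = Σᵢ Xᵢ Vᵢ`; per-voxel current density is `J = −D∇φ`, summarised
  by its Euclidean norm in mA/cm².
- **Optimization** — maximize the mean current-density norm in a target
  region subject to: zero net injected current (Σ Xᵢ = 0, droppable in favour
  of an implicit extracranial return electrode), a cap `J_max` on the mean
  norm in an avoid region, bounds `C_min < ½Σ|Xᵢ| < C_max` on the total
  injected current, and a target/avoid contrast ratio `r`. Solved with an
  interior-point method plus an exact homogeneity-based feasibility polish
  and a deterministic pattern-search refinement; a brute-force random-search
  oracle is built in for cross-checking.
- **Synthetic phantoms and oracles** — multi-shell truncated-sphere and slab
  phantoms with embedded target/avoid blobs, plus closed-form solutions
  (Ohm's-law slab, Legendre-series potential of a surface electrode pair on a
  homogeneous sphere) against which the solver is certified, so the whole
  chain is testable without any external dataset.

The optimizer follows a statsmodels-style surface: build a
`CurrentSteeringModel` from data, call `.fit()`, get a `SteeringResult` with
the weights, constraint diagnostics and a `summary()` table.

## Worked example

The shipped demo synthesizes a coarse four-shell sphere phantom
(skin/skull/CSF/gray matter, 5 mm voxels) with a superficial target blob and
a deep central avoid blob, places 4 electrodes, solves the basis fields, and
optimizes the montage:

```bash
tdcsteer run --config examples/demo_config.yaml
```

prints (abridged):

```
Current steering optimization results
=====================================================
Electrodes                                          4
Objective: mean target |J|         0.00289332 mA/cm^2
Total injected current                      0.8677 mA
Extracranial remainder                    1.11e-16 mA
Termination                                iterations
Max constraint violation                    1.110e-16
-----------------------------------------------------
electrode       weight (mA)
E01                 0.86771
E02                -0.02595
E03                -0.42185
E04                -0.41991
-----------------------------------------------------
constraint                            value     viol.
[on ] net_current_zero             -1.11e-16  1.11e-16
[on ] avoid_mean_below_J_max          0.0005  0.00e+00
[on ] total_current_above_C_min       0.8677  0.00e+00
[on ] total_current_below_C_max       0.8677  0.00e+00
[on ] target_at_least_r_times_avoid 0.001893  0.00e+00
```

Reading this: the fitted pattern injects 0.87 mA through the electrode over
the target blob (E01) and returns it through the two far electrodes, reaching
a mean target current-density norm of 2.9×10⁻³ mA/cm² while the avoid-region
mean sits exactly at its cap of 5×10⁻⁴ mA/cm² (the binding constraint — the
total-current budget of 2 mA is *not* exhausted because pushing more current
would overdose the avoid region). All constraints hold to 10⁻¹⁰ or better.
The run directory also contains `stats.csv` (per-region mean/median/
percentiles/max in mA/cm²), a norm map (`norm.nii.gz`), the basis fields
(`basis.h5`), and a reduced 2-electrode approximation of the pattern with its
extracranial remainder (`reduced.json`).

The same chain is available as a library:

```python
from tdcsteer import (PhantomSpec, Blob, build_phantom, standard_montage,
                      assemble_tensor_field, assemble, compute_basis,
                      ProblemSpec, CurrentSteeringModel)
from tdcsteer.phantoms import phantom_center_mm

spec = PhantomSpec(kind="sphere", voxel_mm=4.0,
                   target_blobs=(Blob((30, 18, 30), 10.0, "target"),),
                   avoid_blobs=(Blob((0, 0, -10), 10.0, "avoid"),))
volume, table, _ = build_phantom(spec)
montage = standard_montage(volume, n=19, area_cm2=16.0,
                           origin_mm=phantom_center_mm(spec))
tensors = assemble_tensor_field(volume, table)
basis = compute_basis(assemble(volume, tensors, montage))
problem = ProblemSpec(target=("target",), avoid=("avoid",),
                      J_max=5e-4, C_min=0.5, C_max=2.0, r=2.0)
result = CurrentSteeringModel(basis, tensors, volume, problem).fit()
print(result.summary())
```

CLI subcommands `build-phantom`, `basis`, `optimize`, `stats`, `reduce`, and
`run` expose each stage separately; see `tdcsteer --help`.

## Further reading

`docs/methods.md` documents the discretisation, boundary conditions, the
optimization algorithm and its termination rules, the phantom design, unit
conventions, and known limitations.
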