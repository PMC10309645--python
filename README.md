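# fmtrecon

Greedy sparse reconstruction for **fluorescence molecular tomography (FMT)**:
recovering the 3D distribution of a fluorescent probe inside scattering
tissue from photon intensities measured on the surface.

FMT reconstruction is severely ill-posed — measurements are few, photons
scatter strongly, and the unknown nodal yield field vastly outnumbers the
data. When the fluorophore marks a small lesion, the unknown is *sparse*,
and the inverse problem can be posed with an L0 prior:

```
min ||x||_0   subject to   ||A x − Φm||²₂ < ε
```

where `Φm` are surface intensities, `x` is the nodal fluorescent yield
(mm⁻¹) on a tetrahedral finite-element mesh, and `A` is the Born-coupled
system matrix obtained from two diffusion-equation FEM solves (excitation
and emission) with Robin boundary conditions.

The package provides:

- **`fmtrecon.mesh`** — tetrahedral meshes (structured cube generator,
  TetGen-style `.node/.ele` and legacy VTK I/O), boundary extraction, edge
  adjacency, and the neighbor operator `N(S)` over tetrahedral edges.
- **`fmtrecon.forward`** — P1 FEM assembly of the diffusion operator
  `−∇·(D∇Φ) + μa Φ = q`, `D = 1/(3(μa+μs′))`, with Robin boundary
  `Φ + 2AₙD ∂Φ/∂n = 0`; isotropic point sources one transport mean free
  path (1/μs′) beneath the surface; field-of-view detector selection; the
  system matrix `A[(s,d), j] = G_m(j,d) · Φx(j) · V_j`.
- **`fmtrecon.solvers`** — the core algorithm **NASOLS**
  (neighbor-based adaptive sparsity orthogonal least squares) and the
  baselines ASOLS, fixed-sparsity OLS, OMP, gOMP and CoSaMP. NASOLS needs
  no sparsity prior: the target sparsity `K_i` grows and the selection
  width `L_i` shrinks by ceilinged `∝ 1/(i+1)²` steps from `(K0, L0)`,
  and candidates are restricted to the tetrahedral-edge neighborhood of
  the current support, exploiting the spatial connectedness of a real
  lesion.
- **`fmtrecon.phantom`** — synthetic experiments: spherical/cylindrical
  yield targets, equally spaced projection sources, relative Gaussian
  measurement noise, and an end-to-end `run_experiment` that simulates on
  a refined mesh and inverts on a coarser one (no inverse crime).
- **`fmtrecon.metrics`** — location error (LE), NRMSE, contrast-to-noise
  ratio (CNR), and connected-component target-separation analysis.
- **`fmtrecon` CLI** — `mesh`, `simulate`, `reconstruct`, `evaluate`,
  `benchmark` subcommands with reproducible run manifests.

## Worked example

```python
import fmtrecon as fr

# two 1 mm spheres of yield 0.05 /mm, 4 mm edge-to-edge, in a 25 mm cube
targets = [fr.TargetSpec(center=(9.5, 12.5, 12.5)),
           fr.TargetSpec(center=(15.5, 12.5, 12.5))]
cfg = fr.ExperimentConfig(targets=targets, spacing_mm=25/16,
                          noise_level=0.0, seed=1,
                          solvers=("nasols", "ols"))
res = fr.run_experiment(cfg)          # simulate (refined mesh) + invert
for name, sol in res.solutions.items():
    rep = fr.evaluate(sol.x_hat, res.x_true, targets, res.mesh, res.graph)
    print(name, rep.text())
```

Printed output (NASOLS block):

```
Center (mm)              LE (mm)  NRMSE    CNR
(10.94,12.50,12.50)      1.44     0.1022   -0.00
(13.68,12.12,12.50)      1.85     0.1022   -0.00
```

Both spheres are recovered as separate clusters with sub-2 mm location
error. On noiseless data fixed-sparsity OLS also splits the energy, but
with 5% measurement noise it loses one of the targets in the majority of
repeats while the neighbor expansion keeps both — the failure mode the
method is designed to fix. (CNR is near zero here because each 1 mm target
covers a single node of the ~1.6 mm inverse mesh and the reconstruction
peaks on neighboring nodes; the single-target benchmark, whose target is
mesh-resolved, reports CNR ≈ 3.9.)

The same pipeline from the shell:

```bash
fmtrecon simulate --spacing 2.5 --noise 0 --seed 1 \
    --target 12.5,12.5,12.5,1.5 -o sim
fmtrecon reconstruct --system sim/system.h5 --mesh sim/inverse.node \
    --solver nasols -o rec
fmtrecon evaluate --solution rec/solution.csv --truth sim/phantom.csv \
    --mesh sim/inverse.node --targets sim/targets.csv -o eval
```

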