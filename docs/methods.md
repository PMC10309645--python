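# Methods

## Physical model

Continuous-wave light transport in strongly scattering tissue is modelled
by the diffusion approximation. For each wavelength band (excitation `x`,
emission `m`) the nodal fluence solves

    −∇·(D ∇Φ) + μa Φ = q,      D = 1 / (3 (μa + μs′)),

on a tetrahedral mesh with the Robin boundary condition
`Φ + 2 Aₙ D ∂Φ/∂n = 0`. The mismatch coefficient `Aₙ` is computed from the
tissue refractive index by the standard effective-reflection polynomial
fit, with `Aₙ = 1` exactly for a matched interface. Assembly is Galerkin
P1: element stiffness `V·D·(∇φi·∇φj)`, consistent mass `μa·V/20·(1+δij)`,
and a triangle boundary mass `Area/(24 Aₙ)·(1+δij)` from the Robin term.
The resulting operators are sparse, symmetric and positive definite; they
are factorized once (sparse LU) and reused across right-hand sides.

A collimated source hitting the surface is modelled as an isotropic point
source one transport mean free path `1/μs′` beneath the anchor along the
inward face normal, spread onto the enclosing element's vertices by
barycentric weights. Measurements are linear in the fluorescent yield by
Born coupling: row `(s, d)` of the system matrix is
`G_m(j, d) · Φx^s(j) · V_j` with `V_j` the lumped nodal volume and
`G_m(·, d)` obtained by one adjoint solve per detector node (the operator
is symmetric, so adjoint = forward with a unit point load). Tiny negative
FEM undershoots far from sources are clamped to zero, since both
Green's-function factors are physically nonnegative fields. Validation:
on the homogeneous 25 mm cube the fluence of a centered source matches the
infinite-medium Green's function `exp(−μeff r)/(4πDr)` to better than 20%
for r ∈ [4, 8] mm at 2.5 mm spacing, improving at 1.25 mm.

Default optical properties (config values, not reproductions of any
measured tissue) are μa = 0.02/0.01 mm⁻¹ (excitation/emission),
μs′ = 1.0 mm⁻¹, n = 1.37 — typical soft-tissue magnitudes in the FMT
literature.

## The solver family

All pursuits solve `min ||x||₀ s.t. ||Ax − Φm||² < ε` greedily. The OLS
machinery keeps, for every unselected column, a deflated vector `t_j`
(the component of `a_j` orthogonal to the accepted basis). A candidate's
score is `||q_j||` with `q_j = (a_j·r / a_j·t_j) t_j`, the residual's
projection onto the deflated direction; the accepted update appends
`u = q_j` to the basis and sets `r ← r − u`, which is exactly monotone in
`||r||` and keeps the basis orthogonal by construction. Candidates whose
deflated direction is numerically exhausted
(`|a_j·t_j| < 1e-12 ||a_j|| ||t_j||`) are excluded for that pass; argmax
ties break to the lowest column index for cross-platform determinism.

NASOLS adds two ingredients:

- **Adaptive schedule.** `K_i = K_{i−1} + ⌈K0/(i+1)²⌉` and
  `L_i = max(1, L_{i−1} − ⌈L0/(i+1)²⌉)`: large steps early, unit steps
  late. Defaults K0 = 6, L0 = 10 (the published operating point; the
  benchmark sweep reproduces the grid at reduced scale). The L-floor of 1
  exists because the raw recursion eventually yields non-positive widths.
- **Neighbor expansion.** After the initial L0-column stage, candidates
  are restricted to `N(S_i)`, the union of tetrahedral-edge neighbors of
  the support minus the support itself (selections are united with `S_i`,
  so keeping support members inside `N(S_i)` would waste selections).
  With a complete graph NASOLS reduces bitwise to ASOLS.

The final estimate solves restricted least squares on the first
`K_final = min(K_i, |S|)` selected columns (selection order), zeros
elsewhere; an optional nonnegativity clamp is off by default.

### Halting

The halting threshold ε is an absolute residual norm (default 1e-8), with
an optional relative mode, because the convention is scale-fragile: the
solvers are scale-equivariant only when ε is scaled with the data. On
synthetic data generated from a *different* (finer) mesh than the inverse
mesh, the residual floors at the forward-model mismatch (~1–2% of ||Φm||)
and an absolute 1e-8 is never reached; the while-loop alone would then
grow the support until the iteration cap and scatter the reconstruction.
The loop therefore also stops when an iteration improves the residual norm
by less than `stall_tol` (default 2%) of its current value — the same kind
of stagnation halt CoSaMP uses — or when `max_iter` (default 50) or the
selection cap `min(m, n)` is reached, or the candidate set empties (the
solution is then flagged non-converged).

### Initialization regimes

The initial support takes L0 columns scored over the whole mesh. Two
regimes are supported, switchable via `SolverConfig.init_single_pass`:

- **Re-scored** (library default): deflate and re-score between initial
  selections — the classical greedy behavior, and the right choice for
  incoherent systems (it is what makes exact recovery on random Gaussian
  matrices reliable, since the selection order then reflects actual
  residual reduction and the first-K truncation keeps the true columns).
- **Single pass** (enabled by the FMT experiment pipeline): take the top
  L0 columns of one scoring pass. FMT system-matrix columns of adjacent
  nodes are nearly parallel, so after one deflation the whole peak cluster
  is suppressed and re-scored initialization scatters the seed across the
  domain; a single pass seeds a compact cluster around the energy maximum,
  which the neighbor expansion then grows — the behavior the method is
  designed around.

Within later iterations the selection of `L_i` columns from `N(S_i)`
re-scores after every single selection by default (preserving the
orthogonality invariant exactly); a single-pass variant is available.

Baselines follow their standard published forms: OLS with fixed manual
sparsity (comparison value 10), OMP (one max-correlation atom per
iteration), gOMP (N = 3 atoms per iteration, target sparsity 6), CoSaMP
(identify 2K, merge, restricted LS, prune to K; stagnation-stopped;
comparison sparsity 8), ASOLS (adaptive schedule without the neighbor
restriction, K0 = 4).

## Synthetic test bed

The desk-scale geometry is a homogeneous 25 mm cube (the mouse-atlas
geometries of the original study are external data and are loadable but
not shipped). Targets are 1 mm-radius spheres (or 1 mm × 2 mm cylinders)
of yield 0.05 mm⁻¹ — the published target specification. Sources: 2–16
points equally spaced in angle at the mid-height plane, one transport mean
free path deep; detectors: boundary nodes within a 120° field of view
opposite each source, evenly subsampled to at most 64 per source (the
original system images the surface with a CCD; the cap models a finite
detector array and keeps the row count proportionate to the mesh).
Measurement noise is *relative* Gaussian: `y_i ← y_i(1 + σ g_i)` with σ
the quoted percentage — the common convention in this literature, the
alternative additive model being config-selectable. Negative noisy
intensities clamp to zero.

To avoid the inverse crime, data are simulated on a mesh refined 2× in
spacing and the phantom is evaluated independently on each mesh; the
resulting 1–2% systematic data-model mismatch is what exercises the
stagnation halt above.

What the test bed does **not** emulate: heterogeneous organ optical
properties (a region-label mechanism exists but defaults to homogeneous),
free-space CCD-to-surface light transport, CT-derived anatomy, and
autofluorescence background. Passing tests therefore demonstrate the
algorithmic properties (separation, noise robustness, schedule behavior)
on an idealized but honestly mismatched forward model, not performance on
animal data.

## Evaluation

- **LE**: Euclidean distance between the energy-weighted centroid of a
  reconstructed cluster and the true center. Validated against published
  table rows that recompute exactly from their printed centers.
- **NRMSE**: nodal RMSE normalized by the dynamic range of the true field.
- **CNR**: `(μ_ROI − μ_BCK) / sqrt(w_ROI σ²_ROI + w_BCK σ²_BCK)` with
  node-count-fraction weights and ROI = the true target node set;
  invariant under positive scaling of the reconstruction.
- **Separation**: the reconstructed region is the set of nodes ≥ 10% of
  the peak value (a configurable relative cut); its edge-connected
  components are matched to true targets by greedy nearest-centroid
  pairing without replacement. A target left unmatched reports no LE (the
  dash of a collapsed double-target reconstruction). A component counts as
  *resolved* when its matched LE is ≤ 2 mm; this guards against scattered
  fixed-sparsity solutions getting credit for fragments that land near a
  target by chance.

The NRMSE/CNR normalizations published alongside the original tables are
not independently recomputable from printed data; the formulas here are
documented package choices and are excluded from numeric comparisons.

## Problem sizes and determinism

Default experiment sizes — single target: 2.5 mm inverse mesh
(1331 nodes) with 1.25 mm forward mesh; double target: 25/16 mm inverse
mesh (4913 nodes) with ~0.78 mm forward mesh (35,937 nodes); 8
projections, ≤ 64 detectors each — chosen so a full experiment builds and
inverts in roughly a minute on one CPU while keeping the forward/inverse
separation. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); repeated runs are bit-identical, and solver
tie-breaks are index-deterministic.

## Known limitations

- The diffusion approximation is invalid within ~1 transport mean free
  path of sources and in low-scattering regions; no radiative-transfer or
  Monte Carlo reference is included.
- Nodal lumping of the emission source term keeps one adjoint solve per
  detector but is first-order accurate; refined meshes reduce the error.
- The stagnation halt trades a possible premature stop on slowly
  converging clean data for robustness on mismatched data; set
  `stall_tol=0` to recover the pure threshold-halting behavior.
- Greedy matching of clusters to targets is not globally optimal
  assignment; with ≤ 2 targets (all shipped protocols) it is.
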