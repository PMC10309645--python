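"""Synthetic FMT experiments: yield phantoms, projection layouts, noisy data.

The desk-scale test bed is a homogeneous 25 mm cube carrying one or two
small spherical (or cylindrical) fluorescent targets of yield 0.05 mm^-1 and
radius 1 mm.  Point sources sit one transport mean free path beneath equally
spaced anchors around the boundary at a fixed axial plane; each source is
read out by boundary detectors on the opposite side within a 120-degree
field of view.  Measurements carry relative (multiplicative) Gaussian noise:
"X% Gaussian noise" means each measurement is perturbed with standard
deviation X% of its own magnitude.

To avoid the inverse crime, data are simulated on a finer mesh than the one
used for inversion (refinement factor 2 by default) and the phantom is
evaluated independently on each mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .forward import (
    DetectorSet,
    Measurements,
    OpticalProperties,
    SourceSpec,
    SystemMatrix,
    build_system_matrix,
    place_point_source,
    select_detectors_fov,
)
from .mesh import (
    NeighborGraph,
    TetMesh,
    boundary_patch,
    edge_adjacency,
    generate_cube_mesh,
)
from . import solvers as _solvers

__all__ = [
    "TargetSpec",
    "ExperimentConfig",
    "ExperimentResult",
    "make_yield_phantom",
    "layout_projections",
    "simulate_measurements",
    "run_experiment",
]


@dataclass(frozen=True)
class TargetSpec:
    """One fluorescent inclusion.

    ``shape`` is ``"sphere"`` or ``"cylinder"`` (axis along z, total height
    ``height``); ``yield_value`` is the fluorescent yield in mm^-1.
    """

    center: tuple[float, float, float]
    radius: float = 1.0
    yield_value: float = 0.05
    shape: str = "sphere"
    height: float = 2.0

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError("radius must be positive")
        if not (self.yield_value > 0):
            raise ValueError("yield_value must be positive")
        if self.shape not in ("sphere", "cylinder"):
            raise ValueError("shape must be 'sphere' or 'cylinder'")

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = points - np.asarray(self.center)
        if self.shape == "sphere":
            return np.einsum("ij,ij->i", d, d) <= self.radius**2
        radial = d[:, 0] ** 2 + d[:, 1] ** 2 <= self.radius**2
        axial = np.abs(d[:, 2]) <= self.height / 2.0
        return radial & axial


def make_yield_phantom(mesh: TetMesh, targets: list[TargetSpec]) -> np.ndarray:
    """Nodal yield field: ``yield_value`` inside any target, 0 elsewhere.

    Overlapping targets take the maximum.  A target enclosing no node is
    smaller than the local mesh resolution and triggers a warning.
    """
    x = np.zeros(mesh.n_nodes)
    for t in targets:
        inside = t.contains(mesh.nodes)
        if not np.any(inside):
            warnings.warn(
                f"target at {t.center} encloses no mesh node "
                "(smaller than the mesh resolution)",
                RuntimeWarning, stacklevel=2,
            )
            continue
        x[inside] = np.maximum(x[inside], t.yield_value)
    return x


def layout_projections(
    mesh: TetMesh,
    patch,
    n: int,
    plane_coord: float,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    phase_deg: float = 0.0,
) -> list[np.ndarray]:
    """Source anchors equally spaced in angle on the boundary at one plane.

    Anchor k sits where the ray from the domain centroid (moved into the
    plane) at angle ``phase + k*360/n`` degrees about ``axis`` crosses the
    boundary.  Deterministic for fixed inputs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
    center = mesh.centroid()
    center = center + (plane_coord - center @ axis) * axis
    if not np.all((center >= lo - 1e-9) & (center <= hi + 1e-9)):
        raise ValueError("plane_coord lies outside the mesh")

    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    tri = mesh.nodes[patch.faces]
    anchors = []
    for k in range(n):
        theta = np.deg2rad(phase_deg) + 2.0 * np.pi * k / n
        d = np.cos(theta) * u + np.sin(theta) * v
        t_hit = _ray_boundary(center, d, tri)
        if t_hit is None:
            raise ValueError("projection ray misses the boundary")
        anchors.append(center + t_hit * d)
    return anchors


def _ray_boundary(origin: np.ndarray, direction: np.ndarray,
                  tri: np.ndarray) -> float | None:
    """Farthest positive ray-triangle intersection (Moller-Trumbore, vectorized)."""
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    pvec = np.cross(direction[None, :], e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin[None, :] - tri[:, 0]
    uu = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    vv = qvec @ direction * inv
    tt = np.einsum("ij,ij->i", qvec, e2) * inv
    hit = ok & (uu >= -1e-9) & (vv >= -1e-9) & (uu + vv <= 1 + 1e-9) & (tt > 1e-9)
    if not np.any(hit):
        return None
    return float(tt[hit].max())


def simulate_measurements(A_forward: SystemMatrix, x_true: np.ndarray,
                          noise_level: float, seed: int) -> Measurements:
    """Project the phantom and add relative Gaussian measurement noise.

    y_i <- (A x)_i * (1 + noise_level * g_i) with g_i iid standard normal
    drawn from ``seed``; negative noisy intensities are clamped to 0.
    """
    if not (0.0 <= noise_level < 1.0):
        raise ValueError("noise_level must lie in [0, 1)")
    y = A_forward.values @ np.asarray(x_true, dtype=float)
    if noise_level > 0.0:
        g = np.random.default_rng(seed).standard_normal(len(y))
        y = y * (1.0 + noise_level * g)
        np.clip(y, 0.0, None, out=y)
    return Measurements(values=y)


# ---------------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------------

_DEFAULT_PROPS_X = OpticalProperties(mua=0.02, musp=1.0, n_refr=1.37)
_DEFAULT_PROPS_M = OpticalProperties(mua=0.01, musp=1.0, n_refr=1.37)


@dataclass
class ExperimentConfig:
    """Full description of one synthetic reconstruction experiment."""

    targets: list[TargetSpec]
    side_mm: float = 25.0
    spacing_mm: float = 2.5
    refine: int = 2                      # forward-mesh refinement factor
    n_projections: int = 8
    fov_deg: float = 120.0
    plane_coord: float | None = None     # default: mid-plane
    noise_level: float = 0.0
    seed: int = 0
    max_detectors: int | None = 64
    props_x: OpticalProperties = _DEFAULT_PROPS_X
    props_m: OpticalProperties = _DEFAULT_PROPS_M
    # single-pass initial scoring keeps the seed support compact on the
    # highly coherent FMT operator (see SolverConfig.init_single_pass)
    solver_cfg: _solvers.SolverConfig = field(
        default_factory=lambda: _solvers.SolverConfig(init_single_pass=True))
    solvers: tuple[str, ...] = ("nasols", "asols", "ols", "cosamp", "gomp")
    # fixed sparsity levels of the comparison solvers
    K_asols: int = 4
    K_ols: int = 10
    K_cosamp: int = 8
    K_gomp: int = 6
    gomp_n: int = 3                      # atoms added per gOMP iteration

    def __post_init__(self) -> None:
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")
        if not (0.0 <= self.noise_level < 1.0):
            raise ValueError("noise_level must lie in [0, 1)")
        if self.refine < 1:
            raise ValueError("refine must be >= 1")


@dataclass
class ExperimentResult:
    """Inverse-mesh geometry, data, and per-solver reconstructions."""

    mesh: TetMesh
    graph: NeighborGraph
    A: SystemMatrix
    y: Measurements
    x_true: np.ndarray               # phantom on the inverse mesh
    solutions: dict[str, _solvers.Solution]
    sources: list[SourceSpec]


def _system_for_mesh(mesh: TetMesh, cfg: ExperimentConfig,
                     anchors: list[np.ndarray],
                     detector_coords: list[np.ndarray] | None = None):
    """A on one mesh; detector nodes either chosen by FOV or matched to
    given physical coordinates (for the forward/inverse mesh pair)."""
    patch = boundary_patch(mesh)
    loads, specs, dsets = [], [], []
    for anchor in anchors:
        b, spec = place_point_source(mesh, patch, anchor, cfg.props_x.musp)
        loads.append((b, spec))
        specs.append(spec)
    if detector_coords is None:
        for spec in specs:
            dsets.append(select_detectors_fov(mesh, patch, spec, cfg.fov_deg,
                                              max_detectors=cfg.max_detectors))
    else:
        from scipy.spatial import cKDTree
        tree = cKDTree(mesh.nodes[patch.boundary_nodes])
        for coords in detector_coords:
            _, idx = tree.query(coords)
            dsets.append(DetectorSet(node_ids=patch.boundary_nodes[idx]))
    A = build_system_matrix(mesh, cfg.props_x, cfg.props_m, loads, dsets, patch)
    return A, specs, dsets, patch


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Simulate measurements on a refined mesh, invert on the coarse mesh.

    Fully deterministic for a fixed (config, seed): sources are laid out,
    data are generated on the forward mesh (refinement ``cfg.refine``) with
    the configured noise, the system matrix is rebuilt on the inverse mesh
    at the same physical source/detector positions, and every configured
    solver runs on the identical (A, y).
    """
    inv_mesh = generate_cube_mesh(cfg.side_mm, cfg.spacing_mm)
    plane = cfg.plane_coord if cfg.plane_coord is not None else cfg.side_mm / 2.0
    inv_patch = boundary_patch(inv_mesh)
    anchors = layout_projections(inv_mesh, inv_patch, cfg.n_projections, plane)

    A_inv, specs, dsets, _ = _system_for_mesh(inv_mesh, cfg, anchors)
    det_coords = [inv_mesh.nodes[ds.node_ids] for ds in dsets]

    if cfg.refine > 1:
        fwd_mesh = generate_cube_mesh(cfg.side_mm, cfg.spacing_mm / cfg.refine)
        A_fwd, _, _, _ = _system_for_mesh(fwd_mesh, cfg, anchors, det_coords)
    else:
        fwd_mesh, A_fwd = inv_mesh, A_inv

    x_fwd = make_yield_phantom(fwd_mesh, cfg.targets)
    y = simulate_measurements(A_fwd, x_fwd, cfg.noise_level, cfg.seed)

    graph = edge_adjacency(inv_mesh)
    x_true = make_yield_phantom(inv_mesh, cfg.targets)

    solutions: dict[str, _solvers.Solution] = {}
    for name in cfg.solvers:
        if name == "nasols":
            solutions[name] = _solvers.nasols(A_inv.values, y.values, graph,
                                              cfg.solver_cfg)
        elif name == "asols":
            acfg = replace(cfg.solver_cfg, K0=cfg.K_asols)
            solutions[name] = _solvers.asols(A_inv.values, y.values, acfg)
        elif name == "ols":
            solutions[name] = _solvers.ols_fixed(A_inv.values, y.values,
                                                 cfg.K_ols, cfg.solver_cfg)
        elif name == "cosamp":
            solutions[name] = _solvers.cosamp(A_inv.values, y.values,
                                              cfg.K_cosamp, cfg.solver_cfg)
        elif name == "gomp":
            solutions[name] = _solvers.gomp(A_inv.values, y.values,
                                            K=cfg.K_gomp,
                                            N_per_iter=cfg.gomp_n,
                                            cfg=cfg.solver_cfg)
        elif name == "omp":
            solutions[name] = _solvers.omp(A_inv.values, y.values,
                                           cfg.K_gomp, cfg.solver_cfg)
        else:
            raise ValueError(f"unknown solver {name!r}")
    return ExperimentResult(mesh=inv_mesh, graph=graph, A=A_inv, y=y,
                            x_true=x_true, solutions=solutions, sources=specs)
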