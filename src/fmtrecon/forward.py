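"""Diffusion-approximation forward model for continuous-wave FMT.

Light transport in highly scattering tissue is modelled by the diffusion
equation -div(D grad Phi) + mua Phi = q with diffusion coefficient
D = 1/(3(mua + musp)) and Robin boundary condition
Phi + 2 A_n D dPhi/dn = 0, where A_n accounts for the refractive-index
mismatch at the tissue-air interface.  Excitation and emission wavelengths
are two independent solves of this equation; Born (first-order) coupling of
the two fields makes the surface emission measurements linear in the nodal
fluorescent yield x:

    phi_m = A x,    A[(s,d), j] = G_m(j, d) * Phi_x^s(j) * V_j

with Phi_x^s the excitation fluence of source s, G_m(., d) the emission
Green's function of detector d (one adjoint solve per detector; the FEM
operator is symmetric so the adjoint equals a forward solve), and V_j the
lumped nodal volume.

Everything is assembled with P1 (linear) elements on tetrahedra, giving
sparse symmetric positive-definite systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .mesh import BoundaryPatch, TetMesh, boundary_patch

__all__ = [
    "OpticalProperties",
    "SourceSpec",
    "DetectorSet",
    "SystemMatrix",
    "Measurements",
    "assemble_diffusion_system",
    "place_point_source",
    "select_detectors_fov",
    "build_system_matrix",
    "save_system",
    "load_system",
]


class ConfigurationError(ValueError):
    """Missing or inconsistent optical/geometry configuration."""


class GeometryError(ValueError):
    """A requested point or placement falls outside the mesh."""


# ---------------------------------------------------------------------------
# optical properties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalProperties:
    """Optical coefficients of one tissue region at one wavelength band.

    Parameters
    ----------
    mua : float
        Absorption coefficient, mm^-1.
    musp : float
        Reduced scattering coefficient, mm^-1.
    n_refr : float
        Tissue refractive index (>= 1) relative to the surrounding air.
    """

    mua: float
    musp: float
    n_refr: float = 1.0

    def __post_init__(self) -> None:
        if not (self.mua > 0 and self.musp > 0):
            raise ConfigurationError("mua and musp must be positive")
        if self.n_refr < 1.0:
            raise ConfigurationError("n_refr must be >= 1")

    @property
    def D(self) -> float:
        """Diffusion coefficient 1/(3(mua+musp)), mm."""
        return 1.0 / (3.0 * (self.mua + self.musp))

    @property
    def transport_mfp(self) -> float:
        """Transport mean free path 1/musp, mm."""
        return 1.0 / self.musp

    @property
    def A_n(self) -> float:
        """Robin boundary coefficient from the index mismatch.

        Uses the standard effective-reflection fit R_eff(n) with
        A_n = (1+R_eff)/(1-R_eff); exactly 1 for a matched interface.
        """
        n = self.n_refr
        if n == 1.0:
            return 1.0
        r_eff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
        return (1.0 + r_eff) / (1.0 - r_eff)


def _props_per_element(mesh: TetMesh, props) -> list[OpticalProperties]:
    """Normalize props to one record per element via region labels."""
    if isinstance(props, OpticalProperties):
        return [props] * mesh.n_elements
    labels = np.unique(mesh.region_label)
    missing = [int(l) for l in labels if int(l) not in props]
    if missing:
        raise ConfigurationError(f"no optical properties for region label(s) {missing}")
    return [props[int(l)] for l in mesh.region_label]


# ---------------------------------------------------------------------------
# FEM assembly
# ---------------------------------------------------------------------------

def assemble_diffusion_system(
    mesh: TetMesh,
    props: OpticalProperties | dict[int, OpticalProperties],
    patch: BoundaryPatch | None = None,
) -> sp.csr_matrix:
    """Galerkin P1 assembly of the diffusion operator with Robin boundary.

    Returns the sparse symmetric positive-definite matrix of
    -div(D grad Phi) + mua Phi = q with Phi + 2 A_n D dPhi/dn = 0, i.e.
    stiffness (D) + mass (mua) + boundary mass (1/(2 A_n)).

    ``props`` is a single record for homogeneous media or a mapping from
    region label to record.
    """
    if patch is None:
        patch = boundary_patch(mesh)
    per_el = _props_per_element(mesh, props)
    D_el = np.array([p.D for p in per_el])
    mua_el = np.array([p.mua for p in per_el])

    el = mesh.elements
    p = mesh.nodes[el]                       # (M, 4, 3)
    J = p[:, 1:] - p[:, :1]                  # (M, 3, 3)
    detJ = np.linalg.det(J)
    vol = np.abs(detJ) / 6.0
    Jinv = np.linalg.inv(J)                  # rows: gradients of local coords
    # gradients of the 4 P1 basis functions (constant per element)
    g = np.empty((len(el), 4, 3))
    g[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)

    # element stiffness V * D * (gi . gj) and consistent mass mua*V/20*(1+dij)
    K_el = np.einsum("eid,ejd->eij", g, g) * (vol * D_el)[:, None, None]
    M_el = (np.ones((4, 4)) + np.eye(4))[None] * (mua_el * vol / 20.0)[:, None, None]
    A_el = K_el + M_el

    rows = np.repeat(el, 4, axis=1).ravel()
    cols = np.tile(el, (1, 4)).ravel()
    A = sp.coo_matrix((A_el.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))

    # Robin boundary term: (1/(2 A_n)) * integral of phi_i phi_j over faces,
    # triangle mass = Area/12 * (1+dij); A_n from the owning element's region.
    An_face = np.array([per_el[e].A_n for e in patch.face_elements])
    B_el = (np.ones((3, 3)) + np.eye(3))[None] * \
        (patch.areas / (2.0 * An_face) / 12.0)[:, None, None]
    brows = np.repeat(patch.faces, 3, axis=1).ravel()
    bcols = np.tile(patch.faces, (1, 3)).ravel()
    B = sp.coo_matrix((B_el.ravel(), (brows, bcols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    out = (A + B).tocsr()
    if not np.all(np.isfinite(out.data)):
        raise ConfigurationError("assembled system contains non-finite entries")
    return out


# ---------------------------------------------------------------------------
# sources and detectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceSpec:
    """An isotropic point source one transport mean free path below the surface.

    A collimated beam hitting the boundary at ``surface_anchor`` is modelled
    as an isotropic emitter at depth 1/musp along the inward surface normal.
    """

    surface_anchor: tuple[float, float, float]
    interior_position: tuple[float, float, float]
    amplitude: float = 1.0


@dataclass(frozen=True)
class DetectorSet:
    """Boundary node indices acting as measurement sites for one source."""

    node_ids: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_ids",
                           np.asarray(self.node_ids, dtype=np.intp))
        if len(self.node_ids) == 0:
            raise ConfigurationError("detector set is empty")


def _barycentric(p: np.ndarray, tet: np.ndarray) -> np.ndarray:
    T = np.column_stack([tet[1] - tet[0], tet[2] - tet[0], tet[3] - tet[0]])
    lam = np.linalg.solve(T, p - tet[0])
    return np.concatenate([[1.0 - lam.sum()], lam])


def find_element(mesh: TetMesh, point: np.ndarray, tol: float = 1e-9) -> tuple[int, np.ndarray]:
    """Locate the element containing ``point``; returns (element, barycentric)."""
    point = np.asarray(point, dtype=float)
    p = mesh.nodes[mesh.elements]
    # vectorized barycentric test over all elements
    T = np.transpose(p[:, 1:] - p[:, :1], (0, 2, 1))
    rhs = point[None, :] - p[:, 0, :]
    lam = np.linalg.solve(T, rhs[:, :, None])[:, :, 0]
    lam0 = 1.0 - lam.sum(axis=1)
    bary = np.column_stack([lam0, lam])
    inside = np.all(bary >= -tol, axis=1)
    hits = np.flatnonzero(inside)
    if len(hits) == 0:
        raise GeometryError(f"point {point.tolist()} lies outside the mesh")
    e = int(hits[0])
    return e, np.clip(bary[e], 0.0, None) / np.clip(bary[e], 0.0, None).sum()


def place_point_source(
    mesh: TetMesh,
    patch: BoundaryPatch,
    anchor: np.ndarray,
    musp: float,
    amplitude: float = 1.0,
) -> tuple[np.ndarray, SourceSpec]:
    """Build the FEM load vector for a source anchored on the boundary.

    The interior position sits one transport mean free path (1/musp) beneath
    ``anchor`` along the inward normal of the nearest boundary face; the unit
    load is spread onto the vertices of the enclosing element by barycentric
    weights, so it sums to ``amplitude``.
    """
    anchor = np.asarray(anchor, dtype=float)
    fc = patch.face_centroids(mesh)
    face = int(np.argmin(np.linalg.norm(fc - anchor, axis=1)))
    inward = -patch.normals[face]
    pos = anchor + inward / musp
    try:
        e, bary = find_element(mesh, pos)
    except GeometryError as exc:
        raise GeometryError(
            f"interior source position {pos.tolist()} falls outside the mesh"
        ) from exc
    b = np.zeros(mesh.n_nodes)
    b[mesh.elements[e]] = bary * amplitude
    spec = SourceSpec(surface_anchor=tuple(anchor), interior_position=tuple(pos),
                      amplitude=amplitude)
    return b, spec


def _angle_about(points: np.ndarray, center: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Angular coordinate of points about ``axis`` through ``center``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    d = points - center
    return np.arctan2(d @ v, d @ u)


def select_detectors_fov(
    mesh: TetMesh,
    patch: BoundaryPatch,
    source: SourceSpec,
    fov_deg: float = 120.0,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    max_detectors: int | None = 64,
) -> DetectorSet:
    """Boundary nodes on the side opposite a source, within an angular window.

    Nodes are kept when their angular coordinate about ``axis`` (measured
    from the domain centroid) lies within +-fov_deg/2 of the direction
    opposite the source.  ``max_detectors`` subsamples the window evenly
    (ordered by angle) to model a finite detector array; ``None`` keeps all.
    """
    if not (0.0 < fov_deg <= 360.0):
        raise ConfigurationError("fov_deg must lie in (0, 360]")
    center = mesh.centroid()
    axis_v = np.asarray(axis, dtype=float)
    axis_v = axis_v / np.linalg.norm(axis_v)
    d = mesh.nodes[patch.boundary_nodes] - center
    radial = np.linalg.norm(d - np.outer(d @ axis_v, axis_v), axis=1)
    if fov_deg < 360.0:
        # nodes on the rotation axis have no defined angular coordinate
        usable = patch.boundary_nodes[radial > 1e-9]
    else:
        usable = patch.boundary_nodes
    theta_nodes = _angle_about(mesh.nodes[usable], center, axis)
    theta_src = float(_angle_about(np.asarray(source.surface_anchor)[None, :],
                                   center, axis)[0])
    delta = np.angle(np.exp(1j * (theta_nodes - (theta_src + np.pi))))
    keep = np.abs(delta) <= np.deg2rad(fov_deg) / 2.0 + 1e-12
    ids = usable[keep]
    if len(ids) == 0:
        raise ConfigurationError("field of view selects no boundary nodes")
    order = np.argsort(delta[keep], kind="stable")
    ids = ids[order]
    if max_detectors is not None and len(ids) > max_detectors:
        pick = np.linspace(0, len(ids) - 1, max_detectors).round().astype(int)
        ids = ids[np.unique(pick)]
    return DetectorSet(node_ids=np.sort(ids))


# ---------------------------------------------------------------------------
# system matrix
# ---------------------------------------------------------------------------

@dataclass
class SystemMatrix:
    """Dense Born-coupled system matrix A of phi_m = A x.

    Rows are stacked (source, detector) pairs, source-major; columns are mesh
    nodes.  ``row_index`` holds the (source id, detector node id) of each row.
    """

    values: np.ndarray
    row_index: np.ndarray  # (rows, 2): source index, detector node index

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __matmul__(self, x: np.ndarray) -> np.ndarray:
        return self.values @ x


@dataclass
class Measurements:
    """Surface photon intensities aligned with the rows of a SystemMatrix."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("measurement vector contains non-finite entries")

    def __len__(self) -> int:
        return len(self.values)


def build_system_matrix(
    mesh: TetMesh,
    props_x: OpticalProperties | dict[int, OpticalProperties],
    props_m: OpticalProperties | dict[int, OpticalProperties],
    sources: list[tuple[np.ndarray, SourceSpec]],
    detectors: list[DetectorSet],
    patch: BoundaryPatch | None = None,
    row_normalize: bool = False,
) -> SystemMatrix:
    """Assemble the measurement operator A by Born coupling.

    For every source the excitation system (``props_x``) is solved for the
    fluence Phi_x; for every distinct detector node the emission system
    (``props_m``) is solved adjointly with a unit point load, giving the
    Green's function G_m(., d).  Row (s, d) then has entries
    G_m(j, d) * Phi_x(j) * V_j over nodes j.  Both operators are factorized
    once and reused across right-hand sides.

    ``row_normalize`` divides each row (for later, the matching measurement)
    by its own Euclidean norm; off by default.
    """
    if patch is None:
        patch = boundary_patch(mesh)
    if len(sources) != len(detectors):
        raise ConfigurationError("need one detector set per source")
    bset = set(int(i) for i in patch.boundary_nodes)
    for ds in detectors:
        stray = [int(d) for d in ds.node_ids if int(d) not in bset]
        if stray:
            raise ConfigurationError(f"detector node(s) {stray} are not boundary nodes")

    Ax = assemble_diffusion_system(mesh, props_x, patch)
    Am = assemble_diffusion_system(mesh, props_m, patch)
    lu_x = splu(Ax.tocsc())
    lu_m = splu(Am.tocsc())

    vols = mesh.nodal_volumes()
    unique_d = np.unique(np.concatenate([ds.node_ids for ds in detectors]))
    G = np.empty((len(unique_d), mesh.n_nodes))
    for k, d in enumerate(unique_d):
        e = np.zeros(mesh.n_nodes)
        e[d] = 1.0
        G[k] = lu_m.solve(e)
    g_of = {int(d): k for k, d in enumerate(unique_d)}

    rows, index = [], []
    for s, ((b, spec), ds) in enumerate(zip(sources, detectors)):
        phi_x = lu_x.solve(b)
        w = phi_x * vols
        for d in ds.node_ids:
            rows.append(G[g_of[int(d)]] * w)
            index.append((s, int(d)))
    values = np.array(rows)
    # tiny negative FEM undershoots far from the source are discretization
    # artifacts; both Green's-function factors are nonnegative fields
    np.clip(values, 0.0, None, out=values)
    if row_normalize:
        nrm = np.linalg.norm(values, axis=1, keepdims=True)
        nrm[nrm == 0.0] = 1.0
        values = values / nrm
    return SystemMatrix(values=values, row_index=np.array(index, dtype=np.intp))


def solve_fluence(
    mesh: TetMesh,
    props: OpticalProperties | dict[int, OpticalProperties],
    load: np.ndarray,
    patch: BoundaryPatch | None = None,
) -> np.ndarray:
    """Solve one diffusion system for the nodal fluence of a given load."""
    A = assemble_diffusion_system(mesh, props, patch)
    return splu(A.tocsc()).solve(np.asarray(load, dtype=float))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_system(path: str | Path, A: SystemMatrix, y: Measurements | None = None,
                mesh_ref: str = "") -> None:
    """Persist A (and optionally phi_m) in an HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("A", data=A.values)
        fh.create_dataset("row_index", data=A.row_index)
        fh.attrs["mesh_ref"] = mesh_ref
        if y is not None:
            fh.create_dataset("phi_m", data=y.values)


def load_system(path: str | Path) -> tuple[SystemMatrix, Measurements | None, str]:
    with h5py.File(path, "r") as fh:
        A = SystemMatrix(values=fh["A"][...], row_index=fh["row_index"][...])
        y = Measurements(values=fh["phi_m"][...]) if "phi_m" in fh else None
        ref = str(fh.attrs.get("mesh_ref", ""))
    return A, y, ref


def export_matrix_market(path: str | Path, A: SystemMatrix) -> None:
    mmwrite(str(path), sp.coo_matrix(A.values))


def import_matrix_market(path: str | Path) -> SystemMatrix:
    m = mmread(str(path))
    vals = np.asarray(m.todense() if sp.issparse(m) else m, dtype=float)
    idx = np.column_stack([np.zeros(len(vals), dtype=np.intp),
                           np.arange(len(vals), dtype=np.intp)])
    return SystemMatrix(values=vals, row_index=idx)
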