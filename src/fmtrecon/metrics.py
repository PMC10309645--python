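"""Reconstruction quality indicators: LE, NRMSE, CNR, target separation.

Location error (LE) is the Euclidean distance between the energy-weighted
centroid of a reconstructed cluster and the true target center.  NRMSE is
the nodal root-mean-square error normalized by the dynamic range of the
true field.  CNR contrasts the mean reconstructed value inside the true
target region against the background, pooled over the two variances with
node-count-fraction weights.  A multi-target reconstruction counts as
resolved when the thresholded support splits into at least as many
edge-connected components as there are true targets, each matched to its
nearest true center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import NeighborGraph, TetMesh, connected_components
from .phantom import TargetSpec

__all__ = [
    "EvaluationReport",
    "weighted_centroid",
    "location_error",
    "nrmse",
    "cnr",
    "evaluate",
]

# nodes at or above this fraction of the peak belong to the reconstructed region
SUPPORT_THRESHOLD = 0.1


@dataclass
class EvaluationReport:
    """Per-target and global indicators for one reconstruction."""

    le: list[float | None]                 # per true target, None if unmatched
    nrmse: float
    cnr: float | None
    n_components: int
    resolved: bool
    matched_centroids: list[np.ndarray | None]

    def rows(self) -> list[dict]:
        out = []
        for k, (e, c) in enumerate(zip(self.le, self.matched_centroids)):
            out.append({
                "target": k + 1,
                "center_x": None if c is None else float(c[0]),
                "center_y": None if c is None else float(c[1]),
                "center_z": None if c is None else float(c[2]),
                "le_mm": e,
                "nrmse": self.nrmse,
                "cnr": self.cnr,
                "n_components": self.n_components,
                "resolved": self.resolved,
            })
        return out

    def text(self) -> str:
        lines = ["Center (mm)              LE (mm)  NRMSE    CNR"]
        for e, c in zip(self.le, self.matched_centroids):
            cs = "--" if c is None else f"({c[0]:.2f},{c[1]:.2f},{c[2]:.2f})"
            es = "--" if e is None else f"{e:.2f}"
            cn = "--" if self.cnr is None else f"{self.cnr:.2f}"
            lines.append(f"{cs:<24} {es:<8} {self.nrmse:<8.4f} {cn}")
        return "\n".join(lines)


def weighted_centroid(x: np.ndarray, cluster, mesh: TetMesh) -> np.ndarray:
    """Energy-weighted centroid sum(x_i p_i)/sum(x_i) over cluster nodes."""
    idx = np.fromiter((int(k) for k in sorted(cluster)), dtype=np.intp)
    if len(idx) == 0:
        raise ValueError("cluster is empty")
    w = np.asarray(x, dtype=float)[idx]
    total = w.sum()
    if total <= 0:
        raise ValueError("cluster has non-positive total weight")
    return (w[:, None] * mesh.nodes[idx]).sum(axis=0) / total


def location_error(c_rec, c_true) -> float:
    """Euclidean distance between reconstructed and true centers (mm)."""
    return float(np.linalg.norm(np.asarray(c_rec, float) - np.asarray(c_true, float)))


def nrmse(x_rec: np.ndarray, x_true: np.ndarray) -> float:
    """RMSE over nodes normalized by the true field's dynamic range."""
    x_rec = np.asarray(x_rec, dtype=float)
    x_true = np.asarray(x_true, dtype=float)
    if x_rec.shape != x_true.shape:
        raise ValueError("fields must live on the same mesh")
    rng = float(x_true.max() - x_true.min())
    if rng == 0.0:
        raise ValueError("NRMSE undefined for a constant true field")
    return float(np.sqrt(np.mean((x_rec - x_true) ** 2)) / rng)


def cnr(x_rec: np.ndarray, roi) -> float:
    """ROI-vs-background contrast over pooled, fraction-weighted variance.

    CNR = (mu_ROI - mu_BCK) / sqrt(w_ROI var_ROI + w_BCK var_BCK) with
    weights the node-count fractions; invariant under positive scaling of
    the reconstruction.
    """
    x_rec = np.asarray(x_rec, dtype=float)
    roi_idx = np.fromiter((int(k) for k in sorted(roi)), dtype=np.intp)
    if len(roi_idx) == 0 or len(roi_idx) == len(x_rec):
        raise ValueError("ROI and background must both be nonempty")
    mask = np.zeros(len(x_rec), dtype=bool)
    mask[roi_idx] = True
    a, b = x_rec[mask], x_rec[~mask]
    w_roi = mask.mean()
    w_bck = 1.0 - w_roi
    denom2 = w_roi * a.var() + w_bck * b.var()
    if denom2 <= 0.0:
        raise ValueError("CNR undefined: zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(denom2))


def evaluate(
    x_rec: np.ndarray,
    x_true: np.ndarray,
    targets: list[TargetSpec],
    mesh: TetMesh,
    graph: NeighborGraph,
    support_threshold: float = SUPPORT_THRESHOLD,
) -> EvaluationReport:
    """Full report: cluster the reconstruction, match clusters to targets.

    The reconstructed region is the set of nodes at or above
    ``support_threshold`` times the peak value; its edge-connected
    components are matched to true targets by greedy nearest-centroid
    pairing without replacement.  Unmatched targets get LE None (reported
    as a dash), mirroring solvers that collapse two targets onto one.
    """
    x_rec = np.asarray(x_rec, dtype=float)
    x_true = np.asarray(x_true, dtype=float)
    err = nrmse(x_rec, x_true)
    roi = np.flatnonzero(x_true > 0)
    try:
        contrast = cnr(x_rec, roi) if len(roi) else None
    except ValueError:
        contrast = None

    peak = x_rec.max(initial=0.0)
    if peak <= 0.0:
        return EvaluationReport(le=[None] * len(targets), nrmse=err, cnr=contrast,
                                n_components=0, resolved=False,
                                matched_centroids=[None] * len(targets))
    support = set(np.flatnonzero(x_rec >= support_threshold * peak).tolist())
    comps = connected_components(graph, support)
    comps = [c for c in comps if x_rec[sorted(c)].sum() > 0]
    centroids = [weighted_centroid(x_rec, c, mesh) for c in comps]

    # greedy global-nearest matching without replacement
    pairs: list[tuple[float, int, int]] = []
    for ci, c in enumerate(centroids):
        for ti, t in enumerate(targets):
            pairs.append((location_error(c, t.center), ci, ti))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_c: set[int] = set()
    le: list[float | None] = [None] * len(targets)
    matched: list[np.ndarray | None] = [None] * len(targets)
    for d, ci, ti in pairs:
        if ci in used_c or le[ti] is not None:
            continue
        used_c.add(ci)
        le[ti] = d
        matched[ti] = centroids[ci]
    n_matched = sum(1 for e in le if e is not None)
    return EvaluationReport(
        le=le, nrmse=err, cnr=contrast, n_components=len(comps),
        resolved=len(comps) >= len(targets) and n_matched >= len(targets),
        matched_centroids=matched,
    )
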