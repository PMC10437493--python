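"""Surface triangulation of canopy point clouds and abnormal-facet pruning.

The base triangulation is a per-region 2.5-D Delaunay: points are grouped
into surface patches (by provenance labels when available, else by spatial
connectivity), projected onto the patch's principal plane, triangulated in
2-D and lifted back to 3-D.  Raw canopy triangulations contain long sliver
facets bridging separate surfaces; these are removed by the interquartile
range (IQR) rule on a per-facet statistic (longest edge by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .filters import FilterParams, statistical_outlier_filter, voxel_downsample
from .geometry import ORGAN_UNKNOWN, PointCloud, TriangleMesh


class TriangulationError(ValueError):
    """Raised when the input cannot be triangulated (degenerate geometry)."""


def _connectivity_groups(xyz: np.ndarray, radius: float) -> np.ndarray:
    """Label points by connected component of the radius graph."""
    n = len(xyz)
    tree = cKDTree(xyz)
    labels = np.full(n, -1, dtype=np.int64)
    current = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        stack = [start]
        labels[start] = current
        while stack:
            i = stack.pop()
            for j in tree.query_ball_point(xyz[i], radius):
                if labels[j] == -1:
                    labels[j] = current
                    stack.append(j)
        current += 1
    return labels


def _triangulate_patch(pts: np.ndarray, idx: np.ndarray,
                       max_edge: float | None) -> list[tuple[int, int, int]]:
    """Delaunay-triangulate one patch on its principal plane; lift to 3-D."""
    ctr = pts.mean(axis=0)
    q = pts - ctr
    # principal plane via SVD; normal = smallest singular vector
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    uv = q @ vt[:2].T
    try:
        tri = Delaunay(uv)
    except QhullError:
        return []
    faces = []
    normal = vt[2] if vt.shape[0] > 2 else np.array([0.0, 0.0, 1.0])
    for s in tri.simplices:
        p = pts[s]
        if max_edge is not None:
            e = (np.linalg.norm(p[0] - p[1]), np.linalg.norm(p[1] - p[2]),
                 np.linalg.norm(p[2] - p[0]))
            if max(e) > max_edge:
                continue
        # orient consistently with the patch normal
        fn = np.cross(p[1] - p[0], p[2] - p[0])
        if fn @ normal < 0:
            faces.append((idx[s[0]], idx[s[2]], idx[s[1]]))
        else:
            faces.append((idx[s[0]], idx[s[1]], idx[s[2]]))
    return faces


def triangulate_canopy(cloud: PointCloud, max_edge: float | None = None) -> TriangleMesh:
    """Triangulate a canopy cloud into an open surface mesh.

    Points are partitioned into patches: labelled points by
    (plant_id, organ, leaf_id), unlabelled points by spatial connectivity.
    Facets inherit the patch labels.  Edges longer than ``max_edge`` (metres)
    are not created.
    """
    n = len(cloud)
    if n < 3:
        raise TriangulationError(f"need at least 3 points, got {n}")

    keys = np.column_stack([cloud.plant_id, cloud.organ, cloud.leaf_id])
    labelled = cloud.organ != ORGAN_UNKNOWN
    groups: list[np.ndarray] = []
    if labelled.any():
        lab_idx = np.nonzero(labelled)[0]
        _, inv = np.unique(keys[lab_idx], axis=0, return_inverse=True)
        for g in range(inv.max() + 1):
            groups.append(lab_idx[inv == g])
    if (~labelled).any():
        un_idx = np.nonzero(~labelled)[0]
        pts = cloud.xyz[un_idx]
        if len(pts) >= 2:
            tree = cKDTree(pts)
            d, _ = tree.query(pts[:: max(1, len(pts) // 500)], k=2)
            radius = 3.0 * float(np.median(d[:, 1]))
        else:
            radius = np.inf
        comp = _connectivity_groups(pts, radius)
        for g in range(comp.max() + 1):
            groups.append(un_idx[comp == g])

    faces: list[tuple[int, int, int]] = []
    for idx in groups:
        if len(idx) < 3:
            continue
        faces.extend(_triangulate_patch(cloud.xyz[idx], idx, max_edge))
    if not faces:
        raise TriangulationError("triangulation produced no facets "
                                 "(degenerate or overly sparse input)")
    F = np.asarray(faces, dtype=np.int64)
    # drop exactly-degenerate facets (collinear points)
    tri = cloud.xyz[F]
    area2 = np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    F = F[area2 > 0]
    if len(F) == 0:
        raise TriangulationError("all candidate facets are degenerate (collinear input)")
    # keep the full point set as vertices; pruning compacts later
    return TriangleMesh(cloud.xyz, F,
                        plant_id=cloud.plant_id[F[:, 0]],
                        organ=cloud.organ[F[:, 0]],
                        leaf_id=cloud.leaf_id[F[:, 0]])


_STATISTICS = ("longest_edge", "area", "aspect")


@dataclass
class PruneResult:
    """Pruned mesh plus bookkeeping of what was removed."""

    mesh: TriangleMesh
    removed_fraction: float
    threshold: float
    statistic: str


def prune_abnormal_facets(mesh: TriangleMesh, iqr_multiplier: float = 1.5,
                          statistic: str = "longest_edge") -> PruneResult:
    """Remove facets whose statistic exceeds Q3 + iqr_multiplier * IQR.

    The default statistic is the longest edge length (abnormal facets from
    canopy triangulation are long slivers); ``area`` and ``aspect`` (longest
    edge / shortest edge) are selectable.  A zero IQR (congruent facets)
    removes nothing.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {_STATISTICS}")
    if mesh.n_faces == 0:
        raise ValueError("mesh has no facets")
    tri = mesh.triangles()
    e = np.stack([
        np.linalg.norm(tri[:, 0] - tri[:, 1], axis=1),
        np.linalg.norm(tri[:, 1] - tri[:, 2], axis=1),
        np.linalg.norm(tri[:, 2] - tri[:, 0], axis=1),
    ], axis=1)
    if statistic == "longest_edge":
        stat = e.max(axis=1)
    elif statistic == "area":
        stat = mesh.face_areas()
    else:
        stat = e.max(axis=1) / np.maximum(e.min(axis=1), 1e-300)
    q1, q3 = np.percentile(stat, [25, 75])
    iqr = q3 - q1
    threshold = q3 + iqr_multiplier * iqr
    # small relative slack: a zero-IQR population of congruent facets keeps
    # every facet (statistic == Q3), while genuinely larger ones are removed
    keep = stat <= threshold * (1 + 1e-12)
    pruned = mesh.select_faces(keep)
    removed = 1.0 - keep.mean()
    return PruneResult(mesh=pruned, removed_fraction=float(removed),
                       threshold=float(threshold), statistic=statistic)


def reconstruct_canopy_mesh(cloud: PointCloud,
                            params: FilterParams | None = None,
                            max_edge: float = 0.06,
                            iqr_multiplier: float = 1.5) -> TriangleMesh:
    """Full cloud-to-surface pipeline: statistical filter, voxel downsample,
    per-region Delaunay triangulation, IQR facet pruning."""
    params = params or FilterParams()
    if len(cloud) > params.stat_k:
        cloud = statistical_outlier_filter(cloud, params.stat_k, params.stat_std_ratio)
    cloud = voxel_downsample(cloud, params.voxel_size)
    mesh = triangulate_canopy(cloud, max_edge=max_edge)
    return prune_abnormal_facets(mesh, iqr_multiplier).mesh
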