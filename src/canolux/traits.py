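"""Multidimensional canopy phenotypic traits.

Four traits summarise canopy structure in one, two and three dimensions:

* PH  — plant height: 99th-percentile z minus minimum z (m);
* CC  — canopy cover: occupied projected grid cells over the area of the
  2-D alpha shape of the projected canopy (dimensionless, <= 1);
* PAI — plant area index: Heron-formula surface area over ground area;
* COV — canopy occupation volume: total volume of the 1 cm^3 voxels that
  intersect at least one mesh triangle (m^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import Delaunay, QhullError, cKDTree

from .geometry import (
    ORGAN_GROUND,
    ORGAN_UNKNOWN,
    PointCloud,
    TriangleMesh,
    triangle_areas_heron,
)
from .scene import CanopyScene


@dataclass(frozen=True)
class TraitSet:
    """One canopy's trait battery plus provenance."""

    ph: float
    cc: float
    pai: float
    cov: float
    scene_id: str = ""
    stage: str = ""
    canopy_type: str = ""

    def __post_init__(self):
        if min(self.ph, self.cc, self.pai, self.cov) < 0 or self.cc > 1 + 1e-9:
            raise ValueError("traits out of range (all >= 0, CC <= 1)")


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, PointCloud):
        return obj.xyz
    if isinstance(obj, TriangleMesh):
        return obj.vertices
    if isinstance(obj, CanopyScene):
        return obj.merged_mesh().vertices
    return np.asarray(obj, dtype=np.float64).reshape(-1, 3)


def plant_height(obj, percentile: float = 99.0,
                 method: str = "linear") -> float:
    """PH = z(percentile) - z(min), linear-interpolation percentile."""
    z = _as_points(obj)[:, 2]
    if len(z) == 0:
        raise ValueError("no points for plant height")
    return float(np.percentile(z, percentile, method=method) - z.min())


def alpha_shape_area(xy: np.ndarray, alpha: float) -> float:
    """Area of the 2-D alpha shape: union of Delaunay triangles whose
    circumradius is at most ``alpha`` (metres)."""
    xy = np.asarray(xy, dtype=np.float64)
    if len(xy) < 3:
        raise ValueError("need at least 3 points for an alpha shape")
    try:
        tri = Delaunay(xy)
    except QhullError as err:
        raise ValueError(f"degenerate projected points: {err}") from None
    p = xy[tri.simplices]
    a = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    b = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    s = 0.5 * (a + b + c)
    area = np.sqrt(np.maximum(s * (s - a) * (s - b) * (s - c), 0.0))
    circum = np.where(area > 0, a * b * c / (4.0 * np.maximum(area, 1e-300)), np.inf)
    # Delaunay simplices are interior-disjoint, so the alpha-shape area is
    # the plain sum of the kept simplex areas
    return float(area[circum <= alpha].sum())


def default_alpha(xy: np.ndarray) -> float:
    """2x the 95th-percentile nearest-neighbour distance of the projection."""
    tree = cKDTree(xy)
    d, _ = tree.query(xy, k=2)
    return 2.0 * float(np.percentile(d[:, 1], 95))


def canopy_cover(cloud: PointCloud, grid_cell: float = 0.02,
                 alpha: float | None = None) -> float:
    """CC = occupied projected grid-cell area / alpha-shape projected area.

    Uses vegetation points only (organ label not ground/outlier) when labels
    are present.
    """
    veg = cloud
    if np.any(cloud.organ != ORGAN_UNKNOWN):
        veg = cloud.select((cloud.organ != ORGAN_GROUND)
                           & (cloud.organ != ORGAN_UNKNOWN))
    if len(veg) < 3:
        raise ValueError("need at least 3 vegetation points for canopy cover")
    xy = veg.xyz[:, :2]
    cells = np.unique(np.floor(xy / grid_cell).astype(np.int64), axis=0)
    occupation = len(cells) * grid_cell**2
    if alpha is None:
        alpha = default_alpha(xy)
    area = alpha_shape_area(xy, alpha)
    if area <= 0:
        raise ValueError("alpha-shape area is zero; increase alpha")
    return float(min(occupation / area, 1.0))


def plant_area_index(mesh: TriangleMesh, ground_area: float) -> float:
    """PAI = Heron surface area of leaf facets / ground area.

    When organ labels are absent, all non-ground facets count — the usual
    plant-area-index convention for meshes without organ separation.
    """
    if ground_area <= 0:
        raise ValueError("ground area must be positive")
    if np.any(mesh.organ != ORGAN_UNKNOWN):
        faces = mesh.faces[(mesh.organ != ORGAN_GROUND)
                           & (mesh.organ != ORGAN_UNKNOWN)]
    else:
        faces = mesh.faces
    if len(faces) == 0:
        return 0.0
    return float(triangle_areas_heron(mesh.vertices, faces).sum()) / ground_area


# ---------------------------------------------------------------------------
# canopy occupation volume
# ---------------------------------------------------------------------------

_SAT_EPS = 1e-10  # conservative: touching within this margin counts as overlap


@njit(cache=True)
def _axis_test(a, b, fa, fb, v0a, v0b, v1a, v1b, half_a, half_b):
    p0 = a * v0a + b * v0b
    p1 = a * v1a + b * v1b
    if p0 < p1:
        mn, mx = p0, p1
    else:
        mn, mx = p1, p0
    rad = fa * half_a + fb * half_b + _SAT_EPS
    return mn > rad or mx < -rad


@njit(cache=True)
def _tri_box_overlap(cx, cy, cz, hx, hy, hz,
                     t0x, t0y, t0z, t1x, t1y, t1z, t2x, t2y, t2z):
    """Akenine-Moller separating-axis triangle/axis-aligned-box test."""
    v0x, v0y, v0z = t0x - cx, t0y - cy, t0z - cz
    v1x, v1y, v1z = t1x - cx, t1y - cy, t1z - cz
    v2x, v2y, v2z = t2x - cx, t2y - cy, t2z - cz

    # box axes
    mn = min(v0x, min(v1x, v2x))
    mx = max(v0x, max(v1x, v2x))
    if mn > hx + _SAT_EPS or mx < -hx - _SAT_EPS:
        return False
    mn = min(v0y, min(v1y, v2y))
    mx = max(v0y, max(v1y, v2y))
    if mn > hy + _SAT_EPS or mx < -hy - _SAT_EPS:
        return False
    mn = min(v0z, min(v1z, v2z))
    mx = max(v0z, max(v1z, v2z))
    if mn > hz + _SAT_EPS or mx < -hz - _SAT_EPS:
        return False

    e0x, e0y, e0z = v1x - v0x, v1y - v0y, v1z - v0z
    e1x, e1y, e1z = v2x - v1x, v2y - v1y, v2z - v1z
    e2x, e2y, e2z = v0x - v2x, v0y - v2y, v0z - v2z

    # 9 cross-product axes
    for (ex, ey, ez, pax, pay, paz, pbx, pby, pbz) in (
        (e0x, e0y, e0z, v0x, v0y, v0z, v2x, v2y, v2z),
        (e1x, e1y, e1z, v0x, v0y, v0z, v2x, v2y, v2z),
        (e2x, e2y, e2z, v0x, v0y, v0z, v1x, v1y, v1z),
    ):
        fex, fey, fez = abs(ex), abs(ey), abs(ez)
        # axis = e x X
        if _axis_test(ez, -ey, fez, fey, pay, paz, pby, pbz, hy, hz):
            return False
        # axis = e x Y
        if _axis_test(-ez, ex, fez, fex, pax, paz, pbx, pbz, hx, hz):
            return False
        # axis = e x Z
        if _axis_test(ey, -ex, fey, fex, pax, pay, pbx, pby, hx, hy):
            return False

    # triangle plane vs box
    nx = e0y * e1z - e0z * e1y
    ny = e0z * e1x - e0x * e1z
    nz = e0x * e1y - e0y * e1x
    r = hx * abs(nx) + hy * abs(ny) + hz * abs(nz)
    d = nx * v0x + ny * v0y + nz * v0z
    return abs(d) <= r + _SAT_EPS


@njit(cache=True)
def _voxelize(tri, origin, voxel, i0, j0, k0, occ):
    eps = 1e-9
    for t in range(tri.shape[0]):
        lox = min(tri[t, 0, 0], min(tri[t, 1, 0], tri[t, 2, 0]))
        hix = max(tri[t, 0, 0], max(tri[t, 1, 0], tri[t, 2, 0]))
        loy = min(tri[t, 0, 1], min(tri[t, 1, 1], tri[t, 2, 1]))
        hiy = max(tri[t, 0, 1], max(tri[t, 1, 1], tri[t, 2, 1]))
        loz = min(tri[t, 0, 2], min(tri[t, 1, 2], tri[t, 2, 2]))
        hiz = max(tri[t, 0, 2], max(tri[t, 1, 2], tri[t, 2, 2]))
        # expand by eps so triangles exactly on a boundary plane are tested
        # against both adjacent voxels (the SAT test treats touching as hit)
        ia = int(np.floor((lox - origin[0]) / voxel - eps)) - i0
        ib = int(np.floor((hix - origin[0]) / voxel + eps)) - i0
        ja = int(np.floor((loy - origin[1]) / voxel - eps)) - j0
        jb = int(np.floor((hiy - origin[1]) / voxel + eps)) - j0
        ka = int(np.floor((loz - origin[2]) / voxel - eps)) - k0
        kb = int(np.floor((hiz - origin[2]) / voxel + eps)) - k0
        ia = max(ia, 0)
        ja = max(ja, 0)
        ka = max(ka, 0)
        ib = min(ib, occ.shape[0] - 1)
        jb = min(jb, occ.shape[1] - 1)
        kb = min(kb, occ.shape[2] - 1)
        h = voxel / 2.0
        for i in range(ia, ib + 1):
            cx = origin[0] + (i0 + i + 0.5) * voxel
            for j in range(ja, jb + 1):
                cy = origin[1] + (j0 + j + 0.5) * voxel
                for k in range(ka, kb + 1):
                    if occ[i, j, k]:
                        continue
                    cz = origin[2] + (k0 + k + 0.5) * voxel
                    if _tri_box_overlap(cx, cy, cz, h, h, h,
                                        tri[t, 0, 0], tri[t, 0, 1], tri[t, 0, 2],
                                        tri[t, 1, 0], tri[t, 1, 1], tri[t, 1, 2],
                                        tri[t, 2, 0], tri[t, 2, 1], tri[t, 2, 2]):
                        occ[i, j, k] = True


def canopy_occupation_volume(mesh: TriangleMesh, voxel: float = 0.01,
                             origin=(0.0, 0.0, 0.0),
                             method: str = "triangles") -> float:
    """COV: total volume of voxels intersected by canopy triangles (m^3).

    The voxel grid is anchored at the plot origin (not the mesh bounding
    box), so replicas translated by whole-voxel offsets voxelate
    identically.  ``method='vertices'`` counts only voxels containing mesh
    vertices (a cheaper, non-conservative variant).
    """
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    if mesh.n_faces == 0:
        raise ValueError("mesh has no facets")
    origin = np.asarray(origin, dtype=np.float64)
    if np.any(mesh.organ != ORGAN_UNKNOWN):
        mesh = mesh.select_faces((mesh.organ != ORGAN_GROUND)
                                 & (mesh.organ != ORGAN_UNKNOWN))
        if mesh.n_faces == 0:
            return 0.0

    if method == "vertices":
        keys = np.floor((mesh.vertices - origin) / voxel).astype(np.int64)
        return len(np.unique(keys, axis=0)) * voxel**3
    if method != "triangles":
        raise ValueError("method must be 'triangles' or 'vertices'")

    tri = np.ascontiguousarray(mesh.triangles())
    lo = tri.reshape(-1, 3).min(axis=0)
    hi = tri.reshape(-1, 3).max(axis=0)
    i0 = int(np.floor((lo[0] - origin[0]) / voxel)) - 1
    j0 = int(np.floor((lo[1] - origin[1]) / voxel)) - 1
    k0 = int(np.floor((lo[2] - origin[2]) / voxel)) - 1
    ni = int(np.floor((hi[0] - origin[0]) / voxel)) + 2 - i0
    nj = int(np.floor((hi[1] - origin[1]) / voxel)) + 2 - j0
    nk = int(np.floor((hi[2] - origin[2]) / voxel)) + 2 - k0
    occ = np.zeros((ni, nj, nk), dtype=np.bool_)
    _voxelize(tri, origin, voxel, i0, j0, k0, occ)
    return float(occ.sum()) * voxel**3


def extract_traits(scene: CanopyScene, grid_cell: float = 0.02,
                   alpha: float | None = None, voxel: float = 0.01,
                   scene_id: str = "") -> TraitSet:
    """Trait battery of a canopy scene, computed from its merged mesh."""
    mesh = scene.merged_mesh()
    ph = plant_height(mesh)
    vert_organ = np.full(mesh.n_vertices, ORGAN_UNKNOWN, dtype=np.int32)
    vert_organ[mesh.faces.ravel()] = np.repeat(mesh.organ, 3)
    cloud = PointCloud(mesh.vertices, organ=vert_organ)
    cc = canopy_cover(cloud, grid_cell=grid_cell, alpha=alpha)
    pai = plant_area_index(mesh, scene.ground_area)
    cov = canopy_occupation_volume(mesh, voxel=voxel)
    return TraitSet(ph=ph, cc=cc, pai=pai, cov=cov, scene_id=scene_id,
                    stage=scene.stage, canopy_type=scene.provenance)
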