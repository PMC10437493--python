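"""Core geometric containers shared by every pipeline stage.

Coordinate convention: right-handed plot-local frame, metres, z up, ground at
z = 0.  The x axis runs along the rows (the within-row plant direction, which
in the simulated fields points north-south), the y axis across the rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

# Organ codes used in per-point / per-facet labels.
ORGAN_STEM = 0
ORGAN_LEAF = 1
ORGAN_GROUND = 2
ORGAN_UNKNOWN = -1  # also used to mark injected outlier points


def _as_xyz(a) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected an (N, 3) coordinate array, got shape {a.shape}")
    if a.size and not np.isfinite(a).all():
        raise ValueError("coordinates must be finite")
    return a


def _label_array(values, n: int, name: str) -> np.ndarray:
    if values is None:
        return np.full(n, ORGAN_UNKNOWN, dtype=np.int32)
    out = np.asarray(values, dtype=np.int32)
    if out.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {out.shape}")
    return out.copy()


@dataclass
class PointCloud:
    """Labelled 3-D point set in the plot-local frame.

    ``plant_id``, ``organ`` and ``leaf_id`` carry ground-truth provenance for
    synthetic clouds (-1 where unknown; organ -1 additionally marks injected
    outlier points).
    """

    xyz: np.ndarray
    plant_id: np.ndarray | None = None
    organ: np.ndarray | None = None
    leaf_id: np.ndarray | None = None

    def __post_init__(self):
        self.xyz = _as_xyz(self.xyz)
        n = len(self.xyz)
        self.plant_id = _label_array(self.plant_id, n, "plant_id")
        self.organ = _label_array(self.organ, n, "organ")
        self.leaf_id = _label_array(self.leaf_id, n, "leaf_id")

    def __len__(self) -> int:
        return len(self.xyz)

    def select(self, mask) -> "PointCloud":
        mask = np.asarray(mask)
        return PointCloud(
            self.xyz[mask],
            self.plant_id[mask],
            self.organ[mask],
            self.leaf_id[mask],
        )

    def translated(self, offset) -> "PointCloud":
        off = np.asarray(offset, dtype=np.float64).reshape(3)
        return PointCloud(self.xyz + off, self.plant_id, self.organ, self.leaf_id)

    @staticmethod
    def concatenate(clouds: Sequence["PointCloud"]) -> "PointCloud":
        if not clouds:
            return PointCloud(np.zeros((0, 3)))
        return PointCloud(
            np.vstack([c.xyz for c in clouds]),
            np.concatenate([c.plant_id for c in clouds]),
            np.concatenate([c.organ for c in clouds]),
            np.concatenate([c.leaf_id for c in clouds]),
        )


@dataclass
class TriangleMesh:
    """Indexed triangle surface with per-facet organ/plant labels.

    Open (non-watertight) surfaces are the norm: leaves are one-layer laminae
    treated as two-sided by the radiation model.
    """

    vertices: np.ndarray
    faces: np.ndarray
    plant_id: np.ndarray | None = None
    organ: np.ndarray | None = None
    leaf_id: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = _as_xyz(self.vertices)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size == 0:
            self.faces = self.faces.reshape(0, 3)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError(f"faces must be (F, 3), got {self.faces.shape}")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of vertex range")
        f = len(self.faces)
        self.plant_id = _label_array(self.plant_id, f, "plant_id")
        self.organ = _label_array(self.organ, f, "organ")
        self.leaf_id = _label_array(self.leaf_id, f, "leaf_id")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangles(self) -> np.ndarray:
        """(F, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        if normalize:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def face_areas(self) -> np.ndarray:
        """Areas via the cross product ||AB x AC|| / 2."""
        t = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.face_areas().sum())

    def translated(self, offset) -> "TriangleMesh":
        off = np.asarray(offset, dtype=np.float64).reshape(3)
        return TriangleMesh(
            self.vertices + off, self.faces, self.plant_id, self.organ, self.leaf_id
        )

    def select_faces(self, mask) -> "TriangleMesh":
        """Sub-mesh of the selected facets with unused vertices dropped."""
        mask = np.asarray(mask)
        faces = self.faces[mask]
        used = np.unique(faces)
        remap = np.full(len(self.vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(
            self.vertices[used],
            remap[faces],
            self.plant_id[mask],
            self.organ[mask],
            self.leaf_id[mask],
        )

    def with_labels(self, plant_id=None, organ=None, leaf_id=None) -> "TriangleMesh":
        f = self.n_faces
        out = replace(self)
        if plant_id is not None:
            out.plant_id = np.full(f, plant_id, dtype=np.int32) if np.isscalar(plant_id) else _label_array(plant_id, f, "plant_id")
        if organ is not None:
            out.organ = np.full(f, organ, dtype=np.int32) if np.isscalar(organ) else _label_array(organ, f, "organ")
        if leaf_id is not None:
            out.leaf_id = np.full(f, leaf_id, dtype=np.int32) if np.isscalar(leaf_id) else _label_array(leaf_id, f, "leaf_id")
        return out

    @staticmethod
    def concatenate(meshes: Sequence["TriangleMesh"]) -> "TriangleMesh":
        meshes = [m for m in meshes if m.n_vertices]
        if not meshes:
            return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
        offsets = np.cumsum([0] + [m.n_vertices for m in meshes[:-1]])
        return TriangleMesh(
            np.vstack([m.vertices for m in meshes]),
            np.vstack([m.faces + o for m, o in zip(meshes, offsets)]),
            np.concatenate([m.plant_id for m in meshes]),
            np.concatenate([m.organ for m in meshes]),
            np.concatenate([m.leaf_id for m in meshes]),
        )


def triangle_areas_heron(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-facet areas from edge lengths via Heron's formula.

    Uses Kahan's numerically stable rearrangement (sides sorted a >= b >= c):
    A = sqrt((a+(b+c)) (c-(a-b)) (c+(a-b)) (a+(b-c))) / 4, which keeps needle
    triangles accurate to machine precision.
    """
    tri = np.asarray(vertices, dtype=np.float64)[np.asarray(faces, dtype=np.int64)]
    e = np.stack(
        [
            np.linalg.norm(tri[:, 1] - tri[:, 2], axis=1),
            np.linalg.norm(tri[:, 2] - tri[:, 0], axis=1),
            np.linalg.norm(tri[:, 0] - tri[:, 1], axis=1),
        ],
        axis=1,
    )
    e.sort(axis=1)
    c, b, a = e[:, 0], e[:, 1], e[:, 2]
    prod = (a + (b + c)) * (c - (a - b)) * (c + (a - b)) * (a + (b - c))
    return 0.25 * np.sqrt(np.maximum(prod, 0.0))


def mesh_area(mesh: TriangleMesh, organ: int | Iterable[int] | None = None) -> float:
    """Total surface area by Heron's formula, optionally filtered by organ label."""
    if organ is None:
        faces = mesh.faces
    else:
        organs = np.atleast_1d(np.asarray(organ, dtype=np.int32))
        faces = mesh.faces[np.isin(mesh.organ, organs)]
    if len(faces) == 0:
        return 0.0
    return float(triangle_areas_heron(mesh.vertices, faces).sum())
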