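"""Parametric maize plants, canopies, and SfM-like noisy point clouds.

The generator stands in for field-reconstructed canopies: it builds maize-like
plants (drooping laminae on a stem) on the plot grid with controllable
plant-to-plant variability, and samples noisy point clouds from the meshes
the way structure-from-motion surveys would observe them (surface noise,
sparse outliers, occlusion dropout in the canopy interior).

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    ORGAN_GROUND,
    ORGAN_LEAF,
    ORGAN_STEM,
    ORGAN_UNKNOWN,
    PointCloud,
    TriangleMesh,
)
from .scene import CanopyLayout, CanopyScene


@dataclass(frozen=True)
class LeafParams:
    """One lamina: midrib arc length, width profile, and orientation.

    ``insertion_angle`` is measured in degrees from the vertical stem axis
    (0 = pointing straight up, 90 = horizontal); ``curvature`` is a
    dimensionless droop coefficient adding up to ``curvature * 90`` degrees of
    extra downward bend from base to tip.
    """

    length: float = 0.6
    max_width: float = 0.08
    insertion_height: float = 0.5
    insertion_angle: float = 45.0
    azimuth: float = 0.0
    curvature: float = 0.6
    segments_along: int = 10
    segments_across: int = 2
    width_profile: str = "sine"  # "sine" or "rect"
    profile_power: float = 0.7

    def __post_init__(self):
        if self.length <= 0 or self.max_width <= 0:
            raise ValueError("leaf length and max_width must be positive")
        if not 0.0 <= self.insertion_angle <= 180.0:
            raise ValueError("insertion_angle must be in [0, 180] degrees")
        if self.segments_along < 2 or self.segments_across < 2:
            raise ValueError("segments must be >= 2")
        if self.width_profile not in ("sine", "rect"):
            raise ValueError("width_profile must be 'sine' or 'rect'")


@dataclass(frozen=True)
class PlantParams:
    """A maize plant: stem plus an ordered list of leaves."""

    n_leaves: int
    height: float
    leaf_params: tuple[LeafParams, ...]
    stem_radius: float = 0.012
    phyllotaxy_noise_sd: float = 10.0

    def __post_init__(self):
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if len(self.leaf_params) != self.n_leaves:
            raise ValueError("leaf_params must have n_leaves entries")


@dataclass(frozen=True)
class NoiseModel:
    """SfM-like measurement imperfections applied to sampled clouds."""

    surface_sd: float = 0.005
    outlier_fraction: float = 0.02
    outlier_box_scale: float = 1.3
    occlusion_dropout: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.surface_sd < 0:
            raise ValueError("surface_sd must be >= 0")
        for name in ("outlier_fraction", "occlusion_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class PlantVariability:
    """Plant-to-plant and plot-to-plot structural variability.

    Multiplicative lognormal factors (sigma of log) on plant height, leaf
    length and leaf width; an integer jitter on leaf count; positional jitter
    (m) on the grid; and a plot-level lognormal scale applied to all leaf
    dimensions of a plot (emulating fertility/treatment differences between
    plots, the main between-plot variance source).
    """

    height_sd: float = 0.06
    length_sd: float = 0.12
    width_sd: float = 0.10
    angle_sd: float = 6.0  # degrees, additive on insertion angles
    n_leaves_jitter: int = 1
    position_jitter: float = 0.02
    plot_scale_sd: float = 0.10
    # border effect: plants at the plot edge face less competition and grow
    # larger (and unusually tall); fractional leaf-area boost of the
    # outermost ring.  Grows with canopy closure, so centre plants become
    # less representative of the stand late in the season.
    edge_effect: float = 0.1


@dataclass(frozen=True)
class StagePreset:
    """Growth-stage preset: sparse early canopy vs. dense late canopy.

    Late-stage plants are both larger and more variable: by 70 days after
    sowing, competition has amplified plant-to-plant size and architecture
    differences, which is what makes replicated canopies least faithful then.
    """

    n_leaves: int
    height: float
    leaf_length: float
    leaf_width: float
    variability: PlantVariability


STAGES: dict[str, StagePreset] = {
    "early": StagePreset(
        n_leaves=8, height=1.25, leaf_length=0.56, leaf_width=0.076,
        variability=PlantVariability(
            height_sd=0.05, length_sd=0.08, width_sd=0.07, angle_sd=5.0,
            n_leaves_jitter=1, position_jitter=0.015, plot_scale_sd=0.10,
            edge_effect=0.05),
    ),
    "late": StagePreset(
        n_leaves=13, height=2.25, leaf_length=0.72, leaf_width=0.092,
        variability=PlantVariability(
            height_sd=0.12, length_sd=0.20, width_sd=0.16, angle_sd=9.0,
            n_leaves_jitter=2, position_jitter=0.02, plot_scale_sd=0.10,
            edge_effect=0.30),
    ),
}


# ---------------------------------------------------------------------------
# Leaf and plant construction
# ---------------------------------------------------------------------------

def _leaf_width(params: LeafParams, s_frac: np.ndarray) -> np.ndarray:
    if params.width_profile == "rect":
        return np.full_like(s_frac, params.max_width)
    return params.max_width * np.sin(np.pi * s_frac) ** params.profile_power


def generate_leaf(params: LeafParams, seed: int = 0) -> TriangleMesh:
    """Build a single lamina mesh.

    The midrib is a planar curve whose tangent angle from vertical grows
    linearly with arc length from ``insertion_angle`` to
    ``insertion_angle + curvature * 90`` degrees; discretised at equal
    arc-length steps, so the polyline midrib length equals ``length`` exactly.
    The lamina is flat across the midrib with the configured width profile.
    """
    n = params.segments_along
    m = params.segments_across
    az = math.radians(params.azimuth)
    u = np.array([math.cos(az), math.sin(az), 0.0])   # horizontal midrib dir
    v = np.array([-math.sin(az), math.cos(az), 0.0])  # cross-midrib dir
    step = params.length / n
    theta0 = math.radians(params.insertion_angle)
    dtheta = params.curvature * math.pi / 2

    # midrib nodes at arc lengths k * step, via midpoint tangent angles
    pts = np.zeros((n + 1, 3))
    for k in range(n):
        smid = (k + 0.5) / n
        th = theta0 + dtheta * smid
        pts[k + 1] = pts[k] + step * (math.sin(th) * u + np.array([0, 0, math.cos(th)]))

    s_frac = np.arange(n + 1) / n
    widths = _leaf_width(params, s_frac)
    w_eps = 1e-9 * params.max_width

    rows: list[np.ndarray] = []
    for k in range(n + 1):
        if widths[k] <= w_eps:
            rows.append(pts[k][None, :])
        else:
            t = np.linspace(-0.5, 0.5, m + 1)
            rows.append(pts[k][None, :] + widths[k] * t[:, None] * v[None, :])

    verts: list[np.ndarray] = []
    row_start: list[int] = []
    for r in rows:
        row_start.append(sum(len(x) for x in verts))
        verts.append(r)
    V = np.vstack(verts)

    faces: list[tuple[int, int, int]] = []
    for k in range(n):
        a0, b0 = row_start[k], row_start[k + 1]
        na, nb = len(rows[k]), len(rows[k + 1])
        if na == 1 and nb == 1:
            continue
        if na == 1:
            for j in range(nb - 1):
                faces.append((a0, b0 + j, b0 + j + 1))
        elif nb == 1:
            for j in range(na - 1):
                faces.append((a0 + j, a0 + j + 1, b0))
        else:
            for j in range(m):
                faces.append((a0 + j, b0 + j, b0 + j + 1))
                faces.append((a0 + j, b0 + j + 1, a0 + j + 1))
    F = np.asarray(faces, dtype=np.int64)
    mesh = TriangleMesh(V, F)
    return mesh.with_labels(organ=ORGAN_LEAF)


def _stem_mesh(height: float, radius: float, sides: int = 6) -> TriangleMesh:
    ang = np.linspace(0, 2 * np.pi, sides, endpoint=False)
    ring = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(sides)])
    bottom = ring.copy()
    top = ring + np.array([0, 0, height])
    V = np.vstack([bottom, top])
    faces = []
    for i in range(sides):
        j = (i + 1) % sides
        faces.append((i, j, sides + j))
        faces.append((i, sides + j, sides + i))
    return TriangleMesh(V, np.asarray(faces, dtype=np.int64)).with_labels(organ=ORGAN_STEM)


def generate_plant(params: PlantParams, seed: int = 0) -> TriangleMesh:
    """Stem plus leaves; leaf azimuths perturbed by phyllotaxy noise."""
    rng = np.random.default_rng(seed)
    parts = [_stem_mesh(params.height, params.stem_radius)]
    for i, lp in enumerate(params.leaf_params):
        az = lp.azimuth + float(rng.normal(0.0, params.phyllotaxy_noise_sd))
        leaf = generate_leaf(replace(lp, azimuth=az))
        base = np.array([
            params.stem_radius * math.cos(math.radians(az)),
            params.stem_radius * math.sin(math.radians(az)),
            lp.insertion_height,
        ])
        parts.append(leaf.translated(base).with_labels(leaf_id=i))
    mesh = TriangleMesh.concatenate(parts)
    areas = mesh.face_areas()
    if areas.size and areas.min() <= 0:
        raise AssertionError("degenerate zero-area facet in generated plant")
    return mesh


def default_plant_params(stage: str, rng: np.random.Generator,
                         variability: PlantVariability | None = None,
                         plot_scale: float = 1.0,
                         edge_proximity: float = 0.0) -> PlantParams:
    """Draw one plant's parameters from the stage preset plus variability.

    ``edge_proximity`` in [0, 1] applies the border-effect size boost (1 for
    plants in the outermost ring of the plot).
    """
    preset = STAGES[stage]
    var = variability if variability is not None else preset.variability
    edge = 1.0 + var.edge_effect * edge_proximity
    h = (preset.height * plot_scale ** 0.5 * edge ** 0.6
         * float(np.exp(rng.normal(0, var.height_sd))))
    len_mult = plot_scale * edge ** 0.5 * float(np.exp(rng.normal(0, var.length_sd)))
    wid_mult = plot_scale * edge ** 0.5 * float(np.exp(rng.normal(0, var.width_sd)))
    n_leaves = int(preset.n_leaves + rng.integers(-var.n_leaves_jitter,
                                                  var.n_leaves_jitter + 1))
    n_leaves = max(3, n_leaves)
    base_az = float(rng.uniform(0, 360))
    leaves = []
    for i in range(n_leaves):
        frac = (i + 1) / (n_leaves + 1)
        # mid-stem leaves are the largest
        size = 0.55 + 0.45 * math.sin(math.pi * min(frac * 1.15, 1.0)) ** 0.8
        length = preset.leaf_length * size * len_mult
        width = preset.leaf_width * (0.7 + 0.3 * size) * wid_mult
        angle = float(np.clip(rng.normal(42.0 + 18.0 * frac, var.angle_sd), 10.0, 95.0))
        leaves.append(LeafParams(
            length=max(length, 0.05),
            max_width=max(width, 0.01),
            insertion_height=h * (0.12 + 0.8 * frac),
            insertion_angle=angle,
            azimuth=base_az + 180.0 * i,
            curvature=float(rng.uniform(0.35, 0.8)),
        ))
    return PlantParams(n_leaves=n_leaves, height=h, leaf_params=tuple(leaves))


def generate_canopy(layout: CanopyLayout | None = None,
                    variability: PlantVariability | None = None,
                    stage: str = "late",
                    seed: int = 0,
                    identical_plants: bool = False) -> CanopyScene:
    """Generate a heterogeneous (RCM-like) canopy on the plot grid.

    ``identical_plants=True`` clones one plant into every cell (no jitter),
    giving a perfectly homogeneous, spatially periodic stand.
    """
    layout = layout or CanopyLayout()
    if stage not in STAGES:
        raise ValueError(f"unknown stage '{stage}'; choose from {sorted(STAGES)}")
    var = variability if variability is not None else STAGES[stage].variability
    rng = np.random.default_rng(seed)
    plot_scale = float(np.exp(rng.normal(0, var.plot_scale_sd)))

    plants: list[TriangleMesh] = []
    grid: list[tuple[int, int]] = []
    proto = None
    if identical_plants:
        proto = generate_plant(default_plant_params(stage, rng, var, plot_scale),
                               seed=int(rng.integers(2**31 - 1)))
    pid = 0
    for row in range(layout.n_rows):
        for col in range(layout.n_cols):
            ring = min(row, col, layout.n_rows - 1 - row, layout.n_cols - 1 - col)
            prox = 1.0 if ring == 0 else (0.35 if ring == 1 else 0.0)
            if identical_plants:
                mesh = proto
                jitter = np.zeros(2)
            else:
                params = default_plant_params(stage, rng, var, plot_scale,
                                              edge_proximity=prox)
                mesh = generate_plant(params, seed=int(rng.integers(2**31 - 1)))
                jitter = rng.normal(0, var.position_jitter, size=2)
            pos = layout.position(row, col) + np.array([jitter[0], jitter[1], 0.0])
            plants.append(mesh.translated(pos).with_labels(plant_id=pid))
            grid.append((row, col))
            pid += 1
    return CanopyScene(plants=plants, grid=grid, layout=layout, stage=stage,
                       provenance="RCM")


# ---------------------------------------------------------------------------
# Point-cloud sampling
# ---------------------------------------------------------------------------

def sample_point_cloud(mesh: TriangleMesh, density: float,
                       noise: NoiseModel | None = None) -> PointCloud:
    """Sample an SfM-like point cloud from a mesh surface.

    Points are area-uniform on the surface (expected count density * area),
    perturbed by isotropic Gaussian noise; a fraction of extra outlier points
    is drawn uniformly in the inflated bounding box (labelled organ = -1);
    occlusion dropout removes points with probability increasing towards the
    canopy bottom.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if mesh.n_faces == 0:
        raise ValueError("cannot sample an empty mesh")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)

    areas = mesh.face_areas()
    total = areas.sum()
    n = int(rng.poisson(density * total))
    face_idx = rng.choice(mesh.n_faces, size=n, p=areas / total)
    tri = mesh.triangles()[face_idx]
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    a = 1.0 - r1
    b = r1 * (1.0 - r2)
    c = r1 * r2
    pts = a[:, None] * tri[:, 0] + b[:, None] * tri[:, 1] + c[:, None] * tri[:, 2]
    plant = mesh.plant_id[face_idx]
    organ = mesh.organ[face_idx]
    leaf = mesh.leaf_id[face_idx]

    if noise.occlusion_dropout > 0 and n > 0:
        z = pts[:, 2]
        ztop = max(z.max(), 1e-9)
        p_drop = noise.occlusion_dropout * (1.0 - np.clip(z / ztop, 0, 1))
        keep = rng.random(n) >= p_drop
        pts, plant, organ, leaf = pts[keep], plant[keep], organ[keep], leaf[keep]

    if noise.surface_sd > 0 and len(pts):
        pts = pts + rng.normal(0, noise.surface_sd, size=pts.shape)

    if noise.outlier_fraction > 0 and len(pts):
        n_out = int(round(noise.outlier_fraction * len(pts)))
        if n_out:
            lo = mesh.vertices.min(axis=0)
            hi = mesh.vertices.max(axis=0)
            ctr = (lo + hi) / 2
            half = (hi - lo) / 2 * noise.outlier_box_scale + noise.surface_sd
            out = ctr + rng.uniform(-1, 1, size=(n_out, 3)) * half
            pts = np.vstack([pts, out])
            plant = np.concatenate([plant, np.full(n_out, ORGAN_UNKNOWN, np.int32)])
            organ = np.concatenate([organ, np.full(n_out, ORGAN_UNKNOWN, np.int32)])
            leaf = np.concatenate([leaf, np.full(n_out, ORGAN_UNKNOWN, np.int32)])

    return PointCloud(pts, plant, organ, leaf)


def ground_mesh(bounds: tuple[float, float, float, float],
                resolution: float = 0.25) -> TriangleMesh:
    """Ground plane at z = 0 spanning the lateral domain, as a triangle grid."""
    x0, x1, y0, y1 = bounds
    nx = max(1, int(round((x1 - x0) / resolution)))
    ny = max(1, int(round((y1 - y0) / resolution)))
    xs = np.linspace(x0, x1, nx + 1)
    ys = np.linspace(y0, y1, ny + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    V = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    faces = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = (i + 1) * (ny + 1) + j
            faces.append((a, b, b + 1))
            faces.append((a, b + 1, a + 1))
    return TriangleMesh(V, np.asarray(faces, np.int64)).with_labels(organ=ORGAN_GROUND)


def sample_scene_cloud(scene: CanopyScene, density: float,
                       noise: NoiseModel | None = None,
                       include_ground: bool = True,
                       ground_resolution: float = 0.25) -> PointCloud:
    """Sample a whole canopy scene (optionally with ground) into one cloud."""
    parts = list(scene.plants)
    if include_ground:
        parts.append(ground_mesh(scene.bounds, ground_resolution))
    return sample_point_cloud(TriangleMesh.concatenate(parts), density, noise)
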