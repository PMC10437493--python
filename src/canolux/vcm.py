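"""Virtual canopy construction: replicate 1, 4 or 8 centre plants of a
realistic canopy onto the full plot grid (VCM-1 / VCM-4 / VCM-8).

Copies are pure translations on the planting grid; the internal jitter of the
replicated block is preserved, so a VCM is a periodic tiling of its unit
block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import TriangleMesh
from .scene import CanopyLayout, CanopyScene

# default replication blocks: n plants -> (rows, cols)
_BLOCK_SHAPES = {1: (1, 1), 4: (2, 2), 8: (2, 4)}


@dataclass(frozen=True)
class ReplicationPlan:
    """How a unit block tiles the full grid."""

    unit_shape: tuple[int, int]
    copies: int
    # grid anchors (row, col) of each copy and metric offsets (dx, dy)
    anchors: tuple[tuple[int, int], ...]
    offsets: tuple[tuple[float, float], ...]


def _block_start(grid: int, block: int) -> int:
    """Floor-centre start index of a centred block (8, 1 -> 4; 8, 2 -> 3)."""
    return (grid - block + 1) // 2


def select_center_plants(scene: CanopyScene, n: int,
                         unit_shape: tuple[int, int] | None = None
                         ) -> tuple[list[TriangleMesh], list[tuple[int, int]]]:
    """Pick the contiguous centre block of n plants (1x1, 2x2 or 2x4).

    Returns the plant meshes and their (row, col) grid cells, ordered
    row-major.  General n is allowed by passing ``unit_shape`` explicitly.
    """
    if unit_shape is None:
        if n not in _BLOCK_SHAPES:
            raise ValueError(
                f"n must be one of {sorted(_BLOCK_SHAPES)} (or pass unit_shape); got {n}")
        unit_shape = _BLOCK_SHAPES[n]
    br, bc = unit_shape
    if br * bc != n:
        raise ValueError(f"unit_shape {unit_shape} does not hold {n} plants")
    lay = scene.layout
    if br > lay.n_rows or bc > lay.n_cols:
        raise ValueError("block larger than the plot grid")
    r0 = _block_start(lay.n_rows, br)
    c0 = _block_start(lay.n_cols, bc)
    plants, cells = [], []
    for r in range(r0, r0 + br):
        for c in range(c0, c0 + bc):
            plants.append(scene.plant_at(r, c))
            cells.append((r, c))
    return plants, cells


def compute_replication_positions(layout: CanopyLayout,
                                  unit_shape: tuple[int, int]) -> ReplicationPlan:
    """Grid anchors and metric offsets tiling the layout with the unit block."""
    br, bc = unit_shape
    if br < 1 or bc < 1 or layout.n_rows % br or layout.n_cols % bc:
        raise ValueError(
            f"unit shape {unit_shape} does not tile a "
            f"{layout.n_rows}x{layout.n_cols} grid")
    anchors, offsets = [], []
    for i in range(layout.n_rows // br):
        for j in range(layout.n_cols // bc):
            anchors.append((i * br, j * bc))
            offsets.append((j * bc * layout.plant_spacing, i * br * layout.row_spacing))
    return ReplicationPlan(unit_shape=unit_shape, copies=len(anchors),
                           anchors=tuple(anchors), offsets=tuple(offsets))


def replicate_canopy(units: list[TriangleMesh], unit_cells: list[tuple[int, int]],
                     plan: ReplicationPlan, layout: CanopyLayout,
                     stage: str = "late", provenance: str = "VCM") -> CanopyScene:
    """Tile translated copies of the unit block into a full canopy scene.

    Copies are placed by block origin (translation only; no rotation or
    mirroring), so per-plant geometry and within-block jitter are preserved
    exactly.
    """
    br, bc = plan.unit_shape
    if len(units) != br * bc or len(unit_cells) != br * bc:
        raise ValueError("units do not match the plan's unit shape")
    r_src = min(r for r, _ in unit_cells)
    c_src = min(c for _, c in unit_cells)
    seen: set[tuple[int, int]] = set()
    plants: list[TriangleMesh] = []
    grid: list[tuple[int, int]] = []
    for (ar, ac) in plan.anchors:
        dr, dc = ar - r_src, ac - c_src
        shift = np.array([dc * layout.plant_spacing, dr * layout.row_spacing, 0.0])
        for mesh, (r, c) in zip(units, unit_cells):
            cell = (r + dr, c + dc)
            if cell in seen:
                raise RuntimeError(f"replication overlap at grid cell {cell}")
            seen.add(cell)
            pid = cell[0] * layout.n_cols + cell[1]
            plants.append(mesh.translated(shift).with_labels(plant_id=pid))
            grid.append(cell)
    if len(seen) != layout.n_plants:
        raise RuntimeError("replication did not cover the full grid")
    return CanopyScene(plants=plants, grid=grid, layout=layout, stage=stage,
                       provenance=provenance)


def build_vcm(scene: CanopyScene, n: int,
              unit_shape: tuple[int, int] | None = None) -> CanopyScene:
    """Build VCM-n from the centre plants of a realistic canopy scene."""
    units, cells = select_center_plants(scene, n, unit_shape)
    shape = _BLOCK_SHAPES.get(n, unit_shape) if unit_shape is None else unit_shape
    plan = compute_replication_positions(scene.layout, shape)
    return replicate_canopy(units, cells, plan, scene.layout, stage=scene.stage,
                            provenance=f"VCM-{n}")


def unit_tile_scene(scene: CanopyScene, n: int,
                    unit_shape: tuple[int, int] | None = None) -> CanopyScene:
    """The VCM-n unit block alone on its own (smaller) periodic tile.

    Under periodic boundary conditions a VCM is an exact tiling of this unit,
    so per-ground-area radiation results of the unit tile equal those of the
    full 64-plant VCM (the clone-tile equivalence).
    """
    units, cells = select_center_plants(scene, n, unit_shape)
    shape = _BLOCK_SHAPES.get(n, unit_shape) if unit_shape is None else unit_shape
    br, bc = shape
    lay = scene.layout
    sub = CanopyLayout(n_rows=br, n_cols=bc, row_spacing=lay.row_spacing,
                       plant_spacing=lay.plant_spacing)
    r0 = min(r for r, _ in cells)
    c0 = min(c for _, c in cells)
    shift = np.array([-c0 * lay.plant_spacing, -r0 * lay.row_spacing, 0.0])
    plants, grid = [], []
    for mesh, (r, c) in zip(units, cells):
        cell = (r - r0, c - c0)
        plants.append(mesh.translated(shift).with_labels(
            plant_id=cell[0] * bc + cell[1]))
        grid.append(cell)
    return CanopyScene(plants=plants, grid=grid, layout=sub, stage=scene.stage,
                       provenance=f"VCM-{n}-tile")
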