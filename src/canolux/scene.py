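"""Canopy scene: plants placed on a plot grid with a periodic lateral domain."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ORGAN_LEAF, TriangleMesh, mesh_area


@dataclass(frozen=True)
class CanopyLayout:
    """Plot planting grid.

    Plants sit at (col * plant_spacing, row * row_spacing); x is the
    within-row direction (row axis), y steps across rows.
    """

    n_rows: int = 8
    n_cols: int = 8
    row_spacing: float = 0.666
    plant_spacing: float = 0.266

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("layout must have at least one row and column")
        if self.row_spacing <= 0 or self.plant_spacing <= 0:
            raise ValueError("spacings must be positive")

    @property
    def n_plants(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def ground_area(self) -> float:
        """S = (n_rows * row_spacing) * (n_cols * plant_spacing)."""
        return self.n_rows * self.row_spacing * self.n_cols * self.plant_spacing

    def position(self, row: int, col: int) -> np.ndarray:
        return np.array([col * self.plant_spacing, row * self.row_spacing, 0.0])

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the periodic lateral domain.

        Each plant is centred in its grid tile, so the domain spans exactly
        n_cols * plant_spacing by n_rows * row_spacing.
        """
        ps, rs = self.plant_spacing, self.row_spacing
        return (-ps / 2, (self.n_cols - 0.5) * ps, -rs / 2, (self.n_rows - 0.5) * rs)


@dataclass
class CanopyScene:
    """A set of plant meshes on a plot grid.

    ``grid[i]`` is the (row, col) cell of ``plants[i]``; every plant mesh
    carries its plant_id label already.  ``provenance`` tags the canopy type
    (RCM for a heterogeneous stand, VCM-n for replicated canopies).
    """

    plants: list[TriangleMesh]
    grid: list[tuple[int, int]]
    layout: CanopyLayout
    stage: str = "late"
    provenance: str = "RCM"

    def __post_init__(self):
        if len(self.plants) != len(self.grid):
            raise ValueError("plants and grid must have equal length")

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def ground_area(self) -> float:
        return self.layout.ground_area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.layout.bounds

    def merged_mesh(self) -> TriangleMesh:
        return TriangleMesh.concatenate(self.plants)

    def total_leaf_area(self) -> float:
        return sum(mesh_area(p, ORGAN_LEAF) for p in self.plants)

    def height(self) -> float:
        return max((float(p.vertices[:, 2].max()) for p in self.plants if p.n_vertices),
                   default=0.0)

    def plant_at(self, row: int, col: int) -> TriangleMesh:
        try:
            i = self.grid.index((row, col))
        except ValueError:
            raise KeyError(f"no plant at grid cell ({row}, {col})") from None
        return self.plants[i]
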