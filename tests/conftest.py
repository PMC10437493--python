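import numpy as np
import pytest

import canolux as cx


@pytest.fixture(scope="session")
def small_layout():
    """A 2x2 plot with the study's row/plant spacing."""
    return cx.CanopyLayout(n_rows=2, n_cols=2, row_spacing=0.666,
                           plant_spacing=0.266)


@pytest.fixture(scope="session")
def early_scene(small_layout):
    return cx.generate_canopy(small_layout, stage="early", seed=7)


@pytest.fixture(scope="session")
def late_scene(small_layout):
    return cx.generate_canopy(small_layout, stage="late", seed=7)


@pytest.fixture(scope="session")
def full_scene():
    """A full 8x8, 64-plant late-stage canopy."""
    return cx.generate_canopy(stage="late", seed=11)


@pytest.fixture(scope="session")
def simple_plant():
    leaves = tuple(
        cx.LeafParams(length=0.5, max_width=0.07, insertion_height=0.25 + 0.15 * i,
                      insertion_angle=50.0, azimuth=180.0 * i, curvature=0.5)
        for i in range(6)
    )
    params = cx.PlantParams(n_leaves=6, height=1.4, leaf_params=leaves,
                            phyllotaxy_noise_sd=5.0)
    return cx.generate_plant(params, seed=3)


def random_triangles(rng: np.random.Generator, n: int,
                     slivers: bool = False) -> cx.TriangleMesh:
    """n random triangles; optionally replace a third with needle shapes."""
    v = rng.normal(size=(n, 3, 3))
    if slivers:
        k = n // 3
        v[:k, 2] = (v[:k, 0] + 1e-4 * (v[:k, 1] - v[:k, 0])
                    + 1e-7 * rng.normal(size=(k, 3)))
    verts = v.reshape(-1, 3)
    faces = np.arange(3 * n).reshape(-1, 3)
    return cx.TriangleMesh(verts, faces)
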