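"""Phenotypic traits: PH, CC, PAI, COV."""

import numpy as np
import pytest

import canolux as cx
from canolux.geometry import ORGAN_LEAF
from canolux.traits import alpha_shape_area, canopy_occupation_volume


def clip_triangle_to_box(tri, lo, hi, eps=1e-12):
    """Independent triangle/box intersection test by Sutherland-Hodgman
    clipping against the six box half-spaces (touching counts)."""
    poly = [np.asarray(p, dtype=float) for p in tri]
    for axis in range(3):
        for sign, bound in ((1.0, lo[axis]), (-1.0, -hi[axis])):
            if not poly:
                return False
            out = []
            d = [sign * p[axis] - bound for p in poly]
            for i in range(len(poly)):
                j = (i + 1) % len(poly)
                if d[i] >= -eps:
                    out.append(poly[i])
                    if d[j] < -eps and abs(d[i] - d[j]) > eps:
                        t = d[i] / (d[i] - d[j])
                        out.append(poly[i] + t * (poly[j] - poly[i]))
                elif d[j] >= -eps and abs(d[i] - d[j]) > eps:
                    t = d[i] / (d[i] - d[j])
                    out.append(poly[i] + t * (poly[j] - poly[i]))
            poly = out
    return len(poly) > 0


def brute_force_cov(mesh, voxel, origin=(0.0, 0.0, 0.0)):
    """Exhaustive voxel scan over the mesh bounding box."""
    origin = np.asarray(origin, float)
    tris = mesh.triangles()
    lo = tris.reshape(-1, 3).min(axis=0)
    hi = tris.reshape(-1, 3).max(axis=0)
    i0 = np.floor((lo - origin) / voxel).astype(int) - 1
    i1 = np.floor((hi - origin) / voxel).astype(int) + 1
    occupied = set()
    for t in tris:
        for i in range(i0[0], i1[0] + 1):
            for j in range(i0[1], i1[1] + 1):
                for k in range(i0[2], i1[2] + 1):
                    if (i, j, k) in occupied:
                        continue
                    vlo = origin + np.array([i, j, k]) * voxel
                    vhi = vlo + voxel
                    if clip_triangle_to_box(t, vlo, vhi):
                        occupied.add((i, j, k))
    return len(occupied) * voxel**3


class TestPlantHeight:
    def test_percentile_oracle_enumerated(self):
        z = np.arange(100) / 100.0
        pts = np.column_stack([np.zeros(100), np.zeros(100), z])
        # linear-interpolation 99th percentile of {0, 0.01, ..., 0.99}
        expected = np.percentile(z, 99) - 0.0
        assert expected == pytest.approx(0.9801)
        assert cx.plant_height(pts) == pytest.approx(0.9801, abs=1e-12)

    def test_constant_height_zero(self):
        pts = np.tile([0.0, 0.0, 0.7], (10, 1))
        assert cx.plant_height(pts) == 0.0

    def test_outlier_robustness(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.random(200), rng.random(200),
                               rng.random(200)])
        base = cx.plant_height(pts)
        excess = 10.0
        spiked = np.vstack([pts, [[0, 0, pts[:, 2].max() + excess]]])
        assert cx.plant_height(spiked) - base < excess

    def test_horizontal_translation_invariant(self, simple_plant):
        a = cx.plant_height(simple_plant)
        b = cx.plant_height(simple_plant.translated([3.0, -2.0, 0.0]))
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cx.plant_height(np.zeros((0, 3)))


class TestCanopyCover:
    def test_ring_fixture_closed_form(self):
        """Dense annulus: alpha shape fills the disc, occupation covers only
        the ring cells, so CC ~ ring area / disc area."""
        rng = np.random.default_rng(1)
        n = 500_000
        r_in, r_out = 0.8, 1.0
        r = np.sqrt(rng.uniform(r_in**2, r_out**2, n))
        t = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(n)])
        cloud = cx.PointCloud(pts)
        # small cells keep the boundary-cell overcount below the tolerance;
        # alpha larger than the hole's circumradii closes the alpha shape
        # over the hole, approximating the full disc
        cc = cx.canopy_cover(cloud, grid_cell=0.005, alpha=2.0)
        ring_area = np.pi * (r_out**2 - r_in**2)
        disc_area = np.pi * r_out**2
        expected = ring_area / disc_area
        assert cc == pytest.approx(expected, rel=0.03)

    def test_saturated_square_cc_near_one(self):
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.random(40000), rng.random(40000),
                               np.zeros(40000)])
        cc = cx.canopy_cover(cx.PointCloud(pts), grid_cell=0.05, alpha=0.2)
        assert cc > 0.97

    def test_single_cluster_ratio(self):
        rng = np.random.default_rng(3)
        # tight cluster inside one cell plus a wide sparse triangle frame
        cluster = rng.normal(scale=0.002, size=(200, 2)) + 0.45
        frame = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
        xy = np.vstack([cluster, frame])
        pts = np.column_stack([xy, np.zeros(len(xy))])
        cell = 0.1
        cc = cx.canopy_cover(cx.PointCloud(pts), grid_cell=cell, alpha=2.0)
        alpha_area = alpha_shape_area(xy, 2.0)
        occupied = len({tuple(c) for c in np.floor(xy / cell).astype(int)})
        assert cc == pytest.approx(occupied * cell**2 / alpha_area, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cx.canopy_cover(cx.PointCloud(np.zeros((2, 3))))

    def test_alpha_shape_square_area(self):
        g = np.linspace(0, 1, 21)
        gx, gy = np.meshgrid(g, g)
        xy = np.column_stack([gx.ravel(), gy.ravel()])
        assert alpha_shape_area(xy, alpha=0.2) == pytest.approx(1.0, rel=1e-9)


class TestPAI:
    def test_half_square_metre_leaf(self):
        mesh = cx.TriangleMesh([[0, 0, 1], [1, 0, 1], [0, 1, 1]], [[0, 1, 2]],
                               organ=[ORGAN_LEAF])
        assert cx.plant_area_index(mesh, 1.0) == pytest.approx(0.5)

    def test_vcm1_replication_arithmetic(self):
        rcm = cx.generate_canopy(stage="early", seed=9)
        vcm1 = cx.build_vcm(rcm, 1)
        unit_leaf = cx.mesh_area(cx.select_center_plants(rcm, 1)[0][0],
                                 ORGAN_LEAF)
        mesh = vcm1.merged_mesh()
        pai = cx.plant_area_index(
            mesh.select_faces(mesh.organ == ORGAN_LEAF), vcm1.ground_area)
        assert pai == pytest.approx(64 * unit_leaf / rcm.ground_area, rel=1e-9)

    def test_generator_truth(self, late_scene):
        mesh = late_scene.merged_mesh()
        leaf_only = mesh.select_faces(mesh.organ == ORGAN_LEAF)
        pai = cx.plant_area_index(leaf_only, late_scene.ground_area)
        truth = late_scene.total_leaf_area() / late_scene.ground_area
        assert pai == pytest.approx(truth, rel=0.01)

    def test_translation_invariant(self, simple_plant):
        a = cx.plant_area_index(simple_plant, 2.0)
        b = cx.plant_area_index(simple_plant.translated([1, 2, 3]), 2.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_bad_ground_area_rejected(self, simple_plant):
        with pytest.raises(ValueError):
            cx.plant_area_index(simple_plant, 0.0)


class TestCOV:
    def test_triangle_inside_one_voxel(self):
        tri = cx.TriangleMesh([[0.002, 0.002, 0.002], [0.008, 0.002, 0.002],
                               [0.002, 0.008, 0.002]], [[0, 1, 2]])
        assert canopy_occupation_volume(tri, voxel=0.01) == pytest.approx(1e-6)

    def test_boundary_square_matches_bruteforce(self):
        """10 cm x 10 cm horizontal square exactly on a voxel boundary
        plane: occupancy equals the exhaustive clip-based oracle."""
        z = 0.05  # exactly on the plane between voxel layers 4 and 5
        mesh = cx.TriangleMesh(
            [[0.001, 0.001, z], [0.101, 0.001, z], [0.101, 0.101, z],
             [0.001, 0.101, z]],
            [[0, 1, 2], [0, 2, 3]])
        got = canopy_occupation_volume(mesh, voxel=0.01)
        expected = brute_force_cov(mesh, 0.01)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_random_mesh_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0.01, 0.4, size=(30, 3))
        faces = np.arange(30).reshape(10, 3)
        mesh = cx.TriangleMesh(v, faces)
        got = canopy_occupation_volume(mesh, voxel=0.02)
        expected = brute_force_cov(mesh, 0.02)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_voxel_aligned_translation_invariant(self, simple_plant):
        a = canopy_occupation_volume(simple_plant, voxel=0.01)
        b = canopy_occupation_volume(simple_plant.translated([0.27, 0.13, 0.0]),
                                     voxel=0.01)
        assert a == pytest.approx(b, rel=1e-12)

    def test_triangle_method_covers_vertex_method(self, simple_plant):
        tri = canopy_occupation_volume(simple_plant, voxel=0.01)
        vert = canopy_occupation_volume(simple_plant, voxel=0.01,
                                        method="vertices")
        assert tri >= vert

    def test_monotone_under_union(self, simple_plant):
        half = simple_plant.select_faces(
            np.arange(simple_plant.n_faces) < simple_plant.n_faces // 2)
        a = canopy_occupation_volume(half, voxel=0.01)
        b = canopy_occupation_volume(simple_plant, voxel=0.01)
        assert b >= a


class TestTraitBattery:
    def test_extract_traits_fields(self, late_scene):
        t = cx.extract_traits(late_scene, scene_id="s1")
        assert 0 < t.cc <= 1
        assert t.ph > 1.0
        assert t.pai > 1.0
        assert t.cov > 0
        assert t.canopy_type == "RCM"

    def test_invalid_traits_rejected(self):
        with pytest.raises(ValueError):
            cx.TraitSet(ph=-1, cc=0.5, pai=1, cov=1)
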