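"""Reverse ray tracing: oracles, energy bookkeeping, daily integration."""

import datetime as dt

import numpy as np
import pytest

import canolux as cx
from canolux.geometry import ORGAN_LEAF
from canolux.radiation import compute_layer_ratios, prepare_scene


def horizontal_square(size=1.0, z=1.0, organ=ORGAN_LEAF, center=(0.0, 0.0)):
    cxx, cy = center
    h = size / 2
    v = np.array([[cxx - h, cy - h, z], [cxx + h, cy - h, z],
                  [cxx + h, cy + h, z], [cxx - h, cy + h, z]])
    return cx.TriangleMesh(v, [[0, 1, 2], [0, 2, 3]]).with_labels(organ=organ)


def direct_sky(dni, zenith_deg, azimuth_deg=180.0):
    s = cx.sun_direction(zenith_deg, azimuth_deg)
    return cx.SkyIrradiance(
        direct_horizontal=dni * max(s[2], 0.0),
        diffuse_horizontal=0.0,
        sun_direction=tuple(s))


BLACK = cx.OpticalProperties(0.0, 0.0, 0.0)


class TestSingleLeafOracle:
    @pytest.mark.parametrize("zenith", [0.0, 30.0, 60.0])
    def test_deterministic_exact_cosine(self, zenith):
        leaf = horizontal_square(z=1.0)
        cfg = cx.RadiationConfig(periodic=False, include_ground=False)
        fm = cx.trace_radiation(leaf, direct_sky(100.0, zenith), BLACK, cfg)
        expected = 100.0 * np.cos(np.radians(zenith)) * leaf.area()
        assert fm.leaf_absorbed_W == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("zenith", [0.0, 30.0, 60.0])
    def test_montecarlo_within_one_percent(self, zenith):
        leaf = horizontal_square(z=1.0)
        cfg = cx.RadiationConfig(periodic=False, include_ground=False,
                                 mode="montecarlo", rays_per_facet_direct=200,
                                 seed=3)
        fm = cx.trace_radiation(leaf, direct_sky(100.0, zenith), BLACK, cfg)
        expected = 100.0 * np.cos(np.radians(zenith)) * leaf.area()
        assert fm.leaf_absorbed_W == pytest.approx(expected, rel=0.01)

    def test_first_interaction_absorbs_1_minus_rho_tau(self):
        leaf = horizontal_square(z=1.0)
        cfg = cx.RadiationConfig(periodic=False, include_ground=False)
        optics = cx.OpticalProperties(0.1, 0.1, 0.0)
        fm = cx.trace_radiation(leaf, direct_sky(100.0, 0.0), optics, cfg)
        assert fm.leaf_absorbed_W == pytest.approx(0.8 * fm.incident_W, rel=1e-12)


class TestOneBounceClosedForm:
    """Opaque full-cover layer (rho = tau = 0.1) over black ground, overhead
    sun: the layer absorbs 0.8 I, the ground 0.1 I, 0.1 I escapes upward."""

    @pytest.mark.parametrize("mode,tol", [("deterministic", 1e-9),
                                          ("montecarlo", 0.01)])
    def test_energy_split(self, mode, tol):
        layer = horizontal_square(size=2.0, z=0.5, center=(1.0, 1.0))
        ground = cx.ground_mesh((0.0, 2.0, 0.0, 2.0), resolution=0.5)
        mesh = cx.TriangleMesh.concatenate([layer, ground])
        cfg = cx.RadiationConfig(periodic=True, include_ground=False,
                                 mode=mode, seed=5,
                                 rays_per_facet_direct=64 if mode == "montecarlo" else 1,
                                 scatter_samples=400 if mode == "montecarlo" else 8)
        # periodic domain exactly the layer/ground footprint
        prep = prepare_scene(mesh, cfg, bounds=(0.0, 2.0, 0.0, 2.0),
                             ground_area=4.0)
        optics = cx.OpticalProperties(0.1, 0.1, 0.0)
        fm = cx.trace_radiation(prep, direct_sky(100.0, 0.0), optics, cfg)
        incident = 100.0 * 4.0  # I x layer area, overhead sun
        assert fm.incident_W == pytest.approx(incident, rel=1e-9)
        assert fm.leaf_absorbed_W == pytest.approx(0.8 * incident, rel=tol)
        assert fm.ground_absorbed_W == pytest.approx(0.1 * incident, rel=tol)
        assert fm.escaped_W == pytest.approx(0.1 * incident, rel=tol)


class TestEnergyLedger:
    def test_closure_on_canopy_scene(self, late_scene):
        cfg = cx.RadiationConfig(diffuse_sky_samples=8)
        geom = cx.SolarGeometry(hour=10.0, date=dt.date(2022, 8, 24))
        sky = cx.clear_sky_irradiance(geom)
        fm = cx.trace_radiation(late_scene, sky, cx.OpticalProperties(), cfg)
        closure = fm.incident_W - (fm.leaf_absorbed_W + fm.ground_absorbed_W
                                   + fm.escaped_W + fm.residual_W)
        assert abs(closure) < 1e-9 * fm.incident_W
        assert fm.residual_W <= 0.2**8 * fm.incident_W

    def test_empty_scene_all_to_ground(self, small_layout):
        scene = cx.CanopyScene(plants=[], grid=[], layout=small_layout)
        cfg = cx.RadiationConfig()
        sky = direct_sky(100.0, 20.0)
        fm = cx.trace_radiation(scene, sky, cx.OpticalProperties(), cfg)
        assert fm.leaf_absorbed_W == 0.0
        assert fm.ground_absorbed_W == pytest.approx(fm.incident_W, rel=1e-12)

    def test_seeded_montecarlo_reproducible(self, early_scene):
        cfg = cx.RadiationConfig(mode="montecarlo", seed=17,
                                 rays_per_facet_direct=4,
                                 diffuse_sky_samples=4, scatter_samples=2)
        sky = direct_sky(300.0, 35.0)
        a = cx.trace_radiation(early_scene, sky, cx.OpticalProperties(), cfg)
        b = cx.trace_radiation(early_scene, sky, cx.OpticalProperties(), cfg)
        assert (a.flux == b.flux).all()

    def test_interception_monotone_in_leaf_area(self):
        """Adding a second (non-overlapping) black leaf never reduces direct
        interception."""
        one = horizontal_square(size=0.5, z=1.0, center=(0.3, 0.3))
        two = cx.TriangleMesh.concatenate(
            [one, horizontal_square(size=0.5, z=0.6, center=(1.2, 1.2))])
        cfg = cx.RadiationConfig(periodic=False, include_ground=False)
        sky = direct_sky(100.0, 25.0)
        a = cx.trace_radiation(one, sky, BLACK, cfg).leaf_absorbed_W
        b = cx.trace_radiation(two, sky, BLACK, cfg).leaf_absorbed_W
        assert b >= a - 1e-12

    def test_direct_interception_vanishes_at_horizon(self):
        leaf = horizontal_square(z=1.0)
        cfg = cx.RadiationConfig(periodic=False, include_ground=False)
        for zenith in (80.0, 88.0, 89.9):
            fm = cx.trace_radiation(leaf, direct_sky(100.0, zenith), BLACK, cfg)
            assert fm.leaf_absorbed_W == pytest.approx(
                100.0 * np.cos(np.radians(zenith)) * leaf.area(), rel=1e-9)
        night = cx.SkyIrradiance(0.0, 0.0, tuple(cx.sun_direction(120.0, 0.0)))
        assert cx.trace_radiation(leaf, night, BLACK, cfg).leaf_absorbed_W == 0.0


class TestPeriodicBoundaries:
    def test_infinite_layer_fully_shades_ground(self):
        """A layer covering the periodic tile shades the ground completely,
        including rays that wrap the lateral bounds."""
        layer = horizontal_square(size=2.0, z=0.5, center=(1.0, 1.0))
        ground = cx.ground_mesh((0.0, 2.0, 0.0, 2.0), resolution=0.5)
        mesh = cx.TriangleMesh.concatenate([layer, ground])
        cfg = cx.RadiationConfig(periodic=True, include_ground=False)
        prep = prepare_scene(mesh, cfg, bounds=(0.0, 2.0, 0.0, 2.0),
                             ground_area=4.0)
        fm = cx.trace_radiation(prep, direct_sky(100.0, 60.0), BLACK, cfg)
        assert fm.ground_absorbed_W == 0.0
        assert fm.leaf_absorbed_W == pytest.approx(100.0 * 0.5 * 4.0, rel=1e-9)

    def test_without_periodicity_oblique_rays_escape(self):
        layer = horizontal_square(size=2.0, z=2.0, center=(1.0, 1.0))
        ground = cx.ground_mesh((0.0, 2.0, 0.0, 2.0), resolution=0.5)
        mesh = cx.TriangleMesh.concatenate([layer, ground])
        sky = direct_sky(100.0, 70.0)
        cfg_p = cx.RadiationConfig(periodic=True, include_ground=False)
        prep_p = prepare_scene(mesh, cfg_p, bounds=(0.0, 2.0, 0.0, 2.0),
                               ground_area=4.0)
        periodic = cx.trace_radiation(prep_p, sky, BLACK, cfg_p)
        open_bc = cx.trace_radiation(
            mesh, sky, BLACK, cx.RadiationConfig(periodic=False,
                                                 include_ground=False))
        # with wrapping the ground is fully shaded; without it some ground
        # sees the sun past the layer edge
        assert periodic.ground_absorbed_W == 0.0
        assert open_bc.ground_absorbed_W > 0.0


class TestDailyIntegration:
    def test_polar_night_zero_dli(self, small_layout):
        scene = cx.generate_canopy(small_layout, stage="early", seed=2)
        geom = cx.SolarGeometry(latitude=-80.0, longitude=0.0,
                                date=dt.date(2022, 6, 21), utc_offset=0.0)
        cfg = cx.RadiationConfig(diffuse_sky_samples=4)
        day = cx.simulate_day(scene, geom, cx.OpticalProperties(), cfg)
        assert day.dli == 0.0
        assert (day.layer_ratios == 0).all()

    def test_dli_equals_trapezoid_of_hourly_power(self, early_scene):
        cfg = cx.RadiationConfig(diffuse_sky_samples=4, scatter_samples=2)
        geom = cx.SolarGeometry(date=dt.date(2022, 8, 2))
        day = cx.simulate_day(early_scene, geom, cx.OpticalProperties(), cfg)
        manual = np.trapezoid(day.hourly_canopy_power,
                              day.hours * 3600.0) / early_scene.ground_area * 1e-6
        assert day.dli == pytest.approx(manual, rel=1e-9)
        assert day.dli > 0

    def test_constant_power_rectangle_rule(self):
        """A constant absorbed power P over the 12 h window integrates to
        P * 43200 / S * 1e-6 MJ/m^2 under the trapezoid rule."""
        hours = np.arange(6.0, 18.5, 1.0)
        p = 250.0
        s = 10.0
        dt_s = np.diff(hours) * 3600.0
        dli = 0.5 * ((p + p) * dt_s).sum() / s * 1e-6
        assert dli == pytest.approx(p * 43200.0 / s * 1e-6, rel=1e-12)

    def test_layer_ratio_partition_sums_to_dli(self, early_scene):
        cfg = cx.RadiationConfig(diffuse_sky_samples=4, scatter_samples=2)
        geom = cx.SolarGeometry(date=dt.date(2022, 8, 2))
        day = cx.simulate_day(early_scene, geom, cx.OpticalProperties(), cfg)
        assert day.dli_layers.sum() == pytest.approx(day.dli, rel=1e-9)
        assert day.layer_ratios.sum() == pytest.approx(1.0, abs=1e-9)


class TestLayerRatios:
    def test_all_energy_in_top_layer(self):
        z = np.array([0.96, 0.99])
        e = np.array([3.0, 2.0])
        dli_h, lr = compute_layer_ratios(e, z, ground_area=1.0,
                                         canopy_height=1.0)
        np.testing.assert_allclose(lr, [0] * 9 + [1])

    def test_uniform_layers(self):
        z = np.arange(10) / 10 + 0.05
        e = np.ones(10)
        _, lr = compute_layer_ratios(e, z, 1.0, canopy_height=1.0)
        np.testing.assert_allclose(lr, 0.1)

    def test_matches_bruteforce_binning(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(0, 2.0, 500)
        e = rng.random(500)
        h = 2.0
        dli_h, lr = compute_layer_ratios(e, z, ground_area=3.0, canopy_height=h)
        # independent per-facet binning
        expect = np.zeros(10)
        for zi, ei in zip(z, e):
            k = min(int(zi / (h / 10)), 9)
            expect[k] += ei
        np.testing.assert_allclose(dli_h, expect / 3.0 * 1e-6, rtol=1e-12)
        assert lr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_energy_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero"):
            _, lr = compute_layer_ratios(np.zeros(3), np.array([0.1, 0.5, 0.9]),
                                         1.0, canopy_height=1.0)
        assert (lr == 0).all()


class TestMShape:
    def test_midday_dip_in_row_aligned_canopy(self):
        """North-south rows with open inter-row corridors: hourly
        interception is M-shaped — at solar noon the beam runs along the
        corridors and more light reaches the ground, so canopy interception
        dips below the mid-morning and mid-afternoon shoulders."""
        leaves = tuple(cx.LeafParams(length=0.38, max_width=0.06,
                                     insertion_height=0.25 + 0.14 * i,
                                     insertion_angle=35.0,
                                     azimuth=180.0 * i + 20.0,
                                     curvature=0.35)
                       for i in range(10))
        plant = cx.generate_plant(
            cx.PlantParams(n_leaves=10, height=1.8, leaf_params=leaves,
                           phyllotaxy_noise_sd=0.0), seed=0)
        lay = cx.CanopyLayout()
        plants, grid = [], []
        for r in range(8):
            for c in range(8):
                plants.append(plant.translated(lay.position(r, c))
                              .with_labels(plant_id=r * 8 + c))
                grid.append((r, c))
        scene = cx.CanopyScene(plants=plants, grid=grid, layout=lay)
        cfg = cx.RadiationConfig(diffuse_sky_samples=4, scatter_samples=2,
                                 rays_per_facet_direct=4)
        # longitude on the zone meridian so solar noon ~ clock noon
        geom = cx.SolarGeometry(latitude=35.3, longitude=120.0,
                                date=dt.date(2022, 8, 2))
        day = cx.simulate_day(scene, geom, cx.OpticalProperties(), cfg,
                              atmosphere=cx.AtmosphereParams(diffuse_fraction=0.05))
        w = day.hourly_interception
        noon = w[6]  # 12:00
        assert w[3:6].max() > noon  # morning shoulder higher
        assert w[7:10].max() > noon  # afternoon shoulder higher
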