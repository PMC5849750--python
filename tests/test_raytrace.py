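"""Geometry, source, Fresnel tracing and detection of the ray tracer."""

import math

import numpy as np
import pytest

from taperlight import (
    RayBundle,
    build_geometry,
    detect_irradiance,
    launch_source,
    simulate_emission_profile,
    trace,
)


@pytest.fixture(scope="module")
def geom66(na066):
    return build_geometry(na066, straight_length_um=5000.0)


class TestGeometry:
    def test_taper_length_follows_cone_formula(self, na066):
        g = build_geometry(na066, tip_truncation_um=1.0)
        expected = (230.0 - 1.0) / (2 * math.tan(math.radians(1.85)))
        assert g.taper_length_um == pytest.approx(expected, rel=1e-12)

    def test_steep_taper_length(self, na066):
        from dataclasses import replace

        steep = replace(na066, taper_angle_deg=60.0)
        g = build_geometry(steep, tip_truncation_um=1.0)
        assert g.taper_length_um == pytest.approx(
            229.0 / (2 * math.tan(math.radians(30.0))), rel=1e-12
        )

    def test_tip_truncation_must_be_smaller_than_cladding(self, na066):
        with pytest.raises(ValueError):
            build_geometry(na066, tip_truncation_um=230.0)

    def test_core_cone_strictly_inside_cladding_cone(self, geom66):
        for z in (0.0, 500.0, 2000.0, geom66.taper_length_um):
            r_core = (z + geom66.vertex_offset_um) * geom66.tan_core
            r_clad = (z + geom66.vertex_offset_um) * geom66.tan_clad
            assert r_core < r_clad

    def test_missing_indices_rejected(self):
        from taperlight import FiberSpec

        bare = FiberSpec(core_um=200, clad_um=230, na=0.66)
        with pytest.raises(ValueError, match="n_core"):
            build_geometry(bare)


class TestLaunchSource:
    def test_same_seed_gives_identical_bundle(self, geom66):
        b1 = launch_source(geom66, 20.0, 500, seed=11)
        b2 = launch_source(geom66, 20.0, 500, seed=11)
        assert np.array_equal(b1.origin, b2.origin)
        assert np.array_equal(b1.direction, b2.direction)

    def test_facet_refraction_preserves_transverse_wavevector(self, geom66):
        # n sin(beta_int) = sin(theta) for every ray of a collimated launch
        b = launch_source(geom66, 20.0, 2000, seed=1, source="collimated")
        sin_int = np.hypot(b.direction[:, 0], b.direction[:, 1])
        assert np.allclose(
            geom66.n_core * sin_int, math.sin(math.radians(20.0)), atol=1e-12
        )

    def test_focused_source_spans_the_divergence_cone(self, geom66):
        b = launch_source(geom66, 20.0, 5000, seed=1, source="focused",
                          divergence_half_angle_deg=4.0)
        # every external angle lies within theta +/- divergence
        sin_ext = geom66.n_core * np.hypot(b.direction[:, 0],
                                           b.direction[:, 1])
        theta_ext = np.degrees(np.arcsin(sin_ext))
        assert theta_ext.min() >= 16.0 - 1e-6
        assert theta_ext.max() <= 24.0 + 1e-6
        assert theta_ext.std() > 0.5  # genuinely spread, not collimated

    def test_axial_launch_is_parallel_to_axis(self, geom66):
        b = launch_source(geom66, 0.0, 100, seed=1, source="collimated")
        assert np.allclose(b.direction[:, :2], 0.0)
        assert np.allclose(b.direction[:, 2], -1.0)

    def test_beyond_acceptance_warns_but_launches(self, geom66):
        with pytest.warns(UserWarning, match="acceptance"):
            b = launch_source(geom66, 45.0, 50, seed=1)
        assert len(b) == 50

    def test_rays_inside_core_after_straight_transport(self, geom66):
        b = launch_source(geom66, 25.0, 5000, seed=3)
        r = np.hypot(b.origin[:, 0], b.origin[:, 1])
        assert np.all(r <= geom66.core_radius_um + 1e-9)


class TestTrace:
    def test_axial_ray_reaches_tip_with_no_wall_events(self, geom66):
        bundle = RayBundle(
            origin=[[0.0, 0.0, geom66.z_top_um]],
            direction=[[0.0, 0.0, -1.0]],
            power=[1.0],
            medium=[0],
        )
        res = trace(bundle, geom66)
        walls = (
            res.event_counts["core_cone"] + res.event_counts["clad_cone"]
            + res.event_counts["core_cylinder"]
            + res.event_counts["clad_cylinder"]
        )
        assert walls == 0
        # nearly all power exits the tip facet (normal-incidence Fresnel)
        tip_power = res.escape_power[res.escape_surface == 4].sum()
        assert tip_power > 0.95
        assert res.conservation_error < 1e-9

    def test_meridional_ray_stays_guided_until_cutoff(self, geom66):
        theta_int = math.asin(math.sin(math.radians(20.0)) / geom66.n_core)
        bundle = RayBundle(
            origin=[[0.0, 0.0, geom66.z_top_um]],
            direction=[[math.sin(theta_int), 0.0, -math.cos(theta_int)]],
            power=[1.0],
            medium=[0],
        )
        res = trace(bundle, geom66)
        # no light leaves the glass above the first core-exit position
        assert res.escape_origin[:, 2].max() <= res.cutoff_z_um.max() + 1e-6

    def test_power_audit_closes_for_random_bundle(self, geom66, rng):
        n = 10_000
        z0 = geom66.z_top_um
        r = geom66.core_radius_um * np.sqrt(rng.random(n))
        phi = 2 * np.pi * rng.random(n)
        origin = np.column_stack(
            [r * np.cos(phi), r * np.sin(phi), np.full(n, z0)]
        )
        beta = np.radians(rng.uniform(0, 23, n))
        az = 2 * np.pi * rng.random(n)
        direction = np.column_stack(
            [np.sin(beta) * np.cos(az), np.sin(beta) * np.sin(az),
             -np.cos(beta)]
        )
        bundle = RayBundle(origin=origin, direction=direction,
                           power=np.ones(n), medium=np.zeros(n, dtype=np.int8))
        res = trace(bundle, geom66)
        assert res.conservation_error < 1e-9
        assert res.n_lost == 0

    def test_unit_power_is_split_not_created(self, geom66):
        b = launch_source(geom66, 15.0, 200, seed=2)
        res = trace(b, geom66)
        assert res.escape_power.max() <= 1.0 + 1e-12
        assert res.launched_power == pytest.approx(200.0)


class TestDetection:
    def test_single_escape_lands_in_exactly_one_pixel(self, geom66):
        from taperlight.raytrace import TraceResult

        z_esc = 1000.0
        r_surf = (z_esc + geom66.vertex_offset_um) * geom66.tan_clad
        res = TraceResult(
            escape_origin=np.array([[r_surf, 0.0, z_esc]]),
            escape_direction=np.array([[1.0, 0.0, 0.0]]),
            escape_power=np.array([0.7]),
            escape_surface=np.array([1]),
            launched_power=1.0,
            escaped_side_power=0.7,
            escaped_back_power=0.0,
            terminated_power=0.3,
            leftover_power=0.0,
            lost_power=0.0,
            n_lost=0,
            event_counts={},
        )
        irr = detect_irradiance(res, geom66)
        assert np.count_nonzero(irr.pixels) == 1
        assert irr.pixels.max() == pytest.approx(0.7)
        assert irr.power_detected == pytest.approx(0.7)

    def test_map_total_equals_detected_power(self, geom66):
        b = launch_source(geom66, 20.0, 2000, seed=5)
        res = trace(b, geom66)
        irr = detect_irradiance(res, geom66)
        assert irr.pixels.sum() == pytest.approx(irr.power_detected, rel=1e-12)
        assert (
            irr.power_detected + irr.power_missed
            == pytest.approx(res.escaped_side_power, rel=1e-9)
        )
        assert irr.power_detected <= res.launched_power

    def test_default_grid_shape(self, geom66):
        b = launch_source(geom66, 20.0, 500, seed=5)
        irr = detect_irradiance(trace(b, geom66), geom66)
        assert irr.pixels.shape == (6000, 41)


class TestSimulatedProfiles:
    def test_identical_seed_and_config_reproduce_bitwise(self, na066):
        kwargs = dict(n_rays=3000, seed=21, straight_length_um=2000.0)
        p1 = simulate_emission_profile(na066, 20.0, **kwargs)
        p2 = simulate_emission_profile(na066, 20.0, **kwargs)
        assert np.array_equal(p1.intensity, p2.intensity)

    def test_zero_angle_emits_near_tip_only(self, na066):
        # axial rays stay guided until the last few hundred um of the cone
        # (off-axis rays leak through the walls right next to the facet)
        p = simulate_emission_profile(
            na066, 0.0, n_rays=2000, seed=3, straight_length_um=2000.0,
            source="collimated",
        )
        centroid = float((p.z_um * p.intensity).sum() / p.intensity.sum())
        assert centroid < 300.0

    def test_monte_carlo_convergence_of_profile(self, na066):
        # doubling the ray count with a fresh seed changes the normalized
        # axial profile by less than 5% in L1 norm
        p1 = simulate_emission_profile(na066, 20.0, n_rays=100_000, seed=31)
        p2 = simulate_emission_profile(na066, 20.0, n_rays=200_000, seed=32)
        a = p1.smoothed(101).intensity
        b = p2.smoothed(101).intensity
        a = a / a.sum()
        b = b / b.sum()
        assert np.abs(a - b).sum() < 0.05

    def test_higher_na_fiber_emits_closer_to_tip_at_equal_kt(
        self, na066, na039
    ):
        # equal injected k_t means equal input angle; the 0.66 NA taper
        # out-couples nearer the tip than the 0.39 NA one
        from taperlight import emission_region

        c = {}
        for name, spec in (("66", na066), ("39", na039)):
            p = simulate_emission_profile(spec, 20.0, n_rays=40_000, seed=41)
            c[name] = emission_region(p.smoothed(101)).centroid_um
        assert c["66"] < c["39"]
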