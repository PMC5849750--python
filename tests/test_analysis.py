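"""Emission characterization pipeline: profiles, FED/EL, regions, fits, power."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taperlight import (
    EmissionProfile,
    EmissionRegion,
    emission_length_from_profile,
    emission_region,
    extract_profile,
    first_emission_diameter,
    fit_centroid_vs_angle,
    mean_power_density,
    power_density_map,
)


def make_profile(z, intensity, **meta):
    return EmissionProfile(np.asarray(z, float), np.asarray(intensity, float),
                           meta)


class TestExtractProfile:
    def test_constant_image_gives_flat_profile(self):
        img = np.full((50, 200), 7.0)
        p = extract_profile(img, ((10, 25), (190, 25)), offset_px=0,
                            pixel_pitch_um=2.0, tip_px=(10, 25))
        assert np.allclose(p.intensity, 7.0)
        assert p.z_um[0] == 0.0
        assert p.z_um[-1] == pytest.approx(180 * 2.0)

    def test_gaussian_band_peak_position(self):
        cols = np.arange(300, dtype=float)
        img = np.tile(np.exp(-0.5 * ((cols - 180) / 12) ** 2), (40, 1))
        p = extract_profile(img, ((20, 20), (280, 20)), offset_px=3,
                            pixel_pitch_um=1.0, tip_px=(20, 20))
        peak_z = p.z_um[np.argmax(p.intensity)]
        assert abs(peak_z - 160.0) <= 1.0  # 180 px - 20 px tip, 1 um pitch

    def test_offset_beyond_image_rejected(self):
        img = np.zeros((30, 100))
        with pytest.raises(ValueError, match="bounds"):
            extract_profile(img, ((5, 15), (95, 15)), offset_px=40,
                            pixel_pitch_um=1.0, tip_px=(5, 15))


class TestFirstEmissionDiameter:
    def test_rectangular_profile(self, na066):
        # I=100 for z in [0, z0], 0 beyond: threshold is 50, crossing at z0
        z = np.linspace(0, 3000, 3001)
        intensity = np.where(z <= 2000, 100.0, 0.0)
        fed = first_emission_diameter(make_profile(z, intensity), na066)
        expected = 2 * 2000 * math.tan(math.radians(3.7 / 2))
        assert fed == pytest.approx(expected, rel=1e-3)

    def test_all_zero_profile_rejected(self, na066):
        z = np.linspace(0, 100, 50)
        with pytest.raises(ValueError, match="no emission"):
            first_emission_diameter(make_profile(z, np.zeros_like(z)), na066)

    def test_angle_selective_profile_rejected(self, na066):
        z = np.linspace(0, 100, 50)
        with pytest.raises(ValueError, match="full-NA"):
            first_emission_diameter(
                make_profile(z, np.ones_like(z), theta_deg=20.0), na066
            )

    @settings(derandomize=True, max_examples=50)
    @given(scale=st.floats(1e-3, 1e3))
    def test_invariant_under_intensity_rescaling(self, scale):
        from taperlight import PRESETS

        na066 = PRESETS["NA066"]
        z = np.linspace(0, 3000, 2000)
        intensity = np.clip(1.0 - z / 2500, 0, None) ** 2
        p1 = make_profile(z, intensity)
        p2 = make_profile(z, intensity * scale)
        assert first_emission_diameter(p1, na066) == pytest.approx(
            first_emission_diameter(p2, na066), rel=1e-9
        )


class TestEmissionLength:
    def test_linear_decay_halves_at_midpoint(self):
        L = 2400.0
        z = np.linspace(0, L, 1200)
        p = make_profile(z, 1.0 - z / L)
        assert emission_length_from_profile(p) == pytest.approx(L / 2, rel=1e-3)

    def test_flat_profile_returns_max_z_with_flag(self):
        z = np.linspace(0, 500, 100)
        p = make_profile(z, np.ones_like(z))
        assert emission_length_from_profile(p) == pytest.approx(500.0)
        assert p.meta.get("el_never_halves") is True

    def test_zero_tip_intensity_rejected(self):
        z = np.linspace(0, 500, 100)
        intensity = np.linspace(0, 1, 100)
        with pytest.raises(ValueError, match="tip"):
            emission_length_from_profile(make_profile(z, intensity))


class TestEmissionRegion:
    def test_triangular_pulse_closed_form(self):
        # symmetric triangle centered at c with base width w:
        # FWHM = w/2, centroid = c
        c, w = 1000.0, 400.0
        z = np.linspace(0, 2000, 4001)
        intensity = np.clip(1 - np.abs(z - c) / (w / 2), 0, None)
        r = emission_region(make_profile(z, intensity),
                            subtract_background=False)
        assert r.centroid_um == pytest.approx(c, abs=1.0)
        assert r.fwhm_um == pytest.approx(w / 2, rel=1e-2)
        assert not r.touches_tip

    def test_centroid_translation_equivariance(self):
        z = np.linspace(0, 3000, 3000)
        band = np.exp(-0.5 * ((z - 800) / 200) ** 2)
        r1 = emission_region(make_profile(z, band))
        band2 = np.exp(-0.5 * ((z - 1300) / 200) ** 2)
        r2 = emission_region(make_profile(z, band2))
        assert r2.centroid_um - r1.centroid_um == pytest.approx(500.0, abs=1.0)

    def test_pulse_truncated_at_tip_flagged(self):
        z = np.linspace(0, 2000, 2000)
        band = np.exp(-0.5 * ((z - 50) / 300) ** 2)
        r = emission_region(make_profile(z, band))
        assert r.touches_tip

    def test_secondary_band_ignored_with_main_peak_used(self, caplog):
        z = np.linspace(0, 3000, 3000)
        main = np.exp(-0.5 * ((z - 2000) / 150) ** 2)
        ghost = 0.7 * np.exp(-0.5 * ((z - 500) / 100) ** 2)
        r = emission_region(make_profile(z, main + ghost))
        assert abs(r.centroid_um - 2000) < 10

    def test_flat_profile_rejected(self):
        z = np.linspace(0, 100, 64)
        with pytest.raises(ValueError):
            emission_region(make_profile(z, np.ones_like(z)))


class TestDemuxFit:
    def _regions(self, thetas, slope, intercept, fwhm=400.0, jitter=None):
        out = []
        for i, t in enumerate(thetas):
            c = slope * t + intercept + (jitter[i] if jitter is not None else 0)
            lo, hi = c - fwhm / 2, c + fwhm / 2
            out.append(
                (t, EmissionRegion(centroid_um=c, fwhm_lower_um=lo,
                                   fwhm_upper_um=hi, touches_tip=lo <= 0))
            )
        return out

    def test_exact_line_recovered(self):
        regions = self._regions(np.arange(10.5, 35.1, 0.5), 58.0, -30.0)
        fit = fit_centroid_vs_angle(regions)
        assert fit.slope_um_per_deg == pytest.approx(58.0, rel=1e-12)
        assert fit.rmse_um == pytest.approx(0.0, abs=1e-9)
        assert fit.n_points_excluded == 0

    def test_exclusions_are_exactly_tip_touching_plus_low_angle(self):
        thetas = np.arange(2.0, 35.1, 0.5)
        regions = self._regions(thetas, 58.0, -30.0, fwhm=800.0)
        flagged = sum(r.touches_tip for _, r in regions)
        low = int(np.sum((thetas < 10.0)))
        overlap = sum(
            1 for t, r in regions if r.touches_tip and t < 10.0
        )
        fit = fit_centroid_vs_angle(regions)
        assert fit.n_points_excluded == flagged + low - overlap
        assert fit.n_points_used + fit.n_points_excluded == len(regions)

    def test_slope_recovery_under_centroid_noise(self, rng):
        thetas = np.arange(10.5, 35.1, 0.5)
        jitter = rng.normal(0, 10.0, thetas.size)
        fit = fit_centroid_vs_angle(
            self._regions(thetas, 58.0, -30.0, jitter=jitter)
        )
        se = 10.0 / math.sqrt(np.sum((thetas - thetas.mean()) ** 2))
        assert abs(fit.slope_um_per_deg - 58.0) < 2 * se + 1e-9

    def test_parameter_recovery_sweep(self, rng):
        # randomized slopes and noise levels; median error well below 5%
        errors = []
        for _ in range(100):
            slope = rng.uniform(40, 80)
            sigma = rng.uniform(5, 30)
            thetas = np.arange(10.5, 35.1, 0.5)
            jitter = rng.normal(0, sigma, thetas.size)
            fit = fit_centroid_vs_angle(
                self._regions(thetas, slope, -30.0, jitter=jitter)
            )
            errors.append(abs(fit.slope_um_per_deg - slope) / slope)
        assert np.median(errors) < 0.05

    def test_too_few_points_rejected(self):
        regions = self._regions([12.0, 14.0], 58.0, -30.0)
        with pytest.raises(ValueError):
            fit_centroid_vs_angle(regions)


class TestPowerDensity:
    def test_uniform_frustum_mean_matches_closed_form(self, na066):
        # uniform emission between diameters d1 and d2: the area-weighted
        # mean density is P / (pi (d1+d2)/2 * slant length); pointwise the
        # density varies like 1/a(z) since equal power spreads over a
        # narrower circumference near the tip
        half = math.radians(3.7 / 2)
        z1, z2 = 1000.0, 2000.0
        z = np.linspace(z1, z2, 2001)
        p = make_profile(z, np.ones_like(z))
        pmap = power_density_map(p, 2.0, na066)
        d1, d2 = 2 * z1 * math.tan(half), 2 * z2 * math.tan(half)
        slant = (z2 - z1) / math.cos(half)
        expected = 2.0 / (math.pi * (d1 + d2) / 2 * slant * 1e-6)
        region = EmissionRegion(centroid_um=1500, fwhm_lower_um=z1,
                                fwhm_upper_um=z2)
        assert mean_power_density(pmap, region) == pytest.approx(
            expected, rel=1e-3
        )
        # pointwise inverse-diameter scaling
        mid = 1000
        ratio = (pmap.power_density_mw_per_mm2[10]
                 / pmap.power_density_mw_per_mm2[mid])
        assert ratio == pytest.approx(z[mid] / z[10], rel=1e-2)

    def test_conservation_on_random_profiles(self, na066, rng):
        for _ in range(1000):
            n = rng.integers(50, 400)
            z = np.sort(rng.uniform(10, 3500, n))
            z += np.arange(n) * 1e-6  # enforce strict monotonicity
            intensity = rng.random(n)
            pmap = power_density_map(make_profile(z, intensity), 1.7, na066)
            assert abs(pmap.surface_integral_mw() - 1.7) / 1.7 < 1e-3

    def test_zero_profile_rejected(self, na066):
        z = np.linspace(10, 100, 64)
        with pytest.raises(ValueError):
            power_density_map(make_profile(z, np.zeros_like(z)), 1.0, na066)

    def test_mean_density_of_constant_map(self, na066):
        z = np.linspace(500, 2500, 1000)
        p = make_profile(z, z)  # intensity ~ diameter gives constant density
        pmap = power_density_map(p, 1.0, na066)
        region = EmissionRegion(centroid_um=1500, fwhm_lower_um=1000,
                                fwhm_upper_um=2000)
        mean = mean_power_density(pmap, region)
        mid = (np.abs(z - 1500)).argmin()
        assert mean == pytest.approx(
            pmap.power_density_mw_per_mm2[mid], rel=1e-2
        )

    def test_equal_mean_density_with_area_scaled_powers(self, na066):
        # two emission regions at different taper positions hold the same
        # mean density when total power scales like the emitting area
        half = math.radians(3.7 / 2)
        z = np.linspace(1, 3500, 3500)

        def band(c):
            return np.exp(-0.5 * ((z - c) / 120) ** 2)

        r1 = EmissionRegion(centroid_um=900, fwhm_lower_um=759,
                            fwhm_upper_um=1041)
        r2 = EmissionRegion(centroid_um=2100, fwhm_lower_um=1959,
                            fwhm_upper_um=2241)
        # area ~ mean diameter ~ centroid for equal axial extents
        p1 = power_density_map(make_profile(z, band(900)), 1.0, na066)
        p2 = power_density_map(make_profile(z, band(2100)), 2100 / 900, na066)
        m1 = mean_power_density(p1, r1)
        m2 = mean_power_density(p2, r2)
        assert m1 == pytest.approx(m2, rel=0.01)

    def test_disjoint_region_rejected(self, na066):
        z = np.linspace(500, 1000, 200)
        pmap = power_density_map(make_profile(z, np.ones_like(z)), 1.0, na066)
        region = EmissionRegion(centroid_um=2000, fwhm_lower_um=1900,
                                fwhm_upper_um=2100)
        with pytest.raises(ValueError):
            mean_power_density(pmap, region)


class TestProfileValidation:
    def test_non_monotonic_z_rejected(self):
        with pytest.raises(ValueError):
            EmissionProfile(np.array([0.0, 2.0, 1.0]), np.ones(3))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            EmissionProfile(np.array([0.0, 1.0, 2.0]),
                            np.array([1.0, -0.5, 0.0]))

    def test_smoothing_preserves_total_and_length(self):
        z = np.linspace(0, 100, 500)
        rng = np.random.default_rng(0)
        p = EmissionProfile(z, rng.random(500))
        sm = p.smoothed(21)
        assert sm.z_um.size == p.z_um.size
        assert sm.intensity.sum() == pytest.approx(p.intensity.sum(), rel=0.02)
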