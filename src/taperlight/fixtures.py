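"""Synthetic inputs with known ground truth.

Every analysis operation in this package is exercised against data whose
true parameters are known by construction: full-NA emission profiles with
prescribed FED and EL, angle-sweep profile families with a prescribed
demultiplexing slope, taper micrograph look-alikes, and far-field ring
images.  Each generator is deterministic under a fixed seed and returns its
ground truth alongside the data.

The profile shapes are idealisations: a full-NA profile is piecewise linear
(an onset ramp at the first emission diameter, a slow shoulder, and a linear
decay from the tip), and angle-selective bands are Gaussians truncated at
the tip.  Real micrographs add speckle, taper-surface irregularities and
tissue scattering that these fixtures deliberately omit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .analysis import EmissionProfile, EmissionRegion
from .farfield import FarFieldSetup, radius_from_kt
from .modal import FiberSpec, kt_of_input_angle

__all__ = [
    "FixtureTruth",
    "gen_fullNA_profile",
    "gen_demux_sweep",
    "gen_emission_image",
    "gen_farfield_ring",
]


@dataclass
class FixtureTruth:
    """Ground truth stored alongside generated data."""

    kind: str
    parameters: dict
    seed: int
    noise: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "parameters": self.parameters,
            "seed": self.seed,
            "noise": self.noise,
        }


def gen_fullNA_profile(
    fed_um: float,
    el_um: float,
    spec: FiberSpec,
    n_points: int = 2000,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[EmissionProfile, FixtureTruth]:
    """Full-NA emission profile with prescribed FED and EL.

    The profile (peak normalised to 1 at the tip) is piecewise linear:

    * tip ramp: from 1 at ``z = 0`` down to 1/2 exactly at ``z = el_um``;
    * shoulder: a shallow run from 1/2 down to the FED detection threshold
      ``T`` (half the mean of the >90%-of-max samples) exactly at the axial
      position of the first emission diameter, ``z_FED = FED / (2 tan(psi/2))``;
    * onset: a steep ramp from ``T`` to zero on the entrance side.

    ``noise`` is the standard deviation of additive Gaussian noise as a
    fraction of the peak (clipped at zero).  Requires ``el < z_FED``
    (equivalently alpha < 1) and ``z_FED`` inside the taper.
    """
    half = spec.half_angle_rad
    z_fed = fed_um / (2.0 * math.tan(half))
    z_max = spec.taper_length_um()
    if not el_um < z_fed:
        raise ValueError(
            f"inconsistent FED/EL for psi={spec.taper_angle_deg} deg: "
            f"EL={el_um} um must be smaller than z_FED={z_fed:.1f} um"
        )
    if z_fed >= z_max:
        raise ValueError(
            f"z_FED={z_fed:.1f} um exceeds the taper length {z_max:.1f} um"
        )
    z = np.linspace(0.0, z_max, n_points)

    # tip ramp; the FED threshold is determined by this segment alone
    intensity = np.clip(1.0 - 0.5 * z / el_um, 0.0, None)
    bright = intensity[intensity > 0.9]
    threshold = 0.5 * float(bright.mean())

    drop_w = min(150.0, 0.5 * (z_max - z_fed))
    knots_z = [0.0, el_um, z_fed, z_fed + drop_w, z_max]
    knots_i = [1.0, 0.5, threshold, 0.0, 0.0]
    intensity = np.interp(z, knots_z, knots_i)

    rng = np.random.default_rng(seed)
    if noise > 0:
        intensity = np.clip(intensity + rng.normal(0.0, noise, z.size), 0.0, None)

    profile = EmissionProfile(
        z, intensity,
        {
            "wavelength_nm": spec.wavelength_nm,
            "pixel_pitch_um": float(z[1] - z[0]),
            "source": "synthetic",
        },
    )
    truth = FixtureTruth(
        kind="fullNA_profile",
        parameters={
            "fed_um": fed_um, "el_um": el_um, "z_fed_um": z_fed,
            "threshold": threshold, "taper_angle_deg": spec.taper_angle_deg,
        },
        seed=seed,
        noise={"gaussian_sigma_frac_of_peak": noise},
    )
    return profile, truth


def gen_demux_sweep(
    slope_um_per_deg: float,
    intercept_um: float,
    fwhm_um: float,
    theta_grid_deg,
    noise: float = 0.0,
    seed: int = 0,
    n_points: int = 2000,
    z_max_um: float | None = None,
) -> tuple[list[EmissionProfile], FixtureTruth]:
    """Family of angle-selective profiles with a linear centroid law.

    Each profile is a Gaussian band of constant FWHM centred at
    ``slope * theta + intercept`` (plus optional Gaussian centroid jitter of
    standard deviation ``noise`` um), truncated at the tip — bands pushed
    below ``z = 0`` at small angles lose their lower tail, which is exactly
    what the tip-exclusion rule of the demultiplexing fit must catch.
    """
    if slope_um_per_deg <= 0:
        raise ValueError("slope must be positive")
    theta_grid_deg = np.asarray(theta_grid_deg, dtype=float)
    rng = np.random.default_rng(seed)
    sigma = fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    centroids = (
        slope_um_per_deg * theta_grid_deg + intercept_um
        + (rng.normal(0.0, noise, theta_grid_deg.size) if noise > 0 else 0.0)
    )
    if z_max_um is None:
        z_max_um = float(centroids.max() + 2.0 * fwhm_um)
    z = np.linspace(0.0, z_max_um, n_points)

    profiles = []
    for theta, c in zip(theta_grid_deg, centroids):
        band = np.exp(-0.5 * ((z - c) / sigma) ** 2)
        profiles.append(
            EmissionProfile(
                z.copy(), band,
                {
                    "theta_deg": float(theta),
                    "pixel_pitch_um": float(z[1] - z[0]),
                    "source": "synthetic",
                },
            )
        )
    truth = FixtureTruth(
        kind="demux_sweep",
        parameters={
            "slope_um_per_deg": slope_um_per_deg,
            "intercept_um": intercept_um,
            "fwhm_um": fwhm_um,
            "theta_grid_deg": theta_grid_deg.tolist(),
            "centroids_um": np.asarray(centroids, dtype=float).tolist(),
        },
        seed=seed,
        noise={"centroid_sigma_um": noise},
    )
    return profiles, truth


def gen_emission_image(
    spec: FiberSpec,
    region: EmissionRegion,
    image_shape: tuple[int, int] = (300, 1200),
    pixel_pitch_um: float = 2.0,
    noise: float = 0.0,
    seed: int = 0,
    amplitude: float = 200.0,
    background: float = 10.0,
) -> tuple[np.ndarray, FixtureTruth]:
    """Render a taper micrograph look-alike: dark wedge + emission band.

    The taper silhouette is a dark wedge with apex at the tip pixel, opening
    toward increasing column index at the cladding half-angle.  A band of
    Gaussian cross-section hugs the upper surface, with an axial Gaussian
    envelope matching the requested emission region (centroid, FWHM).  With
    ``noise > 0`` the signal is Poisson-resampled and Gaussian read noise of
    standard deviation ``noise`` counts is added.

    The returned truth includes the surface line endpoints, the tip pixel
    and the (negative) perpendicular offset to pass to ``extract_profile``
    so that the sampling line runs just outside the glass.
    """
    h, w = image_shape
    tip_col, axis_row = 40.0, 0.65 * h
    tan_half = math.tan(spec.half_angle_rad)
    z_span = (w - 1 - tip_col) * pixel_pitch_um
    if region.fwhm_upper_um >= z_span:
        raise ValueError(
            f"emission region extends to {region.fwhm_upper_um:.0f} um, beyond "
            f"the {z_span:.0f} um field of view"
        )

    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    z_um = (cols - tip_col) * pixel_pitch_um
    inside = (cols >= tip_col) & (np.abs(rows - axis_row) <= (cols - tip_col) * tan_half)

    # perpendicular distance (px) from the upper surface line
    ux = 1.0 / math.hypot(1.0, tan_half)
    uy = -tan_half * ux
    d_perp = -(cols - tip_col) * uy + (rows - axis_row) * ux  # >0 below the line
    sigma_perp_px = 3.0
    sigma_z = region.fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    band = (
        amplitude
        * np.exp(-0.5 * ((z_um - region.centroid_um) / max(sigma_z, 1e-9)) ** 2)
        * np.exp(-0.5 * (np.minimum(d_perp, 0.0) / sigma_perp_px) ** 2)
        * (z_um >= 0)
    )
    band[inside] = 0.0
    signal = background + band
    signal[inside] *= 0.15  # glass silhouette is dark but not pitch black

    rng = np.random.default_rng(seed)
    if noise > 0:
        image = rng.poisson(signal).astype(float)
        image += rng.normal(0.0, noise, image.shape)
        image = np.clip(image, 0.0, None)
    else:
        image = signal

    end_col = float(w - 1)
    end_row = axis_row - (end_col - tip_col) * tan_half
    truth = FixtureTruth(
        kind="emission_image",
        parameters={
            "centroid_um": region.centroid_um,
            "fwhm_um": region.fwhm_um,
            "tip_px": (tip_col, axis_row),
            "surface_line": ((tip_col, axis_row), (end_col, end_row)),
            "profile_offset_px": -3.0,
            "pixel_pitch_um": pixel_pitch_um,
            "amplitude": amplitude,
            "background": background,
        },
        seed=seed,
        noise={"poisson": noise > 0, "read_sigma": noise},
    )
    return image, truth


def gen_farfield_ring(
    theta_deg: float,
    wavelength_nm: float,
    setup: FarFieldSetup | None = None,
    radial_width_px: float = 6.0,
    image_shape: tuple[int, int] = (2048, 2048),
    noise: float = 0.0,
    seed: int = 0,
    amplitude: float = 500.0,
    background: float = 5.0,
) -> tuple[np.ndarray, FixtureTruth]:
    """Far-field annulus for injection angle ``theta``.

    The ring radius follows the imaging-train mapping of
    ``k_t = (2 pi / lambda) sin(theta)``; its radial cross-section is a
    Gaussian of the given width.  ``theta = 0`` renders a centred disk.
    Noise as in :func:`gen_emission_image`.

    The default camera model uses a 13 um effective pitch (2x2-binned
    sCMOS) so that rings up to the NA = 0.66 acceptance fit on the chip;
    pass a custom :class:`FarFieldSetup` to change it.
    """
    if setup is None:
        setup = FarFieldSetup(wavelength_nm=wavelength_nm,
                              chip_pixel_pitch_um=13.0)
    h, w = image_shape
    center = setup.chip_center_px
    kt = kt_of_input_angle(theta_deg, wavelength_nm)
    r_px = radius_from_kt(kt, setup) * 1000.0 / setup.chip_pixel_pitch_um
    margin = min(center[0], center[1], w - 1 - center[0], h - 1 - center[1])
    if r_px + 3.0 * radial_width_px > margin:
        raise ValueError(
            f"ring radius {r_px:.0f} px does not fit the {w}x{h} chip"
        )

    yy, xx = np.mgrid[0:h, 0:w]
    rho = np.hypot(xx - center[0], yy - center[1])
    signal = background + amplitude * np.exp(
        -0.5 * ((rho - r_px) / radial_width_px) ** 2
    )
    rng = np.random.default_rng(seed)
    if noise > 0:
        image = rng.poisson(signal).astype(float)
        image += rng.normal(0.0, noise, image.shape)
        image = np.clip(image, 0.0, None)
    else:
        image = signal

    truth = FixtureTruth(
        kind="farfield_ring",
        parameters={
            "theta_deg": theta_deg,
            "wavelength_nm": wavelength_nm,
            "kt": kt,
            "ring_radius_px": r_px,
            "radial_width_px": radial_width_px,
        },
        seed=seed,
        noise={"poisson": noise > 0, "read_sigma": noise},
    )
    return image, truth
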