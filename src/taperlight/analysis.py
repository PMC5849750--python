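"""Characterization pipeline for taper emission.

Operates on 1D intensity profiles measured (or simulated) along a line just
outside the taper surface, with ``z`` the distance from the tip in um:

* full-NA profiles -> First Emission Diameter (FED) and Emission Length (EL);
* angle-selective profiles -> emission-region centroid ``c`` and FWHM
  ``Delta c``, and the linear demultiplexing fit ``c(theta)``;
* power-density maps on the conical surface assuming rotational symmetry.

Threshold crossings are located by linear interpolation between samples; FED
and EL are therefore invariant under uniform intensity rescaling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .modal import FiberSpec

__all__ = [
    "EmissionProfile",
    "EmissionRegion",
    "DemuxFit",
    "PowerDensityMap",
    "extract_profile",
    "first_emission_diameter",
    "emission_length_from_profile",
    "emission_region",
    "fit_centroid_vs_angle",
    "power_density_map",
    "mean_power_density",
]

log = logging.getLogger(__name__)


@dataclass
class EmissionProfile:
    """1D intensity vs distance-from-tip along the taper surface.

    ``z_um`` is strictly increasing with 0 at the tip; ``meta`` carries
    acquisition metadata (``theta_deg`` for angle-selective profiles,
    ``wavelength_nm``, ``pixel_pitch_um``, ``source`` in
    {measured, simulated, synthetic}).
    """

    z_um: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.z_um.shape != self.intensity.shape or self.z_um.ndim != 1:
            raise ValueError("z_um and intensity must be 1D arrays of equal length")
        if self.z_um.size < 2:
            raise ValueError("profile needs at least two samples")
        if not np.all(np.diff(self.z_um) > 0):
            raise ValueError("z_um must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def pixel_pitch_um(self) -> float:
        pitch = self.meta.get("pixel_pitch_um")
        return float(pitch) if pitch else float(np.median(np.diff(self.z_um)))

    def smoothed(self, window: int) -> "EmissionProfile":
        """Moving-average smoothed copy (odd ``window``, samples)."""
        if window < 1 or window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        if window == 1:
            return self
        kernel = np.ones(window) / window
        sm = ndimage.convolve1d(self.intensity, kernel, mode="nearest")
        return EmissionProfile(self.z_um.copy(), sm, dict(self.meta))


@dataclass(frozen=True)
class EmissionRegion:
    """Angle-selective emission band: centroid and FWHM bounds (um from tip)."""

    centroid_um: float
    fwhm_lower_um: float
    fwhm_upper_um: float
    touches_tip: bool = False

    def __post_init__(self) -> None:
        if not self.fwhm_lower_um <= self.centroid_um <= self.fwhm_upper_um:
            raise ValueError("need fwhm_lower <= centroid <= fwhm_upper")

    @property
    def fwhm_um(self) -> float:
        return self.fwhm_upper_um - self.fwhm_lower_um


@dataclass(frozen=True)
class DemuxFit:
    """OLS fit of emission centroid (and FWHM bound tracks) vs input angle."""

    slope_um_per_deg: float
    intercept_um: float
    rmse_um: float
    theta_range_deg: tuple[float, float]
    n_points_used: int
    n_points_excluded: int
    lower_bound_fit: tuple[float, float] | None = None  # (slope, intercept)
    upper_bound_fit: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.rmse_um < 0:
            raise ValueError("rmse must be non-negative")

    def predict(self, theta_deg: float) -> float:
        return self.slope_um_per_deg * theta_deg + self.intercept_um


@dataclass
class PowerDensityMap:
    """Power density on the taper surface vs distance from tip.

    ``power_density_mw_per_mm2[i]`` is the power per unit lateral surface in
    the axial slice centred at ``z_um[i]``; the surface integral over all
    slices returns ``total_power_mw``.
    """

    z_um: np.ndarray
    local_diameter_um: np.ndarray
    power_density_mw_per_mm2: np.ndarray
    total_power_mw: float
    slice_area_mm2: np.ndarray

    def surface_integral_mw(self) -> float:
        return float(np.sum(self.power_density_mw_per_mm2 * self.slice_area_mm2))


# ---------------------------------------------------------------------------
# profile extraction from images
# ---------------------------------------------------------------------------

def extract_profile(
    image: np.ndarray,
    taper_axis_line: tuple[tuple[float, float], tuple[float, float]],
    offset_px: float,
    pixel_pitch_um: float,
    tip_px: tuple[float, float],
    meta: dict | None = None,
) -> EmissionProfile:
    """Sample an intensity profile along a line parallel to the taper surface.

    Parameters
    ----------
    image:
        2D grayscale image, indexed ``image[row, col]``.
    taper_axis_line:
        Two ``(x, y)`` endpoints (pixel coordinates, x = column) of the line
        along the taper surface.  Samples run from the first endpoint to the
        second at one-pixel spacing.
    offset_px:
        Signed displacement applied perpendicular to the line; positive is
        90 degrees counter-clockwise from the line direction (in image
        coordinates with y down this appears as a clockwise offset).
    pixel_pitch_um:
        Physical size of one pixel, um.
    tip_px:
        ``(x, y)`` pixel position of the fiber tip; its projection onto the
        line defines z = 0.

    Intensities are sampled with bilinear interpolation.  The axial
    coordinate is the (signed) arc-length distance from the tip projection,
    so samples on the entrance side of the tip have z > 0.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    (x1, y1), (x2, y2) = taper_axis_line
    length = math.hypot(x2 - x1, y2 - y1)
    if length < 1:
        raise ValueError("taper_axis_line endpoints are degenerate")
    ux, uy = (x2 - x1) / length, (y2 - y1) / length
    # perpendicular, +90 deg CCW from (ux, uy)
    nx, ny = -uy, ux
    n_samples = int(length) + 1
    s = np.arange(n_samples, dtype=float)
    xs = x1 + s * ux + offset_px * nx
    ys = y1 + s * uy + offset_px * ny

    h, w = img.shape
    inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    if not np.all(inside):
        bad = np.where(~inside)[0]
        raise ValueError(
            f"sampling line leaves image bounds for samples "
            f"{bad[0]}..{bad[-1]} of {n_samples} (offset_px={offset_px})"
        )
    vals = ndimage.map_coordinates(img, np.vstack([ys, xs]), order=1)

    # z = arc-length distance from the projection of the tip onto the line
    s_tip = (tip_px[0] - x1) * ux + (tip_px[1] - y1) * uy
    z = (s - s_tip) * pixel_pitch_um

    m = {"pixel_pitch_um": pixel_pitch_um, "source": "measured"}
    if meta:
        m.update(meta)
    if z[0] > z[-1]:  # orient tip -> entrance
        z, vals = z[::-1], vals[::-1]
    return EmissionProfile(z, np.clip(vals, 0.0, None), m)


# ---------------------------------------------------------------------------
# full-NA profile metrics: FED and EL
# ---------------------------------------------------------------------------

def _crossing(z0: float, z1: float, i0: float, i1: float, level: float) -> float:
    """Linear-interpolated z where intensity crosses ``level`` between samples."""
    if i1 == i0:
        return z0
    return z0 + (level - i0) * (z1 - z0) / (i1 - i0)


def first_emission_diameter(profile: EmissionProfile, spec: FiberSpec) -> float:
    """First Emission Diameter from a full-NA emission profile.

    The detection threshold is half the mean intensity of the pixels brighter
    than 90% of the profile maximum.  Walking from the taper entrance (large
    z) toward the tip, the FED is the local taper diameter
    ``2 z* tan(psi/2)`` at the first (largest-z) sub-pixel crossing where the
    profile rises above the threshold.
    """
    if profile.meta.get("theta_deg") is not None:
        raise ValueError(
            "FED is defined for full-NA profiles (meta.theta_deg must be absent)"
        )
    intensity = profile.intensity
    peak = float(intensity.max())
    if peak <= 0:
        raise ValueError("no emission detected: profile is identically zero")
    bright = intensity[intensity > 0.9 * peak]
    threshold = 0.5 * float(bright.mean())

    above = intensity > threshold
    if not above.any():
        raise ValueError("no emission detected: profile never exceeds the threshold")
    j = int(np.max(np.nonzero(above)[0]))  # largest-z sample above threshold
    if j == intensity.size - 1:
        z_star = float(profile.z_um[j])
    else:
        z_star = _crossing(
            profile.z_um[j], profile.z_um[j + 1],
            intensity[j], intensity[j + 1], threshold,
        )
    return 2.0 * z_star * math.tan(spec.half_angle_rad)


def emission_length_from_profile(profile: EmissionProfile) -> float:
    """Emission Length: largest z where intensity is still >= half the tip value.

    ``I_tip`` is the intensity at the smallest z.  If the profile never drops
    below ``I_tip / 2`` the maximum z is returned (flagged in
    ``profile.meta['el_never_halves']``) rather than raising.
    """
    intensity = profile.intensity
    i_tip = float(intensity[0])
    if i_tip <= 0:
        raise ValueError("tip intensity is zero; EL undefined")
    level = 0.5 * i_tip
    above = intensity >= level
    j = int(np.max(np.nonzero(above)[0]))
    if j == intensity.size - 1:
        profile.meta["el_never_halves"] = True
        return float(profile.z_um[-1])
    return _crossing(
        profile.z_um[j], profile.z_um[j + 1],
        intensity[j], intensity[j + 1], level,
    )


# ---------------------------------------------------------------------------
# angle-selective emission region
# ---------------------------------------------------------------------------

def _subtract_background(intensity: np.ndarray) -> np.ndarray:
    """Median of the lowest-decile intensities, clipped at zero."""
    k = max(1, intensity.size // 10)
    floor = float(np.median(np.sort(intensity)[:k]))
    return np.clip(intensity - floor, 0.0, None)


def emission_region(
    profile: EmissionProfile,
    subtract_background: bool = True,
) -> EmissionRegion:
    """Centroid and FWHM of the emission band in an angle-selective profile.

    After optional background subtraction, the contiguous region around the
    global maximum that stays above half-maximum is delimited by
    linear-interpolated half crossings, and the centroid is the
    intensity-weighted mean z restricted to that region.  If other disjoint
    above-half regions exist they are ignored with a logged warning.
    ``touches_tip`` is set when the lower bound reaches the first sample
    within one pixel pitch.
    """
    z = profile.z_um
    intensity = (
        _subtract_background(profile.intensity)
        if subtract_background
        else profile.intensity.copy()
    )
    peak = float(intensity.max())
    # peaks at the float-noise level of the raw data are not emission
    if peak <= 1e-9 * max(float(profile.intensity.max()), 1e-300):
        raise ValueError("no emission band: profile is flat after background removal")
    half = 0.5 * peak
    imax = int(np.argmax(intensity))

    above = intensity >= half
    # contiguous run containing the global maximum
    lo = imax
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = imax
    while hi < z.size - 1 and above[hi + 1]:
        hi += 1
    n_regions = int(np.sum(np.diff(above.astype(int)) == 1) + above[0])
    if n_regions > 1:
        log.warning(
            "%d disjoint above-half regions; using the one containing the maximum",
            n_regions,
        )

    lower = (
        float(z[0]) if lo == 0
        else _crossing(z[lo - 1], z[lo], intensity[lo - 1], intensity[lo], half)
    )
    upper = (
        float(z[-1]) if hi == z.size - 1
        else _crossing(z[hi], z[hi + 1], intensity[hi], intensity[hi + 1], half)
    )
    sel = slice(lo, hi + 1)
    centroid = float(np.sum(z[sel] * intensity[sel]) / np.sum(intensity[sel]))
    touches = lower <= float(z[0]) + profile.pixel_pitch_um
    return EmissionRegion(
        centroid_um=centroid,
        fwhm_lower_um=lower,
        fwhm_upper_um=upper,
        touches_tip=bool(touches),
    )


def fit_centroid_vs_angle(
    regions: list[tuple[float, EmissionRegion]],
    theta_min_deg: float = 10.0,
) -> DemuxFit:
    """OLS fit of emission centroid on input angle over the linear range.

    Points with ``theta < theta_min_deg`` and points whose emission band
    touches the fiber tip (the tip breaks the band symmetry) are excluded.
    The FWHM lower/upper bound tracks are fitted with the same point set.
    """
    if len(regions) < 3:
        raise ValueError(f"need at least 3 points, got {len(regions)}")
    theta = np.array([t for t, _ in regions], dtype=float)
    keep = (theta >= theta_min_deg) & np.array(
        [not r.touches_tip for _, r in regions]
    )
    n_used = int(keep.sum())
    if n_used < 3:
        raise ValueError(
            f"only {n_used} usable points after exclusions (need >= 3)"
        )
    th = theta[keep]
    c = np.array([r.centroid_um for _, r in regions], dtype=float)[keep]
    lower = np.array([r.fwhm_lower_um for _, r in regions], dtype=float)[keep]
    upper = np.array([r.fwhm_upper_um for _, r in regions], dtype=float)[keep]

    slope, intercept = np.polyfit(th, c, 1)
    resid = c - (slope * th + intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    lo_fit = tuple(np.polyfit(th, lower, 1))
    up_fit = tuple(np.polyfit(th, upper, 1))
    return DemuxFit(
        slope_um_per_deg=float(slope),
        intercept_um=float(intercept),
        rmse_um=rmse,
        theta_range_deg=(float(th.min()), float(th.max())),
        n_points_used=n_used,
        n_points_excluded=len(regions) - n_used,
        lower_bound_fit=(float(lo_fit[0]), float(lo_fit[1])),
        upper_bound_fit=(float(up_fit[0]), float(up_fit[1])),
    )


# ---------------------------------------------------------------------------
# power density on the taper surface
# ---------------------------------------------------------------------------

def power_density_map(
    profile: EmissionProfile,
    total_power_mw: float,
    spec: FiberSpec,
) -> PowerDensityMap:
    """Distribute a measured total output power over the conical surface.

    Assuming rotational symmetry, the power emitted from the axial slice at
    ``z`` is proportional to the profile intensity there; the slice's lateral
    (slant) area is ``dA = pi a(z) dz / cos(psi/2)`` with ``a(z) = 2 z
    tan(psi/2)`` the local diameter.  The returned density ``p = dP/dA``
    integrates back to ``total_power_mw`` by construction.
    """
    if total_power_mw <= 0:
        raise ValueError(f"total_power_mw must be positive: {total_power_mw}")
    z = profile.z_um
    intensity = profile.intensity
    dz = np.gradient(z)
    weight = intensity * dz
    norm = float(weight.sum())
    if norm <= 0:
        raise ValueError("profile has zero integral; cannot distribute power")
    slice_power = total_power_mw * weight / norm

    half = spec.half_angle_rad
    diam = 2.0 * z * math.tan(half)
    if np.any((diam <= 0) & (slice_power > 0)):
        raise ValueError("profile carries power at z <= 0 where the diameter vanishes")
    # um^2 -> mm^2
    area = np.pi * diam * dz / math.cos(half) * 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(area > 0, slice_power / np.where(area > 0, area, 1.0), 0.0)
    return PowerDensityMap(
        z_um=z.copy(),
        local_diameter_um=diam,
        power_density_mw_per_mm2=p,
        total_power_mw=float(total_power_mw),
        slice_area_mm2=area,
    )


def mean_power_density(pmap: PowerDensityMap, region: EmissionRegion) -> float:
    """Area-weighted mean power density over a region's FWHM extent, mW/mm^2."""
    sel = (pmap.z_um >= region.fwhm_lower_um) & (pmap.z_um <= region.fwhm_upper_um)
    area = float(pmap.slice_area_mm2[sel].sum())
    if not sel.any() or area <= 0:
        raise ValueError("emission region does not overlap the power-density map")
    power = float(
        (pmap.power_density_mw_per_mm2[sel] * pmap.slice_area_mm2[sel]).sum()
    )
    return power / area
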