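"""Far-field measurement model of the injected transverse wavevector.

Light injected into a fiber patch cord at angle ``theta`` populates a modal
subset with transverse wavevector ``k_t ~ (2 pi / lambda) sin(theta)``.
Imaging the far field of the fiber facet through an objective (focal length
``f_obj``) and a two-lens relay (``f_a``, ``f_b``) maps each ``k_t`` onto a
ring of radius

    r = (f_obj * f_b / f_a) * tan(asin(lambda k_t / 2 pi))

on the camera chip.  This module provides the forward/inverse mapping and
the ring-image analysis that extracts ``k_t(theta) +/- Delta k_t(theta)``
(peak position and half-prominence width of the azimuthally averaged radial
profile).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FarFieldSetup",
    "RingMeasurement",
    "radius_from_kt",
    "kt_from_radius",
    "analyze_ring_image",
    "kt_curve",
]


@dataclass(frozen=True)
class FarFieldSetup:
    """Far-field imaging train: objective + relay + camera chip."""

    wavelength_nm: float
    objective_focal_mm: float = 4.5
    relay_focal_a_mm: float = 40.0
    relay_focal_b_mm: float = 100.0
    chip_pixel_pitch_um: float = 6.5
    chip_center_px: tuple[float, float] = (1023.5, 1023.5)  # (x, y)

    def __post_init__(self) -> None:
        for name in ("objective_focal_mm", "relay_focal_a_mm", "relay_focal_b_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.wavelength_nm <= 0 or self.chip_pixel_pitch_um <= 0:
            raise ValueError("wavelength and pixel pitch must be positive")

    @property
    def magnification_mm(self) -> float:
        """Radius per unit tangent of the far-field angle (default 11.25 mm)."""
        return self.objective_focal_mm * self.relay_focal_b_mm / self.relay_focal_a_mm


@dataclass(frozen=True)
class RingMeasurement:
    """Peak k_t and half-prominence width for one input angle."""

    theta_deg: float
    kt_peak: float   # nm^-1
    kt_half_prominence_width: float  # nm^-1
    wavelength_nm: float

    def __post_init__(self) -> None:
        k0 = 2.0 * math.pi / self.wavelength_nm
        if not 0 <= self.kt_peak <= k0:
            raise ValueError(f"kt_peak out of [0, 2 pi / lambda]: {self.kt_peak}")
        if self.kt_half_prominence_width < 0:
            raise ValueError("width must be non-negative")


def radius_from_kt(kt: float, setup: FarFieldSetup):
    """Chip radius (mm) of the far-field ring for transverse wavevector ``kt``."""
    kt = np.asarray(kt, dtype=float)
    s = setup.wavelength_nm * kt / (2.0 * math.pi)
    if np.any(kt < 0) or np.any(s >= 1.0):
        raise ValueError(
            "kt must satisfy 0 <= lambda kt / 2 pi < 1 (propagating wave)"
        )
    out = setup.magnification_mm * np.tan(np.arcsin(s))
    return float(out) if out.ndim == 0 else out


def kt_from_radius(r_mm: float, setup: FarFieldSetup):
    """Inverse mapping: transverse wavevector (nm^-1) from chip radius (mm)."""
    r = np.asarray(r_mm, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    out = (2.0 * math.pi / setup.wavelength_nm) * np.sin(
        np.arctan(r / setup.magnification_mm)
    )
    return float(out) if out.ndim == 0 else out


def _radial_profile(image: np.ndarray, center: tuple[float, float],
                    bin_px: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthally averaged intensity vs radius (px), sub-pixel binned."""
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - center[0], yy - center[1]).ravel()
    idx = np.floor(r / bin_px).astype(int)
    vals = image.ravel().astype(float)
    counts = np.bincount(idx)
    sums = np.bincount(idx, weights=vals)
    with np.errstate(invalid="ignore"):
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    radii = (np.arange(prof.size) + 0.5) * bin_px
    good = counts > 0
    return radii[good], prof[good]


def analyze_ring_image(
    image: np.ndarray,
    setup: FarFieldSetup,
    theta_deg: float = float("nan"),
    refine_center: bool = True,
) -> RingMeasurement:
    """Extract peak k_t and half-prominence width from a far-field image.

    The image is azimuthally averaged about the chip center (auto-refined by
    the intensity centroid unless ``refine_center=False``), radii are mapped
    to k_t, and the most prominent peak of the radial profile is located.
    The width is measured at half the peak prominence and reported in k_t
    units via the (nonlinear) radius-to-k_t mapping.  A centered disk
    (``theta = 0`` injection) yields a peak at the innermost bin; its width
    is then twice the half-prominence crossing radius.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    if img.max() <= img.min():
        raise ValueError("blank image: no far-field pattern")
    center = setup.chip_center_px
    if refine_center:
        weight = np.clip(img - np.median(img), 0.0, None)
        tot = weight.sum()
        if tot > 0:
            yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
            center = (float((xx * weight).sum() / tot),
                      float((yy * weight).sum() / tot))

    radii_px, prof = _radial_profile(img, center)
    r_mm = radii_px * setup.chip_pixel_pitch_um / 1000.0
    kt_axis = kt_from_radius(r_mm, setup)

    baseline = float(np.median(prof))
    noise = float(np.median(np.abs(prof - baseline))) + 1e-30
    peaks, props = signal.find_peaks(prof, prominence=5.0 * noise)

    if peaks.size == 0:
        # a disk pattern peaks at the innermost bin, which find_peaks cannot
        # flag; accept it if it clearly dominates the background
        if prof[0] >= prof.max() - 5.0 * noise and prof[0] - baseline > 5.0 * noise:
            half = prof[0] - 0.5 * (prof[0] - baseline)
            below = np.nonzero(prof < half)[0]
            edge = int(below[0]) if below.size else prof.size - 1
            kt_edge = float(
                np.interp(half, [prof[edge], prof[edge - 1]],
                          [kt_axis[edge], kt_axis[edge - 1]])
                if edge > 0 else kt_axis[0]
            )
            return RingMeasurement(
                theta_deg=theta_deg,
                kt_peak=float(kt_axis[0]),
                kt_half_prominence_width=2.0 * kt_edge,
                wavelength_nm=setup.wavelength_nm,
            )
        raise ValueError("no radial peak with prominence above the noise floor")

    best = peaks[np.argmax(props["prominences"])]
    widths, _, left_ips, right_ips = signal.peak_widths(
        prof, [best], rel_height=0.5
    )
    bins = np.arange(prof.size, dtype=float)
    kt_left = float(np.interp(left_ips[0], bins, kt_axis))
    kt_right = float(np.interp(right_ips[0], bins, kt_axis))
    return RingMeasurement(
        theta_deg=theta_deg,
        kt_peak=float(kt_axis[best]),
        kt_half_prominence_width=kt_right - kt_left,
        wavelength_nm=setup.wavelength_nm,
    )


def kt_curve(measurements: list[RingMeasurement]) -> pd.DataFrame:
    """Tabulate k_t(theta) +/- Delta k_t(theta), with model deviation.

    Returns a DataFrame sorted by input angle with columns ``theta_deg``,
    ``kt_peak``, ``kt_width``, ``kt_model`` (``(2 pi / lambda) sin(theta)``)
    and ``model_deviation`` (relative).  Duplicate angles are kept with a
    warning.
    """
    if len(measurements) < 2:
        raise ValueError("need measurements at >= 2 input angles")
    theta = np.array([m.theta_deg for m in measurements])
    if np.unique(theta).size < theta.size:
        warnings.warn("duplicate input angles in k_t curve; keeping both",
                      stacklevel=2)
    rows = sorted(measurements, key=lambda m: m.theta_deg)
    df = pd.DataFrame(
        {
            "theta_deg": [m.theta_deg for m in rows],
            "kt_peak": [m.kt_peak for m in rows],
            "kt_width": [m.kt_half_prominence_width for m in rows],
        }
    )
    lam = rows[0].wavelength_nm
    df["kt_model"] = 2.0 * np.pi / lam * np.sin(np.radians(df["theta_deg"]))
    with np.errstate(divide="ignore", invalid="ignore"):
        df["model_deviation"] = np.where(
            df["kt_model"] > 0,
            (df["kt_peak"] - df["kt_model"]) / df["kt_model"],
            np.nan,
        )
    return df
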