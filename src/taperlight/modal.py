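"""Closed-form waveguide model of a linearly tapered multimode fiber.

A tapered fiber (TF) narrows from its entrance diameter ``a0`` down to a
sub-micrometre tip.  As the local diameter ``a(z)`` shrinks, the transverse
propagation constant of every guided mode grows like ``k_t(a) = (a0/a)
k_t(a0)`` until it violates the guiding condition ``k_t < k_t,max = (2*pi /
lambda) NA`` and the mode is radiated through the taper surface.  Modes
injected with larger ``k_t`` (larger input angle) therefore out-couple at
larger diameters, i.e. farther from the tip — the mode-division
demultiplexing principle this package models.

All lengths are micrometres unless a name says otherwise; transverse
wavevectors are nm^-1 and angles are degrees at the API boundary (converted
to radians internally in exactly one place each).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "FiberSpec",
    "ModeEstimate",
    "DesignResult",
    "PRESETS",
    "kt_at_diameter",
    "kt_max",
    "mode_count",
    "cutoff_diameter",
    "kt_of_input_angle",
    "emission_length",
    "alpha_from_measurement",
    "design_report",
]

#: nm per um, used when mixing the two length units.
NM_PER_UM = 1e3


@dataclass(frozen=True)
class FiberSpec:
    """Physical description of a tapered fiber plus operating wavelength.

    Parameters
    ----------
    core_um, clad_um:
        Core and cladding diameters at the taper entrance, in um.
    na:
        Nominal numerical aperture.
    n_core, n_clad:
        Refractive indices of core and cladding.  When both are given they
        must be consistent with ``na`` (within 5%), since
        ``NA = sqrt(n_core**2 - n_clad**2)``.
    taper_angle_deg:
        Full apex angle ``psi`` of the (cladding) taper cone, degrees.
    wavelength_nm:
        Vacuum wavelength of the injected light, nm.
    """

    core_um: float
    clad_um: float
    na: float
    n_core: float | None = None
    n_clad: float | None = None
    taper_angle_deg: float = 3.7
    wavelength_nm: float = 473.0
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not 0 < self.core_um <= self.clad_um:
            raise ValueError(
                f"need 0 < core_um <= clad_um, got {self.core_um}/{self.clad_um}"
            )
        if not 0 < self.taper_angle_deg < 90:
            raise ValueError(f"taper_angle_deg out of (0, 90): {self.taper_angle_deg}")
        if self.wavelength_nm <= 0:
            raise ValueError(f"wavelength_nm must be positive: {self.wavelength_nm}")
        if self.na <= 0:
            raise ValueError(f"numerical aperture must be positive: {self.na}")
        if self.n_core is not None:
            if self.na >= self.n_core:
                raise ValueError("NA must be smaller than the core index")
            if self.n_clad is not None:
                na_idx = math.sqrt(self.n_core**2 - self.n_clad**2)
                if abs(na_idx - self.na) / self.na >= 0.05:
                    raise ValueError(
                        f"indices give NA={na_idx:.4f}, inconsistent with na={self.na}"
                    )

    # -- derived quantities -------------------------------------------------

    @property
    def half_angle_rad(self) -> float:
        """Taper half-angle psi/2 in radians (the single deg->rad boundary)."""
        return math.radians(self.taper_angle_deg) / 2.0

    @property
    def kt_max_inv_nm(self) -> float:
        return kt_max(self.wavelength_nm, self.na)

    @property
    def acceptance_angle_deg(self) -> float:
        """External half-acceptance angle asin(NA), degrees (launch from air)."""
        if self.na >= 1.0:
            return 90.0
        return math.degrees(math.asin(self.na))

    def mode_count_entrance(self) -> float:
        return mode_count(self.core_um, self.na, self.wavelength_nm)

    def taper_length_um(self, tip_um: float = 0.0) -> float:
        """Axial length of the taper from tip (diameter ``tip_um``) to entrance."""
        return (self.clad_um - tip_um) / (2.0 * math.tan(self.half_angle_rad))

    def diameter_at(self, z_um: float) -> float:
        """Local cladding diameter at axial distance ``z_um`` from the tip."""
        return 2.0 * z_um * math.tan(self.half_angle_rad)

    def to_dict(self) -> dict:
        d = {
            "core_um": self.core_um,
            "clad_um": self.clad_um,
            "na": self.na,
            "taper_angle_deg": self.taper_angle_deg,
            "wavelength_nm": self.wavelength_nm,
        }
        if self.n_core is not None:
            d["n_core"] = self.n_core
        if self.n_clad is not None:
            d["n_clad"] = self.n_clad
        return d


@dataclass(frozen=True)
class ModeEstimate:
    """Guided-mode census at one taper section."""

    diameter_um: float
    mode_count: float
    kt_max: float  # nm^-1

    def __post_init__(self) -> None:
        if self.mode_count < 0 or self.kt_max <= 0:
            raise ValueError("mode_count must be >= 0 and kt_max > 0")


@dataclass(frozen=True)
class DesignResult:
    """Outcome of the emission-length design rule EL = alpha*FED / (2 tan(psi/2))."""

    fed_um: float
    el_um: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.fed_um > 0 and self.el_um > 0):
            raise ValueError("fed_um and el_um must be positive")
        if not 0 < self.alpha <= 1.05:
            raise ValueError(f"alpha out of (0, 1.05]: {self.alpha}")


# -- bundled presets (entrance geometry per manufacturer nominal values) ----

#: The three fiber types characterized experimentally.  The 0.66 NA indices
#: are borosilicate core / cladding; the silica-core presets derive the
#: cladding index from the nominal NA.
PRESETS: Mapping[str, FiberSpec] = {
    "NA022": FiberSpec(
        core_um=50.0, clad_um=125.0, na=0.22,
        n_core=1.4630, n_clad=1.44636, name="NA022",
    ),
    "NA039": FiberSpec(
        core_um=200.0, clad_um=225.0, na=0.39,
        n_core=1.4630, n_clad=1.41006, name="NA039",
    ),
    "NA066": FiberSpec(
        core_um=200.0, clad_um=230.0, na=0.66,
        n_core=1.63, n_clad=1.49, name="NA066",
    ),
}


# -- operations -------------------------------------------------------------

def kt_at_diameter(kt_entrance: float, diameter_entrance_um: float,
                   diameter_um: float) -> float:
    """Transverse propagation constant after the taper narrows.

    ``k_t(a) = k_t(a0) * a0 / a`` — the product ``k_t * a`` is an adiabatic
    invariant of the narrowing waveguide.
    """
    if kt_entrance <= 0 or diameter_entrance_um <= 0 or diameter_um <= 0:
        raise ValueError("kt and diameters must be positive")
    if diameter_um > diameter_entrance_um:
        raise ValueError(
            f"diameter {diameter_um} exceeds entrance diameter {diameter_entrance_um}"
        )
    return kt_entrance * diameter_entrance_um / diameter_um


def kt_max(wavelength_nm: float, numerical_aperture: float) -> float:
    """Largest guided transverse wavevector, ``(2 pi / lambda) NA``, nm^-1.

    ``numerical_aperture = 0`` is allowed and returns 0 (no guided modes).
    """
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive: {wavelength_nm}")
    if numerical_aperture < 0:
        raise ValueError(f"NA must be non-negative: {numerical_aperture}")
    return 2.0 * math.pi / wavelength_nm * numerical_aperture


def mode_count(diameter_um: float, numerical_aperture: float,
               wavelength_nm: float) -> float:
    """Approximate number of guided modes ``M = (1/2) [(pi/lambda) a NA]**2``.

    Returned as a real number; the estimate is asymptotic, not a census of
    discrete modes.  ``diameter_um = 0`` gives 0.
    """
    if diameter_um < 0 or numerical_aperture < 0:
        raise ValueError("diameter and NA must be non-negative")
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive: {wavelength_nm}")
    v = math.pi / wavelength_nm * (diameter_um * NM_PER_UM) * numerical_aperture
    return 0.5 * v * v


def cutoff_diameter(kt_entrance: float, diameter_entrance_um: float,
                    kt_maximum: float) -> float:
    """Taper diameter at which a mode injected with ``kt_entrance`` is cut off.

    From ``k_t(a) = k_t(a0) a0/a = k_t,max``:  ``a_c = a0 * k_t(a0)/k_t,max``.
    A mode with ``kt_entrance = 0`` is guided all the way to the tip (returns 0).
    """
    if kt_entrance < 0:
        raise ValueError(f"kt_entrance must be non-negative: {kt_entrance}")
    if diameter_entrance_um <= 0 or kt_maximum <= 0:
        raise ValueError("entrance diameter and kt_max must be positive")
    if kt_entrance > kt_maximum:
        raise ValueError(
            f"kt_entrance {kt_entrance:.4g} exceeds kt_max {kt_maximum:.4g}: "
            "mode is not guided at the entrance"
        )
    return diameter_entrance_um * kt_entrance / kt_maximum


def kt_of_input_angle(theta_deg: float, wavelength_nm: float,
                      spec: FiberSpec | None = None) -> float:
    """Transverse wavevector injected by external input angle ``theta``.

    The transverse wavevector is invariant under refraction at the flat
    entrance facet, so launching from air at angle ``theta`` injects
    ``k_t = (2 pi / lambda) sin(theta)`` independent of the fiber indices.
    If a :class:`FiberSpec` is supplied and ``theta`` exceeds its acceptance
    angle ``asin(NA)``, a warning is emitted (the light is injected but lost
    early in practice).
    """
    if not 0 <= theta_deg < 90:
        raise ValueError(f"theta_deg out of [0, 90): {theta_deg}")
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive: {wavelength_nm}")
    if spec is not None and theta_deg >= spec.acceptance_angle_deg:
        warnings.warn(
            f"input angle {theta_deg} deg is beyond the NA={spec.na} acceptance "
            f"({spec.acceptance_angle_deg:.1f} deg)",
            stacklevel=2,
        )
    return 2.0 * math.pi / wavelength_nm * math.sin(math.radians(theta_deg))


def emission_length(fed_um: float, taper_angle_deg: float,
                    alpha: float = 1.0) -> float:
    """Emission length from the design rule ``EL = alpha FED / (2 tan(psi/2))``.

    ``FED / (2 tan(psi/2))`` is the axial distance from the (ideal) tip to the
    taper section of diameter FED; ``alpha`` is the empirical ratio between
    the measured EL and that distance.
    """
    if fed_um <= 0:
        raise ValueError(f"fed_um must be positive: {fed_um}")
    if not 0 < taper_angle_deg < 90:
        raise ValueError(f"taper_angle_deg out of (0, 90): {taper_angle_deg}")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive: {alpha}")
    return alpha * fed_um / (2.0 * math.tan(math.radians(taper_angle_deg) / 2.0))


def alpha_from_measurement(el_um: float, fed_um: float,
                           taper_angle_deg: float) -> float:
    """Scale factor ``alpha = EL * 2 tan(psi/2) / FED`` (inverse of the design rule)."""
    if el_um <= 0 or fed_um <= 0:
        raise ValueError("el_um and fed_um must be positive")
    if not 0 < taper_angle_deg < 90:
        raise ValueError(f"taper_angle_deg out of (0, 90): {taper_angle_deg}")
    return el_um * 2.0 * math.tan(math.radians(taper_angle_deg) / 2.0) / fed_um


def design_report(spec: FiberSpec, fed_um: float, alpha: float = 1.0,
                  psi_grid_deg: tuple[float, ...] | None = None) -> dict:
    """Design summary: entrance mode count, kt_max and an EL-vs-psi table.

    The default taper-angle grid covers 2-8 degrees, the range over which
    these tapers are routinely fabricated.
    """
    if psi_grid_deg is None:
        psi_grid_deg = tuple(2.0 + 0.5 * i for i in range(13))  # 2..8 deg
    table = [
        {"taper_angle_deg": psi, "el_um": emission_length(fed_um, psi, alpha)}
        for psi in psi_grid_deg
    ]
    return {
        "spec": spec.to_dict(),
        "mode_count_entrance": spec.mode_count_entrance(),
        "kt_max_inv_nm": spec.kt_max_inv_nm,
        "fed_um": fed_um,
        "alpha": alpha,
        "el_vs_taper_angle": table,
        "design": DesignResult(
            fed_um=fed_um,
            el_um=emission_length(fed_um, spec.taper_angle_deg, alpha),
            alpha=alpha,
        ),
    }
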