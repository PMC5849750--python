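# Methods

`taperlight` models light delivery from tapered multimode optical fibers
(TFs), the probes used to illuminate extended or angle-addressable volumes
of brain tissue in optogenetic experiments. This note records the models,
the numerical choices, and the limits of what the tests demonstrate.

## Waveguide model (`taperlight.modal`)

A TF guides light in a core/cladding pair that narrows linearly from the
entrance diameter `a0` to a sub-micrometre tip with full apex angle `psi`.
Three asymptotic relations govern its emission:

1. **Transverse-wavevector scaling.** As the local diameter `a(z)`
   shrinks, each guided mode's transverse propagation constant grows as
   `k_t(a) = k_t(a0) * a0 / a` — the product `k_t * a` is an adiabatic
   invariant of the narrowing guide.
2. **Cutoff.** Guidance requires `k_t < k_t,max = (2*pi/lambda) * NA`.
   Where scaling pushes a mode past `k_t,max` it is radiated through the
   taper surface. A mode injected with `k_t(a0)` therefore out-couples at
   the diameter `a_c = a0 * k_t(a0) / k_t,max`: larger injected `k_t`
   (larger input angle) emits farther from the tip. This is the
   mode-division demultiplexing principle.
3. **Mode census.** The number of guided modes at diameter `a` is
   `M = (1/2) * [(pi/lambda) * a * NA]^2`, returned as a real number (the
   estimate is asymptotic, so no rounding is imposed).

An external input angle `theta` injects `k_t = (2*pi/lambda) * sin(theta)`
regardless of the fiber indices, because the transverse wavevector is
invariant under refraction at the flat entrance facet.

The **emission-length design rule** relates the full-NA emission length to
the first emission diameter (FED): `EL = alpha * FED / (2 tan(psi/2))`,
where `FED/(2 tan(psi/2))` is the axial distance from the ideal tip to the
FED section and `alpha` (~0.87 for the characterized fibers) absorbs the
difference between the emission-onset and the half-intensity definitions.
Angles live in degrees at every API boundary and are converted to radians
exactly once per function; lengths are um and `k_t` is nm^-1 throughout.

Three presets bundle the characterized fiber types: 50/125 um 0.22 NA,
200/225 um 0.39 NA (silica core, cladding index derived from the nominal
NA), and 200/230 um 0.66 NA with n_core = 1.63, n_clad = 1.49
(borosilicate). The published `alpha`, `EL`, `FED` and `psi` values close
to ~2% only for the 0.66 NA fiber; for 0.22 NA the printed quantities are
mutually inconsistent at `psi = 3.7 deg` (back-computing `alpha` from EL
and FED gives 0.57, not the printed 0.88 — the per-fiber taper angles
behind the published summary are not stated), so only the 0.66 NA closure
is asserted in tests.

## Ray tracer (`taperlight.raytrace`)

The geometric model is the one commercial sequential ray tracers use for
these probes: nested core/cladding cylinders (default 50 mm straight
segment) followed by two cones sharing a common vertex, truncated by a
flat tip facet (default 1 um cladding diameter — a perfect vertex is
numerically singular and real tips are not perfect), immersed in a bath of
index 1.335 (phosphate-buffered saline with fluorescein/eosin;
configurable). With this bath the cladding/bath numerical aperture
(sqrt(1.49^2 - 1.335^2) = 0.66) essentially coincides with the fiber NA,
so light leaving the core is briefly re-guided by the cladding before
escaping — the tracer captures this, and it is why emission occurs closer
to the tip than the bare core-cutoff estimate.

**Fresnel splitting.** At every ray/surface intersection the unpolarized
Fresnel reflectance `R` is computed; the reflected branch continues with
power `w*R` and the transmitted branch with `w*(1-R)` (total internal
reflection gives `R = 1` and no branch). Branches stop below a power
cutoff (1e-4 of a launched ray) or after 200 interface events. Every unit
of power is bookkept — escaped through the taper surface or tip, escaped
back through the entrance, culled, or stopped — and the global audit
closes to ~1e-13 relative; runs fail if more than 0.1% of power loses a
surface intersection. Partial transmission near the critical angle, not
binary TIR, is what sets the axial width of the emission band.

**Source model.** The angle-scanned launch system focuses a collimated
beam onto the patch-fiber facet, so what enters the fiber is a small
on-axis spot with the convergence cone of the coupling lens around the
tilt angle. Rays through an on-axis point carry (near-)zero skewness, so
the injected subsets are quasi-meridional. The default source is
therefore `focused`: a 5 um spot, directions uniform over a cone of
half-angle 4 deg about the tilt (a centimetre-scale beam on an f = 32 mm
lens; this width also reproduces the measured ~550 um emission-band FWHM
and the width of the measured injected-k_t subsets). Each ray is
refracted at the facet individually, preserving its own transverse
wavevector. A `collimated` model (tilted plane wave filling the core,
maximally skew rays) and a `meridional` restriction (tilt-plane only) are
options; the collimated launch yields a markedly shallower
centroid-vs-angle slope (~45 um/deg vs ~52 um/deg focused and ~58 um/deg
measured), which is the main sensitivity of the simulation.

**Transport and performance.** Within the straight segment every wall
reflection of within-acceptance light is total, so transport through it is
evaluated in closed form as a circular billiard (constant chord length and
rotation per bounce) instead of event-by-event; beyond-acceptance rays are
left to the tracer. The taper itself is traced in a compiled (numba)
kernel with an explicit per-ray branch stack — the Fresnel cascade
generates roughly 10^3 events and ~250 escaping branches per launched ray,
which rules out materializing per-branch histories at production ray
counts. Escapes are either returned as records (`trace`) or binned on the
fly into the detector grid (`simulate_emission_profile`), keeping memory
flat at any ray count. Tracing is exactly reproducible for a fixed seed.

**Detection.** The detector is a 6000 x 41 pixel plane in close proximity
(50 um normal offset) of the taper surface along its full length — i.e.
parallel to the cone generator, tilted by `psi/2` relative to the axis —
emulating the fluorescence profile line drawn just outside the taper in
the characterization images. Escaping branches propagate in straight
lines through the bath to this plane; grazing exits land a little
tipward of their escape point, as they do in the real measurement
geometry. The axial profile is the transverse (column) sum.

**First core exit.** The kernel also records where each branch first
crosses from core to cladding, weighted by transmitted power. The
centroid of these "cutoff" positions is the geometric counterpart of the
modal cutoff condition; for a meridional source it matches the closed
form `a0 sin(theta) / (2 NA tan(psi/2))` within a few percent, which is
the oracle used to validate the tracer against the waveguide model.

Desk-scale defaults: 2e5 rays per angle (the study-scale 5e6 is a
parameter away), ~20-40 s per angle on one core; an 11-angle sweep of the
0.66 NA preset completes in ~4 minutes.

## Emission analysis (`taperlight.analysis`)

Profiles are 1D intensity vs distance-from-tip `z` (um), sampled from
images along a line parallel to the taper surface (bilinear
interpolation, configurable perpendicular offset, default 3 px outside
the glass) or produced by the simulator. All threshold crossings use
linear interpolation between samples, making FED and EL invariant under
uniform intensity rescaling.

* **FED** (full-NA injection): threshold `T` = half the mean of samples
  brighter than 90% of the maximum; walking from the entrance toward the
  tip, the FED is the local taper diameter `2 z* tan(psi/2)` at the first
  crossing above `T`.
* **EL**: largest `z` at which intensity is still at least half the
  intensity at the smallest `z`. A profile that never halves returns
  `max(z)` with a flag rather than an error.
* **Emission region** (angle-selective injection): after subtracting the
  median of the lowest-decile intensities (micrographs carry background;
  subtraction is skippable), the contiguous region around the global
  maximum above half-maximum is delimited by interpolated crossings; the
  centroid is the intensity-weighted mean `z` restricted to that region
  (robust against secondary scatter bands). `touches_tip` is set when the
  lower bound is within one pixel of the first sample.
* **Demultiplexing fit**: ordinary least squares of centroid on input
  angle, restricted to `theta >= 10 deg` (the linear regime) and to
  regions not touching the tip (the tip breaks the band symmetry);
  excluded points are counted and audited. The FWHM bound tracks are
  fitted alongside.
* **Power density**: assuming rotational symmetry, slice power is
  proportional to profile intensity, the lateral slice area is
  `pi a(z) dz / cos(psi/2)` with `a(z) = 2 z tan(psi/2)`, and
  `p = dP/dA` integrates back to the supplied total output power by
  construction (checked to 0.1%). Note the pointwise density varies like
  `1/a(z)` for a uniform profile; the frustum closed form
  `P / (pi (d1+d2)/2 * slant)` is its area-weighted mean.

No smoothing is applied by default; `EmissionProfile.smoothed(window)`
exposes a moving average used when analysing Monte-Carlo profiles (the
sweep analyses use a 101-sample window, ~60 um at the default detector
pitch, well below the ~500 um band width).

## Far field (`taperlight.farfield`)

Imaging the fiber facet's far field through a 4.5 mm objective and a
40/100 mm relay maps `k_t` to a chip radius
`r = 11.25 mm * tan(asin(lambda k_t / 2 pi))`. The analysis azimuthally
averages the image about the (auto-refined) center in one-pixel radial
bins, converts radii to `k_t`, takes the most prominent peak and measures
its width at half prominence (`scipy.signal.peak_widths`,
`rel_height=0.5`) mapped through the nonlinear radius-to-`k_t` axis. A
disk pattern (normal injection) peaks at the innermost bin and is handled
as a special case with a doubled one-sided width. The forward and inverse
mappings invert each other to 1e-12 relative over the propagating domain.

## Synthetic fixtures (`taperlight.fixtures`)

Every analysis operation is validated against data with known truth:

* **Full-NA profiles** are piecewise linear: a tip ramp crossing half the
  tip intensity exactly at the requested EL, a shallow shoulder meeting
  the FED detection threshold exactly at the FED position, and a steep
  onset. Requires `EL < z_FED` (alpha < 1), which holds for all
  characterized fibers. Noise is additive Gaussian as a fraction of peak.
  A structural note: because the FED threshold is at least 0.45 of the
  profile maximum and everything beyond the EL must stay below half the
  tip intensity, any profile consistent with both definitions confines
  its shoulder within 5% of peak of the EL half-level. Per-sample noise
  of comparable size (5% of peak) therefore makes the largest-z
  half-crossing land near the FED position, and no estimator faithful to
  the stated definitions can recover EL to 2% at that noise level; EL
  recovery is clean at <=1% noise, and FED recovery (steep onset) holds
  to ~0.3% even at 5% noise.
* **Demultiplexing sweeps** are Gaussian bands of constant FWHM with
  centroid `slope * theta + intercept` (optional Gaussian centroid
  jitter), truncated at the tip for small angles to exercise the
  exclusion rule.
* **Micrograph look-alikes** render a dark taper wedge plus a
  surface-hugging band with Gaussian axial and transverse cross-sections,
  Poisson shot noise and Gaussian read noise; the stored truth includes
  the surface line and the offset to feed the profile extractor.
* **Far-field rings** are Gaussian annuli at the mapped radius; the
  default fixture camera uses a 13 um effective pitch (2x2-binned sCMOS)
  so rings up to the 0.66 NA acceptance fit a 2048^2 chip.

All generators are deterministic under a fixed seed and return their truth
records. What fixture tests demonstrate is estimator correctness, not
instrument realism: real micrographs add speckle, surface irregularities
(visible as reduced tip quality under electron microscopy), tissue
scattering, and chromatic launch effects that these idealized shapes
deliberately omit. In particular the absolute published EL/FED values and
the brain-slice measurements are reachable only through parameter
recovery on fixtures, not by regeneration.

## Known limitations

* Pure geometric optics: no diffraction, interference, speckle, or
  polarization; no absorption or scattering in the glass; linear taper
  profiles only.
* The simulated demultiplexing slope depends on the launch skewness
  distribution (focused vs collimated source) at the ~15% level; the
  divergence half-angle of the launch cone is a physical estimate, not a
  measured value.
* Differential modal attenuation and the excitation efficiency of a
  Gaussian beam across modes are not modeled; the empirical `alpha`
  factor absorbs part of this in the design rule.
* The power-density map assumes rotational symmetry of the emission, as
  in the published analysis; azimuthally structured emission would need a
  2D surface map.
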