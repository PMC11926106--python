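"""Synthetic inputs with known ground truth for every analysis stage.

Raw microscopy data for this kind of study are rarely deposited, so each
analysis stage is validated by parameter recovery on simulated inputs that
carry the statistical structure the stage assumes:

* hyperspectral vesicle cross-sections: ring-shaped masks whose pixels mix
  two Gaussian reference spectra at a known fraction f, with Poisson photon
  noise;
* vesicle-condensate contour sets: three circular arcs constructed from a
  closed tension triangle so the ground-truth angles and geometric factor
  are exact, with Gaussian positional noise;
* condensate drift tracks: uniform drift at the velocity implied by a known
  zeta-potential plus 2-D Brownian motion.

Every generator is deterministic given (parameters, seed) and returns its
ground truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .electrokinetics import DriftTrack, MediumParams, velocity_from_zeta
from .phasor import SpectrumStack
from .wetting import ContourSet, GeometryError, tension_triangle_angles

__all__ = [
    "SpectralComponent",
    "SyntheticTruth",
    "GEL_COMPONENT",
    "FLUID_COMPONENT",
    "DEFAULT_MEDIUM",
    "default_wavelengths",
    "make_reference_spectra",
    "simulate_hsi_vesicle",
    "simulate_wetting_geometry",
    "simulate_drift_track",
]

#: Acquisition range and channel count of a typical spectral-detector scan.
LAMBDA_MIN = 416.0
LAMBDA_MAX = 728.0
N_CHANNELS = 32


@dataclass(frozen=True)
class SpectralComponent:
    """A pure-species emission spectrum modelled as a Gaussian profile."""

    center_nm: float
    sigma_nm: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise ValueError("spectral width must be > 0")


# Default pure-membrane references.  A gel-phase membrane shows a blue,
# narrow emission and a fluid (liquid-disordered) membrane a red-shifted,
# broader one; the ~50 nm separation of the centres reproduces the spectral
# shift between the most ordered and most fluid phospholipid bilayers.
GEL_COMPONENT = SpectralComponent(center_nm=440.0, sigma_nm=25.0)
FLUID_COMPONENT = SpectralComponent(center_nm=490.0, sigma_nm=35.0)

# Plausible droplet/electrolyte parameters for a protein condensate in a
# physiological-salinity buffer: condensate viscosity a few Pa s, water-like
# external viscosity, Debye length ~0.8 nm (150 mM 1:1 salt), 5 um droplet.
DEFAULT_MEDIUM = MediumParams(eta_c=3.0, eta_e=1.0e-3, kappa=1.27e9, R=5.0e-6,
                              eps_r=78.4)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters and the seed that generated an artefact."""

    kind: str
    params: dict[str, Any]
    seed: int | None = None


def default_wavelengths(n_channels: int = N_CHANNELS, lambda_min: float = LAMBDA_MIN,
                        lambda_max: float = LAMBDA_MAX) -> np.ndarray:
    """Channel-centre wavelengths of equal-bandwidth spectral channels."""
    bw = (lambda_max - lambda_min) / n_channels
    return lambda_min + bw * (np.arange(n_channels) + 0.5)


def make_reference_spectra(component_a: SpectralComponent, component_b: SpectralComponent,
                           wavelengths: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalised discrete spectra of two pure components.

    Gaussian profiles sampled at the channel centres, each normalised to
    unit summed intensity so that mixing weights are intensity fractions.
    """
    wl = np.asarray(wavelengths, dtype=float)
    out = []
    for comp in (component_a, component_b):
        spec = comp.amplitude * np.exp(-0.5 * ((wl - comp.center_nm) / comp.sigma_nm) ** 2)
        total = spec.sum()
        if total <= 0:
            raise ValueError("reference spectrum has zero intensity on the channel grid")
        out.append(spec / total)
    return out[0], out[1]


def simulate_hsi_vesicle(f: float, shape: tuple[int, int] = (64, 64),
                         ring_radius_px: float = 20.0, ring_width_px: float = 2.0,
                         photons_per_pixel: float = 1.0e4,
                         seed: int | None = None,
                         gel: SpectralComponent = GEL_COMPONENT,
                         fluid: SpectralComponent = FLUID_COMPONENT,
                         wavelengths: np.ndarray | None = None,
                         lambda_min: float = LAMBDA_MIN, lambda_max: float = LAMBDA_MAX,
                         background_photons: float = 0.0,
                         poisson_noise: bool = True) -> tuple[SpectrumStack, SyntheticTruth]:
    """Hyperspectral stack of one vesicle equatorial cross-section.

    Membrane pixels form a ring (|r - ring_radius| < ring_width) centred in
    the image; each carries the spectrum f * fluid + (1 - f) * gel scaled to
    ``photons_per_pixel`` total counts, with Poisson noise per channel.
    Off-ring pixels carry ``background_photons`` expected counts.  Because
    the references are unit-normalised, f is both the molar and the
    intensity fraction, so the pixel phasor sits at fraction f along the
    gel-to-fluid trajectory.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("mixing fraction f must be in [0, 1]")
    if photons_per_pixel <= 0:
        raise ValueError("photons_per_pixel must be > 0")
    if wavelengths is None:
        wavelengths = default_wavelengths(lambda_min=lambda_min, lambda_max=lambda_max)
    spec_gel, spec_fluid = make_reference_spectra(gel, fluid, wavelengths)
    mix = f * spec_fluid + (1.0 - f) * spec_gel

    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    r = np.hypot(xx - (cols - 1) / 2.0, yy - (rows - 1) / 2.0)
    ring = np.abs(r - ring_radius_px) < ring_width_px
    if not ring.any():
        raise ValueError("ring mask is empty; enlarge the image or shrink the ring")

    expected = np.full((rows, cols, wavelengths.size), background_photons / wavelengths.size)
    expected[ring] = photons_per_pixel * mix
    if poisson_noise:
        rng = np.random.default_rng(seed)
        intensities = rng.poisson(expected).astype(float)
    else:
        intensities = expected
    stack = SpectrumStack(intensities=intensities, wavelengths=wavelengths,
                          lambda_min=lambda_min, lambda_max=lambda_max)
    truth = SyntheticTruth(kind="hsi_vesicle", seed=seed, params={
        "f": f, "photons_per_pixel": photons_per_pixel,
        "n_ring_pixels": int(ring.sum()),
        "gel_center_nm": gel.center_nm, "fluid_center_nm": fluid.center_nm,
    })
    return stack, truth


# ---------------------------------------------------------------------------
# wetting geometry


def _arc_points(a: float, psi: float, start: np.ndarray, end: np.ndarray,
                n_points: int) -> np.ndarray:
    """Sample the circular arc through (+-a, 0) leaving ``start`` along ray psi.

    The circle centre lies on the y axis at h = a * cot(psi); an exactly
    tangent-horizontal ray (|h| infinite) degenerates to the straight chord.
    """
    s = math.sin(psi)
    if abs(s) < 1e-12:
        h = math.inf
    else:
        h = a * math.cos(psi) / s
    if not math.isfinite(h) or 1.0 / math.hypot(a, h) < 1e-12:
        t = np.linspace(0.0, 1.0, n_points)[:, None]
        return start + t * (end - start)
    r = math.hypot(a, h)
    phi1 = math.atan2(start[1] - h, start[0])
    phi2 = math.atan2(end[1] - h, end[0])
    # traversal sense from the into-arc tangent: ccw iff cross(radial, t) > 0
    tvec = np.array([math.cos(psi), math.sin(psi)])
    radial = np.array([start[0], start[1] - h])
    ccw = radial[0] * tvec[1] - radial[1] * tvec[0] > 0
    if ccw:
        while phi2 <= phi1:
            phi2 += 2.0 * math.pi
    else:
        while phi2 >= phi1:
            phi2 -= 2.0 * math.pi
    phis = np.linspace(phi1, phi2, n_points)
    return np.column_stack([r * np.cos(phis), h + r * np.sin(phis)])


def simulate_wetting_geometry(sigma_ce: float, W: float, sigma_mean: float,
                              vesicle_radius: float = 10.0, pixel_size: float = 0.1,
                              noise_sigma: float = 0.0, n_points_per_arc: int = 200,
                              seed: int | None = None,
                              contact_ratio: float | None = None,
                              flat_ic: bool = False,
                              image_id: str = "synthetic",
                              ) -> tuple[ContourSet, SyntheticTruth]:
    """Contour set of a vesicle-condensate cross-section with exact truth.

    The tension triple (Sigma_ce, Sigma_mean -/+ W/2) fixes the apparent
    angles through the closed tension triangle; three circular arcs are then
    constructed meeting at two contact points (+-a, 0) with exactly those
    sector angles, the vesicle arc having radius ``vesicle_radius`` (um).
    ``contact_ratio`` (contact-ring radius / vesicle radius) is the one
    remaining shape degree of freedom; by default it is chosen adaptively,
    c = sin(clip(theta_e / 2, 5 deg, 65 deg)), which keeps the condensate
    cap well conditioned over the whole valid angle domain.  ``flat_ic``
    instead picks c = sin(theta_i) (possible for theta_i > 90 deg), the one
    geometry in which the membrane-condensate interface is exactly flat and
    is emitted as a straight chord.  Contour points get isotropic Gaussian
    noise of ``noise_sigma`` pixels (times ``pixel_size`` um/pixel).

    Requires |W| < Sigma_ce and a tension triple satisfying the strict
    triangle inequality; the ground truth records the angles, Phi = W /
    Sigma_ce and the intrinsic angle.
    """
    if abs(W) >= sigma_ce:
        raise GeometryError("|W| must be < sigma_ce (affinity contrast bound)")
    sigma_ie = sigma_mean - 0.5 * W
    sigma_ic = sigma_mean + 0.5 * W
    angles = tension_triangle_angles(sigma_ce, sigma_ie, sigma_ic)
    theta_i, theta_e, theta_c = (math.radians(v) for v in angles.as_tuple())

    if flat_ic:
        if contact_ratio is not None:
            raise GeometryError("flat_ic chooses the contact ratio itself")
        if not math.pi / 2 < theta_i < math.pi:
            raise GeometryError("a flat ic interface requires theta_i in (90, 180) deg")
        contact_ratio = math.sin(theta_i)
    if contact_ratio is None:
        contact_ratio = math.sin(min(math.radians(65.0),
                                     max(math.radians(5.0), 0.5 * theta_e)))
    if not 0.0 < contact_ratio < 1.0:
        raise GeometryError("contact_ratio must be in (0, 1)")

    R = vesicle_radius
    a = contact_ratio * R
    h_ie = -math.sqrt(R**2 - a**2)  # vesicle centre below the contact chord
    psi_ie = math.atan2(-a, -h_ie)  # into-arc ray: under the vesicle bottom
    psi_ic = psi_ie - theta_i  # interior sector spans ic -> ie (ccw)
    psi_ce = psi_ic - theta_c  # condensate sector spans ce -> ic (ccw)

    p_right = np.array([a, 0.0])
    p_left = np.array([-a, 0.0])
    arcs = {
        "ie": _arc_points(a, psi_ie, p_right, p_left, n_points_per_arc),
        "ic": _arc_points(a, psi_ic, p_right, p_left, n_points_per_arc),
        "ce": _arc_points(a, psi_ce, p_right, p_left, n_points_per_arc),
    }
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        for key in arcs:
            arcs[key] = arcs[key] + rng.normal(0.0, noise_sigma * pixel_size,
                                               size=arcs[key].shape)

    contours = ContourSet(arc_ie=arcs["ie"], arc_ic=arcs["ic"], arc_ce=arcs["ce"],
                          pixel_size=pixel_size, image_id=image_id)
    phi = W / sigma_ce
    truth = SyntheticTruth(kind="wetting_geometry", seed=seed, params={
        "sigma_ce": sigma_ce, "W": W, "sigma_mean": sigma_mean,
        "sigma_ie": sigma_ie, "sigma_ic": sigma_ic,
        "theta_i": angles.theta_i, "theta_e": angles.theta_e, "theta_c": angles.theta_c,
        "phi": phi, "theta_e_in": math.degrees(math.acos(phi)),
        "contact_ratio": contact_ratio, "vesicle_radius": vesicle_radius,
    })
    return contours, truth


def simulate_drift_track(zeta: float, params: MediumParams = DEFAULT_MEDIUM,
                         E: float = 1.0e3, D: float = 0.05,
                         duration: float = 1000.0, dt: float = 1.0,
                         seed: int | None = None,
                         field_axis: tuple[float, float] = (1.0, 0.0),
                         start: tuple[float, float] = (0.0, 0.0),
                         track_id: str = "synthetic",
                         ) -> tuple[DriftTrack, SyntheticTruth]:
    """Condensate trajectory: uniform drift at the zeta-implied velocity
    plus 2-D Brownian motion.

    zeta in volts, E in V/m, D (diffusivity) in um^2/s, duration and dt in
    seconds.  The drift velocity follows from the inverse of the modified
    Smoluchowski relation; Brownian steps are independent Gaussian
    increments of variance 2 D dt per coordinate.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need dt > 0 and duration >= dt")
    nu = velocity_from_zeta(zeta, params, E)  # m/s
    nu_um = nu * 1.0e6
    axis = np.asarray(field_axis, dtype=float)
    axis = axis / np.hypot(*axis)

    n_steps = int(round(duration / dt))
    times = dt * np.arange(n_steps + 1)
    positions = np.asarray(start, dtype=float) + nu_um * times[:, None] * axis
    if D > 0:
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, math.sqrt(2.0 * D * dt), size=(n_steps, 2))
        positions[1:] += np.cumsum(steps, axis=0)

    track = DriftTrack(times=times, positions=positions, field_magnitude=E,
                       field_axis=(float(axis[0]), float(axis[1])), track_id=track_id)
    truth = SyntheticTruth(kind="drift_track", seed=seed, params={
        "zeta": zeta, "zeta_mV": zeta * 1e3, "nu": nu, "E": E, "D": D,
        "duration": duration, "dt": dt,
    })
    return track, truth
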