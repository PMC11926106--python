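"""Condensate zeta-potential from electrophoretic drift under a DC field.

A condensate droplet in a uniform field E drifts at a velocity nu set by its
surface (zeta) potential.  Because condensates are liquid droplets rather
than rigid colloids, the classical Smoluchowski relation is modified to

    zeta = 3 eta_c nu / (eps0 eps_r E) * 1 / (3 eta_e + kappa R)

with eta_c the condensate viscosity, eta_e the external solution viscosity,
kappa the inverse Debye length, R the droplet radius, and eps0, eps_r the
vacuum and relative permittivities.

Unit convention: the bracketed sum (3 eta_e + kappa R) adds the numeric SI
values of a viscosity (Pa s) and the dimensionless product kappa*R, exactly
as the relation is conventionally written.  All inputs must therefore be
given in SI units (Pa s, 1/m, m, F/m, V/m, m/s); the forward and inverse
maps here share the convention, so round trips are exact.  zeta is returned
in volts (multiply by 1e3 for mV).

Drift velocities are estimated as the least-squares slope of the trajectory
projected onto the field axis, which is robust to the Brownian motion
superimposed on the drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DriftTrack",
    "MediumParams",
    "DriftFit",
    "fit_drift",
    "drift_velocity",
    "zeta_potential",
    "velocity_from_zeta",
]

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m


class ElectrokineticsError(ValueError):
    """Raised for invalid tracks or medium parameters."""


@dataclass(frozen=True)
class DriftTrack:
    """A time-stamped 2-D condensate trajectory under a known field.

    times in seconds (strictly increasing), positions in micrometres of
    shape (n, 2), field magnitude in V/m, field axis a unit 2-vector.
    """

    times: np.ndarray
    positions: np.ndarray
    field_magnitude: float
    field_axis: tuple[float, float] = (1.0, 0.0)
    track_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        xy = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", xy)
        if t.ndim != 1 or t.size < 2:
            raise ElectrokineticsError("need at least 2 time points")
        if np.any(np.diff(t) <= 0):
            raise ElectrokineticsError("times must be strictly increasing (no duplicates)")
        if xy.shape != (t.size, 2):
            raise ElectrokineticsError("positions must be (n, 2) matching times")
        ax = np.asarray(self.field_axis, dtype=float)
        nrm = float(np.hypot(*ax))
        if not np.isclose(nrm, 1.0, atol=1e-6):
            raise ElectrokineticsError("field_axis must be a unit vector")
        object.__setattr__(self, "field_axis", (float(ax[0]), float(ax[1])))


@dataclass(frozen=True)
class MediumParams:
    """Material parameters of the droplet and surrounding electrolyte (SI).

    eta_c: condensate viscosity (Pa s); eta_e: external solution viscosity
    (Pa s); kappa: inverse Debye length (1/m); R: condensate radius (m);
    eps0: vacuum permittivity (F/m); eps_r: relative permittivity of the
    external solution.
    """

    eta_c: float
    eta_e: float
    kappa: float
    R: float
    eps_r: float
    eps0: float = VACUUM_PERMITTIVITY

    def __post_init__(self) -> None:
        for name in ("eta_c", "eta_e", "kappa", "R", "eps_r", "eps0"):
            if getattr(self, name) <= 0:
                raise ElectrokineticsError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class DriftFit:
    """Least-squares drift fit diagnostics."""

    velocity: float  # m/s, signed along the field axis
    stderr: float  # m/s
    intercept: float  # um
    r_squared: float


def fit_drift(track: DriftTrack) -> DriftFit:
    """Drift velocity from the projected trajectory (least-squares slope).

    Positions are projected onto the field axis; the slope of projected
    position versus time (um/s) is converted to m/s.  The sign is positive
    for motion along the axis.
    """
    proj = track.positions @ np.asarray(track.field_axis)
    res = stats.linregress(track.times, proj)
    return DriftFit(
        velocity=float(res.slope) * 1e-6,
        stderr=float(res.stderr) * 1e-6,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def drift_velocity(track: DriftTrack) -> float:
    """Signed drift velocity nu in m/s (see :func:`fit_drift`)."""
    return fit_drift(track).velocity


def zeta_potential(nu: float, params: MediumParams, E: float) -> float:
    """zeta (volts) from drift velocity nu (m/s) and field E (V/m).

    Implements the liquid-droplet-modified Smoluchowski relation (see module
    docstring for the unit convention of the 3*eta_e + kappa*R term).  The
    sign of zeta follows the sign of nu.
    """
    if E <= 0:
        raise ElectrokineticsError("field magnitude E must be > 0")
    return (3.0 * params.eta_c * nu / (params.eps0 * params.eps_r * E)
            / (3.0 * params.eta_e + params.kappa * params.R))


def velocity_from_zeta(zeta: float, params: MediumParams, E: float) -> float:
    """Exact algebraic inverse of :func:`zeta_potential`: nu in m/s."""
    if E <= 0:
        raise ElectrokineticsError("field magnitude E must be > 0")
    return (zeta * params.eps0 * params.eps_r * E
            * (3.0 * params.eta_e + params.kappa * params.R)
            / (3.0 * params.eta_c))
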