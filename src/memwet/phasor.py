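"""Spectral phasor analysis of hyperspectral membrane-dye image stacks.

Each pixel of a hyperspectral stack holds an emission spectrum I(lambda).
The spectral phasor transform maps that spectrum to a point (G, S) in the
unit disc, the first-harmonic Fourier coefficients of the spectrum over the
acquisition range::

    G = sum_k I_k cos(2 pi n (lambda_k - lambda_min) / (lambda_max - lambda_min)) / sum_k I_k
    S = sum_k I_k sin(2 pi n (lambda_k - lambda_min) / (lambda_max - lambda_min)) / sum_k I_k

The phasor angle tracks the spectral centre of mass (solvatochromic shift,
i.e. lipid packing and hydration for LAURDAN) and the radius tracks spectral
width.  Because the transform is linear in intensity, a pixel containing a
mixture of two spectral species falls on the straight segment joining the
two pure-species phasors, at the position given by its fractional integrated
intensity.  The two-cursor analysis exploits this: pixels are projected onto
a linear trajectory between two endpoint phasors, giving a per-pixel
"fluidity fraction" in [0, 1] (1 = most fluid endpoint), summarised per
image by the centre of mass of the fraction histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "SpectrumStack",
    "PhasorConfig",
    "PhasorField",
    "Cursor",
    "TrajectoryAxis",
    "FractionHistogram",
    "spectrum_phasor",
    "compute_phasor",
    "classify_cursors",
    "project_fraction",
    "histogram_fractions",
    "center_of_mass",
]


class PhasorError(ValueError):
    """Raised for invalid spectral inputs or empty masks."""


@dataclass(frozen=True)
class SpectrumStack:
    """A hyperspectral image: per-pixel emission spectra.

    Parameters
    ----------
    intensities
        Array of shape (rows, cols, channels), photon-count scale, >= 0.
    wavelengths
        Channel-centre wavelengths in nm, strictly increasing, all inside
        [lambda_min, lambda_max].
    lambda_min, lambda_max
        Bounds of the acquisition range in nm.
    """

    intensities: np.ndarray
    wavelengths: np.ndarray
    lambda_min: float
    lambda_max: float

    def __post_init__(self) -> None:
        intens = np.asarray(self.intensities, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "intensities", intens)
        object.__setattr__(self, "wavelengths", wl)
        if intens.ndim != 3:
            raise PhasorError("intensities must be (rows, cols, channels)")
        if wl.ndim != 1 or wl.size != intens.shape[2]:
            raise PhasorError("wavelengths must match the channel axis")
        if wl.size < 2:
            raise PhasorError("need at least 2 spectral channels")
        if np.any(np.diff(wl) <= 0):
            raise PhasorError("wavelengths must be strictly increasing")
        if not (self.lambda_min < self.lambda_max):
            raise PhasorError("lambda_min must be < lambda_max")
        if wl[0] < self.lambda_min - 1e-9 or wl[-1] > self.lambda_max + 1e-9:
            raise PhasorError("channel centres must lie inside [lambda_min, lambda_max]")
        if np.any(intens < 0):
            raise PhasorError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def total_intensity(self) -> np.ndarray:
        """Per-pixel summed counts over the spectral axis."""
        return self.intensities.sum(axis=2)


@dataclass(frozen=True)
class PhasorConfig:
    """Transform settings.

    harmonic
        Number of trigonometric cycles fit in the wavelength range (n = 1
        is the standard choice for spectral phasors).
    intensity_threshold
        Minimum per-pixel summed intensity for inclusion.  ``None`` selects
        a threshold automatically with Otsu's method on the total-intensity
        image (background exclusion).
    """

    harmonic: int = 1
    intensity_threshold: float | None = None

    def __post_init__(self) -> None:
        if int(self.harmonic) < 1 or self.harmonic != int(self.harmonic):
            raise PhasorError("harmonic must be a positive integer")
        if self.intensity_threshold is not None and self.intensity_threshold < 0:
            raise PhasorError("intensity_threshold must be >= 0")


@dataclass(frozen=True)
class PhasorField:
    """Per-pixel phasor coordinates, with excluded pixels masked out.

    G and S are NaN wherever ``mask`` is False.
    """

    G: np.ndarray
    S: np.ndarray
    total_intensity: np.ndarray
    mask: np.ndarray
    harmonic: int = 1

    def points(self) -> np.ndarray:
        """(N, 2) array of (G, S) for included pixels, row-major order."""
        return np.column_stack([self.G[self.mask], self.S[self.mask]])

    @property
    def n_included(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class Cursor:
    """A circular selection region in the phasor plot."""

    center_G: float
    center_S: float
    radius: float
    label: str

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise PhasorError("cursor radius must be > 0")
        if self.center_G**2 + self.center_S**2 > 1.0 + 1e-12:
            raise PhasorError("cursor centre must lie within the unit circle")

    def contains(self, g: np.ndarray, s: np.ndarray) -> np.ndarray:
        return (g - self.center_G) ** 2 + (s - self.center_S) ** 2 <= self.radius**2


@dataclass(frozen=True)
class TrajectoryAxis:
    """Linear two-component trajectory between two phasor endpoints.

    ``endpoint_1`` is the high-fluidity end: pixels projecting there get
    fraction 1.  Endpoint placement is an analysis convention (the axis is
    usually anchored at the phasors of the pure reference spectra).
    """

    endpoint_0: tuple[float, float]
    endpoint_1: tuple[float, float]

    def __post_init__(self) -> None:
        p0 = np.asarray(self.endpoint_0, dtype=float)
        p1 = np.asarray(self.endpoint_1, dtype=float)
        if np.allclose(p0, p1):
            raise PhasorError("trajectory endpoints must be distinct")
        object.__setattr__(self, "endpoint_0", tuple(p0))
        object.__setattr__(self, "endpoint_1", tuple(p1))


@dataclass(frozen=True)
class FractionHistogram:
    """Normalised pixel distribution along the two-cursor trajectory."""

    bin_positions: np.ndarray  # bin centres, fractions in [0, 1]
    frequencies: np.ndarray  # sum to 1
    n_pixels: int

    def center_of_mass(self) -> float:
        return center_of_mass(self)


def _phases(wavelengths: np.ndarray, lambda_min: float, lambda_max: float,
            harmonic: int) -> np.ndarray:
    return 2.0 * np.pi * harmonic * (wavelengths - lambda_min) / (lambda_max - lambda_min)


def spectrum_phasor(spectrum: Sequence[float], wavelengths: Sequence[float],
                    lambda_min: float, lambda_max: float,
                    harmonic: int = 1) -> tuple[float, float]:
    """Phasor (G, S) of a single 1-D spectrum.

    Convenience for reference spectra and trajectory endpoints; identical
    arithmetic to :func:`compute_phasor`.
    """
    spec = np.asarray(spectrum, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    total = spec.sum()
    if total <= 0:
        raise PhasorError("spectrum has zero total intensity")
    ph = _phases(wl, lambda_min, lambda_max, harmonic)
    return float(spec @ np.cos(ph) / total), float(spec @ np.sin(ph) / total)


def compute_phasor(stack: SpectrumStack, config: PhasorConfig = PhasorConfig()) -> PhasorField:
    """Transform a hyperspectral stack to per-pixel phasor coordinates.

    Pixels whose summed intensity falls at or below the threshold are
    excluded from the mask and carry NaN coordinates.  With the default
    ``intensity_threshold=None`` the threshold is chosen by Otsu's method on
    the total-intensity image (falling back to "any signal" when the image
    has fewer than two distinct intensity levels).

    Raises
    ------
    PhasorError
        If no pixel lies above the threshold (e.g. an all-zero stack).
    """
    total = stack.total_intensity()
    thr = config.intensity_threshold
    if thr is None:
        finite = total[np.isfinite(total)]
        if finite.size and np.unique(finite).size >= 2:
            thr = float(threshold_otsu(finite))
        else:
            thr = 0.0
    mask = total > thr
    if not mask.any():
        raise PhasorError("no pixels above threshold")

    ph = _phases(stack.wavelengths, stack.lambda_min, stack.lambda_max, config.harmonic)
    num_g = stack.intensities @ np.cos(ph)
    num_s = stack.intensities @ np.sin(ph)
    G = np.full(total.shape, np.nan)
    S = np.full(total.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        G[mask] = num_g[mask] / total[mask]
        S[mask] = num_s[mask] / total[mask]
    return PhasorField(G=G, S=S, total_intensity=total, mask=mask,
                       harmonic=config.harmonic)


def classify_cursors(field: PhasorField, cursors: Sequence[Cursor]) -> np.ndarray:
    """Label each pixel with the first cursor containing its phasor.

    Cursor order is the tie-break for overlapping cursors (reciprocity
    principle: the label image paints the pixels whose spectra fall in each
    phasor-plot region).  Pixels outside every cursor, and masked-out
    pixels, are labelled ``"none"``.
    """
    if len(cursors) == 0:
        raise PhasorError("need at least one cursor")
    labels = np.full(field.G.shape, "none", dtype=object)
    unassigned = field.mask.copy()
    for cur in cursors:
        hit = unassigned & cur.contains(field.G, field.S)
        labels[hit] = cur.label
        unassigned &= ~hit
    return labels


def project_fraction(field: PhasorField, axis: TrajectoryAxis) -> np.ndarray:
    """Per-pixel fraction along the trajectory axis, clamped to [0, 1].

    The fraction is the scalar projection of (G, S) onto the segment from
    endpoint_0 to endpoint_1 divided by the segment length; displacement
    perpendicular to the axis (spectral features orthogonal to the
    two-component mixture) is discarded.  Masked pixels are NaN.
    """
    p0 = np.asarray(axis.endpoint_0)
    d = np.asarray(axis.endpoint_1) - p0
    denom = float(d @ d)
    frac = ((field.G - p0[0]) * d[0] + (field.S - p0[1]) * d[1]) / denom
    return np.clip(frac, 0.0, 1.0)


def histogram_fractions(fractions: np.ndarray, n_bins: int = 100) -> FractionHistogram:
    """Normalised histogram of pixel fractions over n_bins bins on [0, 1]."""
    vals = np.asarray(fractions, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise PhasorError("no included pixels to histogram")
    if n_bins < 1:
        raise PhasorError("n_bins must be >= 1")
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    freqs = counts / counts.sum()
    return FractionHistogram(bin_positions=centers, frequencies=freqs,
                             n_pixels=int(vals.size))


def center_of_mass(hist: FractionHistogram) -> float:
    """Centre of mass of the fraction histogram, CM = sum(F_i * i) / sum(F_i).

    i is the bin-centre fraction; CM is the per-image summary statistic of
    membrane fluidity (or dipolar relaxation) used for group comparisons.
    """
    fsum = hist.frequencies.sum()
    if fsum <= 0:
        raise PhasorError("empty histogram")
    return float((hist.frequencies * hist.bin_positions).sum() / fsum)
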