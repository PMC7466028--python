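"""Circular dichroism analysis: concentration-scaled difference spectra and
derivative melting temperatures.

The difference spectrum isolates the peptide contribution of a DNA-peptide
conjugate by subtracting the free-duplex spectrum after dividing each
spectrum by its sample concentration; an alpha-helix shows the
characteristic double minimum near 208/222 nm.  Melting is read at a fixed
wavelength (220 nm by default, where the helix signal dominates and the
peptide has no aromatic contribution): the trace is smoothed with a centered
moving average and T_m is the temperature of the extremal derivative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DataFormatError, ProfileError

Direction = Literal["heating", "cooling"]


@dataclass
class CDSpectrum:
    """Ellipticity (mdeg) vs wavelength (nm) at one temperature (Celsius)."""

    wavelength: np.ndarray
    ellipticity: np.ndarray
    temperature: float
    label: str = ""
    concentration: float | None = None  # mg/mL

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelength.shape != self.ellipticity.shape:
            raise DataFormatError("wavelength and ellipticity must match")
        if np.any(np.diff(self.wavelength) <= 0):
            raise DataFormatError("wavelength grid must be increasing")


@dataclass
class MeltTrace:
    """Ellipticity at a fixed wavelength vs temperature (Celsius)."""

    temperature: np.ndarray
    ellipticity: np.ndarray
    direction: Direction = "heating"
    wavelength: float = 220.0

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.temperature.shape != self.ellipticity.shape:
            raise DataFormatError("temperature and ellipticity must match")
        d = np.diff(self.temperature)
        if self.direction == "heating" and np.any(d <= 0):
            raise DataFormatError("heating trace must have increasing temperature")
        if self.direction == "cooling" and np.any(d >= 0):
            raise DataFormatError("cooling trace must have decreasing temperature")


@dataclass
class MeltFit:
    """Derivative melting-temperature result for one trace."""

    t_m: float  # Celsius
    window: int
    smoothed: np.ndarray
    derivative: np.ndarray
    temperature: np.ndarray
    no_transition: bool = False


def difference_spectrum(conjugate: CDSpectrum, reference: CDSpectrum) -> CDSpectrum:
    """Concentration-scaled difference (conjugate - reference).

    Both spectra are divided by their concentration (mg/mL) before
    subtraction; grids and temperatures must match exactly (no silent
    interpolation).
    """
    if conjugate.wavelength.shape != reference.wavelength.shape or np.any(
        conjugate.wavelength != reference.wavelength
    ):
        raise ProfileError("wavelength grids differ; refusing to interpolate")
    if conjugate.temperature != reference.temperature:
        raise ProfileError(
            f"temperatures differ: {conjugate.temperature} vs {reference.temperature}"
        )
    for s in (conjugate, reference):
        if not s.concentration or s.concentration <= 0:
            raise ProfileError(f"spectrum {s.label!r} lacks a positive concentration")
    diff = (
        conjugate.ellipticity / conjugate.concentration
        - reference.ellipticity / reference.concentration
    )
    return CDSpectrum(
        wavelength=conjugate.wavelength.copy(),
        ellipticity=diff,
        temperature=conjugate.temperature,
        label=f"difference({conjugate.label} - {reference.label})",
        concentration=None,
    )


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge points average over the truncated window."""
    if window < 3 or window % 2 == 0:
        raise ProfileError(f"window must be odd and >= 3, got {window}")
    y = np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty_like(y)
    for i in range(len(y)):
        lo = max(0, i - half)
        hi = min(len(y), i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


def tm_from_derivative(trace: MeltTrace, window: int = 5) -> MeltFit:
    """T_m from the extremal derivative of the smoothed melt trace.

    Centered moving-average smoothing, central-difference derivative;
    T_m is the temperature of maximal |d(ellipticity)/dT| with ties broken
    toward the lower temperature.  An extremum on the first or last point is
    flagged ``no_transition`` (no interior inflection found).
    """
    t, y = trace.temperature, trace.ellipticity
    if len(t) < 20:
        raise ProfileError(f"melt trace needs >= 20 points, got {len(t)}")
    if len(t) < window:
        raise ProfileError("fewer points than the smoothing window")
    smooth = moving_average(y, window)
    deriv = np.gradient(smooth, t)
    mag = np.abs(deriv)
    peak = float(mag.max())
    ties = np.flatnonzero(np.isclose(mag, peak, rtol=0.0, atol=1e-12 * max(peak, 1.0)))
    idx = int(ties[np.argmin(t[ties])])
    # No resolved transition when the extremum sits in the smoothing skirt
    # of a boundary, or when the derivative has no contrast against its
    # typical magnitude (a linear or flat trace).
    half = window // 2
    contrast = peak / max(float(np.median(mag)), 1e-300)
    no_transition = (
        idx <= half or idx >= len(t) - 1 - half or peak == 0.0 or contrast < 3.0
    )
    t_m = float(t[idx])
    if not no_transition:
        # quadratic refinement of the extremum to sub-grid resolution
        lo, hi = max(0, idx - 3), min(len(t), idx + 4)
        coef = np.polyfit(t[lo:hi], mag[lo:hi], 2)
        if coef[0] < 0:
            vertex = -coef[1] / (2.0 * coef[0])
            if t[lo] <= vertex <= t[hi - 1]:
                t_m = float(vertex)
    return MeltFit(
        t_m=t_m,
        window=window,
        smoothed=smooth,
        derivative=deriv,
        temperature=t,
        no_transition=no_transition,
    )


def reversibility(
    heating: MeltFit, cooling: MeltFit, tol: float = 1.5
) -> tuple[bool, float]:
    """Is melting reversible: |T_m,heat - T_m,cool| <= tol (inclusive).

    Returns ``(reversible, delta_t_m)`` with the signed hysteresis
    ``T_m,heat - T_m,cool`` in Celsius.
    """
    if heating.no_transition or cooling.no_transition:
        raise ProfileError("cannot assess reversibility without transitions")
    delta = heating.t_m - cooling.t_m
    return (abs(delta) <= tol, float(delta))
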