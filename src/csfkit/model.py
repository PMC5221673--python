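"""Truncated log-parabola model of the contrast sensitivity function (CSF).

The CSF describes threshold contrast sensitivity as a function of spatial
frequency.  On log-log axes (log10 sensitivity against log10 frequency) it is
well approximated by a downward parabola with an asymmetric plateau at low
frequencies.  The model used throughout this package is the four-parameter
truncated log parabola:

* ``peak_logcs`` -- log10 sensitivity at the peak of the curve (logCS),
* ``peak_sf``   -- spatial frequency of the peak (cycles/degree),
* ``bandwidth_oct`` -- full width of the parabola at half-maximum
  *sensitivity* (a drop of log10(2) in logCS), in octaves,
* ``truncation`` (delta) -- depth below the peak at which the low-frequency
  plateau sits (logCS).

Writing ``l = log10(f)``, ``l0 = log10(peak_sf)`` and
``w = bandwidth_oct * log10(2) / 2`` (the half-width at half height in log10
frequency units), the untruncated parabola is::

    S'(f) = peak_logcs - log10(2) * ((l - l0) / w)**2

and the full curve plateaus below the peak frequency::

    S(f) = S'(f)                                    for f >= peak_sf
    S(f) = max(S'(f), peak_logcs - truncation)      for f <  peak_sf

Sensitivities are stored and computed in log10 units throughout; decimal
sensitivity is available through the conversion helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "LOG2",
    "CSFParams",
    "FrequencySample",
    "evaluate_log_parabola",
    "evaluate_csf",
    "aulcsf",
    "high_sf_cutoff",
    "logcs_to_sensitivity",
    "sensitivity_to_logcs",
    "contrast_threshold_to_logcs",
]

#: log10(2): the logCS drop corresponding to half-maximum sensitivity.
LOG2 = math.log10(2.0)


@dataclass(frozen=True)
class CSFParams:
    """The four functional parameters of one truncated log-parabola CSF."""

    peak_logcs: float
    peak_sf: float
    bandwidth_oct: float
    truncation: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.peak_logcs):
            raise ValueError(f"peak_logcs must be finite, got {self.peak_logcs}")
        if not (self.peak_sf > 0):
            raise ValueError(f"peak_sf must be positive, got {self.peak_sf}")
        if not (self.bandwidth_oct > 0):
            raise ValueError(
                f"bandwidth_oct must be positive, got {self.bandwidth_oct}"
            )
        if not (self.truncation >= 0):
            raise ValueError(f"truncation must be >= 0, got {self.truncation}")

    @property
    def log_peak_sf(self) -> float:
        """log10 of the peak spatial frequency."""
        return math.log10(self.peak_sf)

    @property
    def half_width_log(self) -> float:
        """Half-width at half-maximum sensitivity in log10 frequency units."""
        return self.bandwidth_oct * LOG2 / 2.0

    @property
    def peak_sensitivity(self) -> float:
        """Decimal contrast sensitivity at the peak (1 / contrast threshold)."""
        return 10.0 ** self.peak_logcs

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.peak_logcs, self.peak_sf, self.bandwidth_oct, self.truncation)


class FrequencySample(NamedTuple):
    """One frequency-specific contrast sensitivity measurement."""

    sf: float
    log_cs: float


def logcs_to_sensitivity(log_cs):
    """Decimal contrast sensitivity from logCS."""
    return np.power(10.0, log_cs)


def sensitivity_to_logcs(sensitivity):
    """logCS from decimal contrast sensitivity."""
    return np.log10(sensitivity)


def contrast_threshold_to_logcs(threshold):
    """logCS from a contrast threshold expressed as a proportion (0, 1]."""
    return -np.log10(threshold)


def _check_sf(sf: np.ndarray) -> None:
    if np.any(~(sf > 0)):
        raise ValueError("spatial frequencies must be positive and finite")


def evaluate_log_parabola(params: CSFParams, sf):
    """Evaluate the untruncated log parabola S'(f) in logCS units.

    Symmetric about ``peak_sf`` on the log-frequency axis; scalar in,
    scalar out; array in, array out.
    """
    sf_arr = np.asarray(sf, dtype=float)
    _check_sf(sf_arr)
    rel = (np.log10(sf_arr) - params.log_peak_sf) / params.half_width_log
    out = params.peak_logcs - LOG2 * rel * rel
    return float(out) if np.isscalar(sf) or out.ndim == 0 else out


def evaluate_csf(params: CSFParams, sfs):
    """Evaluate the truncated log parabola S(f) at one or more frequencies.

    For ``f >= peak_sf`` this is the parabola itself; below the peak the
    curve never drops under the plateau ``peak_logcs - truncation``.
    """
    sf_arr = np.atleast_1d(np.asarray(sfs, dtype=float))
    _check_sf(sf_arr)
    parab = params.peak_logcs - LOG2 * (
        (np.log10(sf_arr) - params.log_peak_sf) / params.half_width_log
    ) ** 2
    plateau = params.peak_logcs - params.truncation
    out = np.where(sf_arr < params.peak_sf, np.maximum(parab, plateau), parab)
    return float(out[0]) if np.isscalar(sfs) or np.ndim(sfs) == 0 else out


def _plateau_edge(params: CSFParams) -> float:
    """log10 frequency below which the plateau replaces the parabola."""
    return params.log_peak_sf - params.half_width_log * math.sqrt(
        params.truncation / LOG2
    )


def aulcsf(params: CSFParams, sf_lo: float, sf_hi: float) -> float:
    """Area under the log CSF between two frequencies.

    Integrates ``max(S(f), 0)`` over log10 frequency from ``log10(sf_lo)`` to
    ``log10(sf_hi)``; portions of the curve below 0 logCS (contrast threshold
    above 100%) contribute nothing.  Computed in closed form from the
    piecewise plateau/parabola structure.  Units: logCS * log10(c/deg).
    """
    if not (0 < sf_lo < sf_hi):
        raise ValueError(
            f"require 0 < sf_lo < sf_hi, got sf_lo={sf_lo}, sf_hi={sf_hi}"
        )
    lo, hi = math.log10(sf_lo), math.log10(sf_hi)
    p, l0 = params.peak_logcs, params.log_peak_sf
    a = LOG2 / params.half_width_log**2  # curvature of p - a*(l-l0)^2
    plateau = p - params.truncation
    edge = _plateau_edge(params)

    # Breakpoints: the plateau/parabola seam and the parabola's zero
    # crossings.  Between consecutive breakpoints the integrand is either a
    # constant or a sign-definite quadratic.
    pts = [lo, hi]
    if lo < edge < hi:
        pts.append(edge)
    if p > 0:
        half = math.sqrt(p / a)
        for z in (l0 - half, l0 + half):
            if lo < z < hi:
                pts.append(z)
    pts.sort()

    total = 0.0
    for left, right in zip(pts[:-1], pts[1:]):
        mid = 0.5 * (left + right)
        if mid < edge:  # plateau segment
            if plateau > 0:
                total += plateau * (right - left)
        else:  # parabola segment
            val = p - a * (mid - l0) ** 2
            if val > 0:
                total += p * (right - left) - (a / 3.0) * (
                    (right - l0) ** 3 - (left - l0) ** 3
                )
    return total


def high_sf_cutoff(params: CSFParams) -> float:
    """Spatial frequency above the peak where the parabola crosses 0 logCS.

    This is the acuity-like limit where the contrast threshold reaches 100%.
    Closed form: ``log10(cutoff) = log10(peak_sf) + w * sqrt(peak_logcs /
    log10(2))`` with ``w`` the half-width at half height in log10 units.
    By convention a zero-height curve (``peak_logcs == 0``) returns
    ``peak_sf`` itself; a negative peak has no crossing and raises.
    """
    if params.peak_logcs < 0:
        raise ValueError(
            "high-SF cutoff undefined: peak_logcs < 0 (curve never reaches 0 logCS)"
        )
    if params.peak_logcs == 0:
        return params.peak_sf
    return 10.0 ** (
        params.log_peak_sf
        + params.half_width_log * math.sqrt(params.peak_logcs / LOG2)
    )


def samples_from_arrays(sfs: Sequence[float], log_cs: Sequence[float]) -> list[FrequencySample]:
    """Zip parallel frequency / logCS arrays into FrequencySample records."""
    sfs = list(sfs)
    log_cs = list(log_cs)
    if len(sfs) != len(log_cs):
        raise ValueError("sfs and log_cs must have equal length")
    return [FrequencySample(float(f), float(x)) for f, x in zip(sfs, log_cs)]
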