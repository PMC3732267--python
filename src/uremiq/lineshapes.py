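"""Lorentzian lineshape and first-order multiplet patterns.

The absorption-mode NMR peak is Lorentzian,

    L(d) = (2 A / pi) * w / (4 (d - c)^2 + w^2),

with centre ``c`` (ppm), full width at half maximum ``w`` (ppm) and total
area ``A`` (intensity * ppm); the analytic integral over the whole axis is
exactly ``A`` and the height at the mode is ``2 A / (pi w)``.

Scalar coupling splits a group's signal into a multiplet.  Weak (first
order) coupling gives binomial intensity ratios; the strongly coupled
two-spin AB case gives four lines with the classic "roofing" distortion,
computed from the shift difference ``delta_nu`` and the coupling ``J``.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import LibraryError
from .library import ResonanceGroup

__all__ = ["lorentzian_profile", "multiplet_pattern", "multiplet_profile"]

# (offset multiplier of J in Hz, relative weight) per first-order pattern
_FIRST_ORDER = {
    "singlet": ((0.0, 1.0),),
    "doublet": ((-0.5, 0.5), (0.5, 0.5)),
    "triplet": ((-1.0, 0.25), (0.0, 0.5), (1.0, 0.25)),
    "quartet": ((-1.5, 0.125), (-0.5, 0.375), (0.5, 0.375), (1.5, 0.125)),
}


def lorentzian_profile(
    center: float, fwhm: float, area: float, axis: np.ndarray
) -> np.ndarray:
    """Evaluate a unit-consistent Lorentzian on a ppm axis.

    Parameters are the peak centre (ppm), full width at half maximum (ppm)
    and integrated area (intensity * ppm).  ``area = 0`` yields a zero trace.
    """
    if fwhm <= 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    if area < 0:
        raise ValueError(f"area must be non-negative, got {area}")
    axis = np.asarray(axis, dtype=float)
    return (2.0 * area / math.pi) * fwhm / (4.0 * (axis - center) ** 2 + fwhm**2)


def ab_pattern(j_coupling: float, delta_nu: float) -> tuple[tuple[float, float], ...]:
    """Line offsets (Hz from the pattern centre) and weights of an AB system.

    With ``C = sqrt(delta_nu^2 + J^2) / 2`` the four transitions sit at
    ``+-(C - J/2)`` (inner) and ``+-(C + J/2)`` (outer); the inner pair is
    enhanced and the outer pair suppressed by the roofing factor
    ``1 -+ J / (2 C)``.  Weights are normalized to sum to 1.
    """
    if j_coupling <= 0:
        raise LibraryError("AB system requires a positive J coupling")
    c = 0.5 * math.hypot(delta_nu, j_coupling)
    inner_w = 1.0 + j_coupling / (2.0 * c)
    outer_w = 1.0 - j_coupling / (2.0 * c)
    total = 2.0 * (inner_w + outer_w)
    lines = (
        (-(c + 0.5 * j_coupling), outer_w / total),
        (-(c - 0.5 * j_coupling), inner_w / total),
        (+(c - 0.5 * j_coupling), inner_w / total),
        (+(c + 0.5 * j_coupling), outer_w / total),
    )
    return lines


def multiplet_pattern(group: ResonanceGroup) -> tuple[tuple[float, float], ...]:
    """Line offsets in Hz (relative to the multiplet centre) and area weights.

    Weights always sum to 1 so the multiplet's total area is preserved
    regardless of splitting.
    """
    if group.multiplicity == "AB_system":
        return ab_pattern(group.j_coupling, group.ab_delta_nu)
    try:
        pattern = _FIRST_ORDER[group.multiplicity]
    except KeyError:
        raise LibraryError(f"unknown multiplicity {group.multiplicity!r}") from None
    return tuple((mult * group.j_coupling, weight) for mult, weight in pattern)


def line_positions_ppm(
    group: ResonanceGroup, spectrometer_freq: float, center: float | None = None
) -> list[float]:
    """Absolute line positions of a multiplet in ppm at a given field."""
    c = group.center_shift if center is None else center
    return [c + off_hz / spectrometer_freq for off_hz, _ in multiplet_pattern(group)]


def multiplet_profile(
    axis: np.ndarray,
    group: ResonanceGroup,
    total_area: float,
    spectrometer_freq: float,
    fwhm: float,
    center: float | None = None,
) -> np.ndarray:
    """Sum of the Lorentzian lines of one multiplet on a ppm axis.

    ``total_area`` is distributed over the lines by the pattern weights; Hz
    offsets are converted to ppm via the spectrometer frequency (MHz).
    """
    c = group.center_shift if center is None else center
    trace = np.zeros_like(np.asarray(axis, dtype=float))
    for off_hz, weight in multiplet_pattern(group):
        trace += lorentzian_profile(
            c + off_hz / spectrometer_freq, fwhm, total_area * weight, axis
        )
    return trace
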