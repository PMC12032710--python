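"""Activation timing: full-width at half-maximum of temporal synergy profiles.

Profiles live on the 101-point time-normalized grid (one sample = 1 % of the
movement). The width of the main peak is measured between the half-maximum
crossings found by walking contiguously outward from the peak, with linear
interpolation between samples. Boundary synergies — peaks whose half-height is
never reached before the movement start or after the movement end — are
measured one-sided from/to the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class DegenerateProfileError(ValueError):
    pass


def find_main_peak(profile: np.ndarray) -> tuple[int, float]:
    """Global maximum of a nonnegative profile; ties take the earliest index."""
    p = np.asarray(profile, dtype=float)
    if not np.any(p > 0):
        raise DegenerateProfileError("profile is all-zero")
    idx = int(np.argmax(p))
    return idx, float(p[idx])


def half_max_crossings(
    profile: np.ndarray, peak_index: int | None = None
) -> tuple[float | None, float | None]:
    """Fractional sample positions where the profile crosses half maximum,
    walking outward from the main peak. ``None`` marks a missing crossing
    (boundary case)."""
    p = np.asarray(profile, dtype=float)
    if peak_index is None:
        peak_index, _ = find_main_peak(p)
    half = p[peak_index] / 2.0

    left = None
    for i in range(peak_index - 1, -1, -1):
        if p[i] < half:
            # crossing between i and i+1
            left = i + (half - p[i]) / (p[i + 1] - p[i])
            break
    right = None
    for i in range(peak_index + 1, len(p)):
        if p[i] < half:
            right = i - 1 + (p[i - 1] - half) / (p[i - 1] - p[i])
            break
    return left, right


@dataclass
class FWHMMeasure:
    synergy: str | int
    peak_index: int
    peak_value: float
    width: float          # % of the time-normalized trial (1 sample = 1 %)
    boundary: str         # 'none' | 'start' | 'end' | 'both'
    left_crossing: float | None
    right_crossing: float | None


def fwhm(profile: np.ndarray, synergy: str | int = 0) -> FWHMMeasure:
    """Full-width at half-maximum of the main peak, with the one-sided rule
    for boundary synergies."""
    p = np.asarray(profile, dtype=float)
    peak_index, peak_value = find_main_peak(p)
    left, right = half_max_crossings(p, peak_index)

    boundary = "none"
    lo = left
    hi = right
    if left is None and right is None:
        warnings.warn("profile never falls below half maximum; width set to 100")
        boundary = "both"
        lo, hi = 0.0, float(len(p) - 1)
    elif left is None:
        boundary = "start"
        lo = 0.0
    elif right is None:
        boundary = "end"
        hi = float(len(p) - 1)
    width = float(hi - lo)
    return FWHMMeasure(
        synergy=synergy,
        peak_index=peak_index,
        peak_value=peak_value,
        width=width,
        boundary=boundary,
        left_crossing=left,
        right_crossing=right,
    )


def fwhm_table(profiles: np.ndarray, names=None) -> list[FWHMMeasure]:
    """FWHM of every profile column of a (101, n) matrix."""
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[1]
    names = list(names) if names is not None else list(range(n))
    return [fwhm(profiles[:, j], names[j]) for j in range(n)]
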