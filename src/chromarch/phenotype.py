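"""Phenotype-level formulas: adipocyte volume and group change summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["adipocyte_volume", "group_change", "percent_of", "GroupChange"]


@dataclass
class GroupChange:
    """Fold and percent change of one group mean relative to another."""

    fold: float
    percent: float


def adipocyte_volume(diameters) -> float:
    """Mean adipocyte volume V = pi/6 * mean(D^3).

    Each diameter is the geometric mean of a cell's maximum and minimum
    diameter; the result is the mean of the per-cell sphere volumes.
    Scales cubically: adipocyte_volume(k * D) = k^3 * adipocyte_volume(D).
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one diameter")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    return float(math.pi / 6.0 * np.mean(d ** 3))


def group_change(mean_a: float, mean_b: float, ndigits: int = 2) -> GroupChange:
    """Fold (a/b) and percent (100*(a-b)/b) change of group a vs group b.

    Rounded half-to-even to ``ndigits`` decimals for reporting.
    """
    if mean_b <= 0:
        raise ValueError("reference mean must be positive")
    fold = mean_a / mean_b
    percent = 100.0 * (mean_a - mean_b) / mean_b
    return GroupChange(round(fold, ndigits), round(percent, ndigits))


def percent_of(part: float, whole: float, ndigits: int = 2) -> float:
    """Percentage a count represents of a total, rounded for reporting."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, ndigits)
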