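"""Insulation score, TAD boundary detection, aggregation and concordance.

The insulation score of a bin is the log2 ratio of the mean contact density
in a square window straddling the bin's diagonal position to the chromosome
mean; local minima mark TAD boundaries.  Boundary detection follows the
delta-vector convention: the delta at a bin is the mean insulation over the
left span minus the mean over the right span, boundaries sit at
positive-to-negative zero crossings, and are retained when the local delta
amplitude (max minus min across the crossing) reaches the noise threshold.

Replicate boundary sets are collapsed to a non-redundant list by a greedy
pick-strongest-then-exclude procedure (strongest = lowest group-mean
insulation), and per-center population frequencies are counted over a
+/- radius window.  Partition concordance offers the Jaccard index on
boundary sets, the measure of concordance (MoC) on base-pair overlaps, and
the variation of information (VI).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import ContactMatrix

__all__ = [
    "InsulationTrack",
    "BoundarySet",
    "insulation_score",
    "detect_boundaries",
    "aggregate_boundaries",
    "boundary_frequency",
    "domains_from_boundaries",
    "partition_concordance",
]


@dataclass
class InsulationTrack:
    """Normalized insulation score per bin (NaN where undefined)."""

    chrom: str
    bin_size: int
    is_value: np.ndarray
    window: int = 260_000

    def __post_init__(self) -> None:
        self.is_value = np.asarray(self.is_value, dtype=float)


@dataclass
class BoundarySet:
    """Boundary bin positions with strengths and insulation values."""

    chrom: str
    bin_size: int
    positions: np.ndarray  # bin indices, strictly increasing
    strength: np.ndarray   # delta amplitude at detection
    is_at_boundary: np.ndarray
    replicate: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.strength = np.asarray(self.strength, dtype=float)
        self.is_at_boundary = np.asarray(self.is_at_boundary, dtype=float)
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("boundary positions must be strictly increasing")

    def __len__(self) -> int:
        return self.positions.size


def insulation_score(m: ContactMatrix, window: int = 260_000) -> InsulationTrack:
    """Insulation score with a mean-aggregated off-diagonal square window.

    ``raw(i)`` is the mean of the matrix over ``[i-w, i-1] x [i+1, i+w]``
    (unmasked cells only, ``w = window / bin_size``); the reported value is
    ``log2(raw(i) / mean(raw))``.  Bins within ``w`` of a chromosome edge,
    masked bins, and bins with an empty or zero window are NaN.
    """
    if window % m.bin_size != 0:
        raise ValueError("window must be a multiple of the bin size")
    w = window // m.bin_size
    n = m.n_bins
    raw = np.full(n, np.nan)
    if n < 2 * w + 1:
        warnings.warn(f"{m.chrom}: chromosome shorter than 2*window+1 bins; "
                      "insulation undefined", stacklevel=2)
        return InsulationTrack(m.chrom, m.bin_size, raw, window)
    for i in range(w, n - w):
        if not m.mask[i]:
            continue
        block = m.values[i - w:i, i + 1:i + w + 1]
        vals = block[np.isfinite(block)]
        if vals.size:
            raw[i] = vals.mean()
    defined = np.isfinite(raw) & (raw > 0)
    track = np.full(n, np.nan)
    if defined.any():
        track[defined] = np.log2(raw[defined] / raw[defined].mean())
    return InsulationTrack(m.chrom, m.bin_size, track, window)


def _span_mean(values: np.ndarray, lo: int, hi: int) -> float:
    """NaN-aware mean of values[lo:hi]; NaN when the slice is empty/undefined."""
    if lo < 0 or hi > values.size or lo >= hi:
        return np.nan
    window = values[lo:hi]
    finite = window[np.isfinite(window)]
    return float(finite.mean()) if finite.size else np.nan


def detect_boundaries(track: InsulationTrack, delta_span: int = 200_000,
                      noise_threshold: float = 0.1,
                      replicate: str | None = None) -> BoundarySet:
    """Detect insulation minima via the delta-vector zero-crossing rule.

    ``delta(i)`` is the mean insulation over the left span minus the mean
    over the right span (``s = delta_span / bin_size`` bins each side).
    A boundary is emitted at each positive-to-negative crossing whose local
    amplitude (delta at the flanking maximum minus delta at the flanking
    minimum) reaches ``noise_threshold``; the boundary is placed on the
    minimum-insulation bin inside the crossing (boundary margin of error 0).
    """
    if delta_span % track.bin_size != 0:
        raise ValueError("delta_span must be a multiple of the bin size")
    s = delta_span // track.bin_size
    isv = track.is_value
    n = isv.size
    delta = np.full(n, np.nan)
    for i in range(n):
        if not np.isfinite(isv[i]):
            continue
        left = _span_mean(isv, i - s, i)
        right = _span_mean(isv, i + 1, i + 1 + s)
        if np.isfinite(left) and np.isfinite(right):
            delta[i] = left - right
    defined = np.flatnonzero(np.isfinite(delta))
    defined_set = set(defined.tolist())
    positions, strengths, is_at = [], [], []
    for a, b in zip(defined[:-1], defined[1:]):
        if not (delta[a] > 0 and delta[b] <= 0):
            continue
        # walk outwards to the flanking delta extrema of this crossing
        j = a
        while (j - 1) in defined_set and delta[j - 1] >= delta[j]:
            j -= 1
        left_peak = j
        k = b
        while k + 1 < n and np.isfinite(delta[k + 1]) and delta[k + 1] <= delta[k]:
            k += 1
        right_trough = k
        amplitude = delta[left_peak] - delta[right_trough]
        if amplitude < noise_threshold:
            continue
        segment = isv[left_peak:right_trough + 1]
        if not np.isfinite(segment).any():
            continue
        pos = left_peak + int(np.nanargmin(segment))
        if positions and pos <= positions[-1]:
            continue
        positions.append(pos)
        strengths.append(float(amplitude))
        is_at.append(float(isv[pos]))
    return BoundarySet(track.chrom, track.bin_size, np.array(positions, int),
                       np.array(strengths), np.array(is_at), replicate)


def aggregate_boundaries(boundary_sets: list[BoundarySet],
                         radius: int = 100_000) -> list[tuple[int, float]]:
    """Collapse replicate boundaries into a non-redundant center list.

    Insulation scores are first averaged per genomic bin across the
    replicates carrying a boundary there.  Candidates are then visited in
    ascending order of mean insulation (strongest boundary first, leftmost
    coordinate breaking ties); each emitted center removes every remaining
    candidate within ``+/- radius``.  Emitted centers are pairwise separated
    by more than ``radius``.

    Returns a list of ``(bin_position, group_mean_is)`` tuples in emission
    order.
    """
    if not boundary_sets:
        return []
    bin_size = boundary_sets[0].bin_size
    by_pos: dict[int, list[float]] = {}
    for bs in boundary_sets:
        if bs.bin_size != bin_size:
            raise ValueError("boundary sets must share a bin size")
        for pos, isv in zip(bs.positions, bs.is_at_boundary):
            by_pos.setdefault(int(pos), []).append(float(isv))
    candidates = sorted(((float(np.mean(vals)), pos)
                         for pos, vals in by_pos.items()))
    emitted: list[tuple[int, float]] = []
    removed: set[int] = set()
    radius_bins = radius / bin_size
    for mean_is, pos in candidates:
        if pos in removed:
            continue
        emitted.append((pos, mean_is))
        for _, other in candidates:
            if abs(other - pos) <= radius_bins:
                removed.add(other)
    return emitted


def boundary_frequency(centers: list[int] | np.ndarray,
                       replicate_sets: list[BoundarySet],
                       radius: int = 100_000,
                       high: float = 0.70, low: float = 0.30) -> "pd.DataFrame":
    """Per-center fraction of replicates with a boundary within +/- radius.

    Classes follow the printed TAD rule: high iff frequency >= ``high``,
    low iff frequency < ``low``, else medium.
    """
    import pandas as pd

    if not replicate_sets:
        raise ValueError("need at least one replicate")
    centers = np.asarray(centers, dtype=int)
    bin_size = replicate_sets[0].bin_size
    radius_bins = radius / bin_size
    counts = np.zeros(centers.size, dtype=int)
    for bs in replicate_sets:
        if bs.positions.size == 0:
            continue
        for ci, c in enumerate(centers):
            if np.any(np.abs(bs.positions - c) <= radius_bins):
                counts[ci] += 1
    freq = counts / len(replicate_sets)
    cls = np.full(freq.shape, "medium", dtype=object)
    cls[freq >= high] = "high"
    cls[freq < low] = "low"
    return pd.DataFrame({"center": centers, "frequency": freq,
                         "n_observed": counts, "class": cls})


def domains_from_boundaries(boundaries: np.ndarray, n_bins: int,
                            bin_size: int) -> list[tuple[int, int]]:
    """Inter-boundary intervals (bp, half-open) covering the chromosome."""
    edges = [0] + [int(b) * bin_size for b in sorted(boundaries)
                   if 0 < b < n_bins] + [n_bins * bin_size]
    edges = sorted(set(edges))
    return [(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _check_partition(p: list[tuple[int, int]], name: str) -> list[tuple[int, int]]:
    if not p:
        raise ValueError(f"{name} is empty")
    p = sorted(p)
    for (a1, b1), (a2, b2) in zip(p[:-1], p[1:]):
        if b1 != a2:
            raise ValueError(f"{name} does not tile the chromosome")
    if any(b <= a for a, b in p):
        raise ValueError(f"{name} contains empty intervals")
    return p


def partition_concordance(tads_a: list[tuple[int, int]],
                          tads_b: list[tuple[int, int]],
                          bin_size: int = 20_000) -> dict[str, float]:
    """Jaccard / MoC / VI concordance between two domain partitions.

    * Jaccard on internal boundary sets with a +/- 1 bin matching tolerance;
    * MoC = (sum_ij F_ij^2 / (|P_i| |Q_j|) - 1) / (sqrt(|P| |Q|) - 1) with
      F_ij the bp overlap (1 when both partitions are a single domain);
    * VI = H(P) + H(Q) - 2 I(P, Q) over the bp-mass joint overlap
      distribution, in bits.
    """
    tads_a = _check_partition(list(tads_a), "partition A")
    tads_b = _check_partition(list(tads_b), "partition B")
    if (tads_a[0][0], tads_a[-1][1]) != (tads_b[0][0], tads_b[-1][1]):
        raise ValueError("partitions must cover the same chromosome extent")

    # Jaccard on boundary sets with +/- 1 bin tolerance (greedy matching)
    bounds_a = [iv[1] for iv in tads_a[:-1]]
    bounds_b = [iv[1] for iv in tads_b[:-1]]
    matches = 0
    used = [False] * len(bounds_b)
    for ba in bounds_a:
        for i, bb in enumerate(bounds_b):
            if not used[i] and abs(ba - bb) <= bin_size:
                used[i] = True
                matches += 1
                break
    union = len(bounds_a) + len(bounds_b) - matches
    jaccard = matches / union if union else 1.0

    # bp overlap table
    total = tads_a[-1][1] - tads_a[0][0]
    overlaps: list[tuple[int, int, int]] = []
    for i, (a1, a2) in enumerate(tads_a):
        for j, (b1, b2) in enumerate(tads_b):
            ov = min(a2, b2) - max(a1, b1)
            if ov > 0:
                overlaps.append((i, j, ov))

    if len(tads_a) == 1 and len(tads_b) == 1:
        moc = 1.0
    else:
        acc = sum(ov * ov / ((a2 - a1) * (b2 - b1))
                  for i, j, ov in overlaps
                  for a1, a2 in [tads_a[i]] for b1, b2 in [tads_b[j]])
        moc = (acc - 1.0) / (math.sqrt(len(tads_a) * len(tads_b)) - 1.0)

    sizes_a = np.array([b - a for a, b in tads_a], float) / total
    sizes_b = np.array([b - a for a, b in tads_b], float) / total
    h_a = -float(np.sum(sizes_a * np.log2(sizes_a)))
    h_b = -float(np.sum(sizes_b * np.log2(sizes_b)))
    mi = 0.0
    for i, j, ov in overlaps:
        p_ij = ov / total
        mi += p_ij * math.log2(p_ij / (sizes_a[i] * sizes_b[j]))
    vi = max(0.0, h_a + h_b - 2.0 * mi)
    return {"jaccard": jaccard, "moc": moc, "vi": vi}
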