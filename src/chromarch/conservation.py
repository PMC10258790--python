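"""Cross-species enhancer conservation classes and SNP enrichment.

An enhancer on the reference genome is projected (lifted over) onto the
query genome; the mapped promoter-enhancer contact is ranked against all
query-genome pairs at the same genomic separation, giving a distance-
normalized percentile score (PS).  Classes:

* ``sequence-specific``   -- liftover failed;
* ``usage-conserved``     -- liftover succeeded and PS > 85;
* ``only-sequence-conserved`` -- liftover succeeded and PS <= 85.

SNP enrichment for a region class X is the SNP density in X relative to the
genome-wide density:  ``(N_xsnp / N_all) * (BN_all / BN_x)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConservationCall",
    "percentile_score",
    "stratified_percentile_scores",
    "classify_enhancer_conservation",
    "snp_enrichment",
]

logger = logging.getLogger(__name__)

PS_THRESHOLD = 85.0

SEQUENCE_SPECIFIC = "sequence-specific"
USAGE_CONSERVED = "usage-conserved"
ONLY_SEQUENCE_CONSERVED = "only-sequence-conserved"
UNCLASSIFIABLE = "unclassifiable"


@dataclass
class ConservationCall:
    """Liftover outcome, percentile score and conservation class."""

    liftover_ok: bool
    ps: float | None
    label: str


def percentile_score(contact: float, background: np.ndarray) -> float:
    """Percentile rank (mean rank for ties) of ``contact`` in ``background``.

    PS = 100 * rank / len(background), where rank counts strictly smaller
    background values plus the mean position among ties.  The stratum
    maximum scores 100.
    """
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("empty background stratum")
    less = int(np.sum(background < contact))
    equal = int(np.sum(background == contact))
    if equal:
        rank = less + (equal + 1) / 2.0
    else:
        # contact absent from the stratum: midpoint between neighbours
        rank = less + 0.5
    return 100.0 * rank / background.size


def _pool_strata(counts: pd.Series, min_size: int) -> dict[float, int]:
    """Assign each distance stratum to a pooled group of >= min_size pairs.

    Adjacent strata (in distance order) are accumulated until the pool
    reaches ``min_size``; a trailing undersized pool merges with its
    predecessor.
    """
    groups: dict[float, int] = {}
    gid = 0
    acc = 0
    members: list[float] = []
    for d, c in counts.sort_index().items():
        members.append(d)
        acc += int(c)
        if acc >= min_size:
            for m in members:
                groups[m] = gid
            gid += 1
            acc = 0
            members = []
    if members:
        target = gid - 1 if gid > 0 else 0
        for m in members:
            groups[m] = target
    return groups


def stratified_percentile_scores(queries: pd.DataFrame,
                                 background: pd.DataFrame,
                                 min_stratum: int = 20) -> np.ndarray:
    """PS per query contact within its exact-distance stratum.

    ``queries`` and ``background`` carry columns ``distance`` and
    ``contact``.  Strata with fewer than ``min_stratum`` background pairs are
    pooled with neighboring distances.  Queries whose distance has no
    background stratum get NaN (logged).
    """
    if background.empty:
        raise ValueError("empty background table")
    counts = background.groupby("distance").size()
    groups = _pool_strata(counts, min_stratum)
    bg_group = background["distance"].map(groups)
    pools = {g: background.loc[bg_group == g, "contact"].to_numpy()
             for g in set(groups.values())}
    known = np.array(sorted(groups))
    out = np.full(len(queries), np.nan)
    for k, (d, c) in enumerate(zip(queries["distance"], queries["contact"])):
        if d in groups:
            g = groups[d]
        else:
            nearest = known[np.abs(known - d).argmin()]
            g = groups[nearest]
        out[k] = percentile_score(float(c), pools[g])
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        logger.warning("%d queries had no percentile stratum", n_missing)
    return out


def classify_enhancer_conservation(liftover_ok, ps,
                                   ps_threshold: float = PS_THRESHOLD) -> np.ndarray:
    """Conservation class per enhancer.

    The PS threshold is strict: a score of exactly ``ps_threshold`` is
    only-sequence-conserved.  Lifted enhancers with a missing PS are
    ``unclassifiable`` (logged).
    """
    liftover_ok = np.asarray(liftover_ok, dtype=bool)
    ps = np.asarray(ps, dtype=float)
    if liftover_ok.shape != ps.shape:
        raise ValueError("liftover_ok and ps must be aligned")
    out = np.full(liftover_ok.shape, ONLY_SEQUENCE_CONSERVED, dtype=object)
    out[~liftover_ok] = SEQUENCE_SPECIFIC
    out[liftover_ok & (ps > ps_threshold)] = USAGE_CONSERVED
    missing = liftover_ok & ~np.isfinite(ps)
    if missing.any():
        logger.warning("%d lifted enhancers lack a percentile score",
                       int(missing.sum()))
        out[missing] = UNCLASSIFIABLE
    return out


def snp_enrichment(n_xsnp: float, n_all: float, bn_x: float,
                   bn_all: float) -> float:
    """SNP enrichment of a region class relative to genome-average density.

    ``(N_xsnp / N_all) * (BN_all / BN_x)``; 1.0 means genome-average SNP
    density.  Scale-invariant in the four counts.
    """
    for name, v in (("n_xsnp", n_xsnp), ("n_all", n_all),
                    ("bn_x", bn_x), ("bn_all", bn_all)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if n_all <= 0:
        raise ValueError("n_all must be positive")
    if bn_x <= 0:
        raise ValueError("bn_x must be positive")
    if n_xsnp > n_all or bn_x > bn_all:
        raise ValueError("class counts cannot exceed genome totals")
    return (n_xsnp / n_all) * (bn_all / bn_x)
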