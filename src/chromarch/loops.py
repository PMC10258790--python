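"""CTCF-loop filtering/merging, promoter-enhancer regulation, and RPS.

Loop calls arrive as BEDPE-like tables (``chrom, start1, end1, start2, end2,
q``) from an upstream significance caller; this module applies the retention
filters (q-value, CTCF anchors, span range) and collapses redundant calls by
the iterative odd/even-rank merging procedure.  Promoter-enhancer interaction
(PEI) tables carry a normalized interaction strength ``l_n`` (observed minus
expected contact frequency); a gene's regulatory potential score is

    RPS = sum_i log10(l_n_i)

over its retained enhancers with ``l_n > 0``.  Differential-RPS and
RPS-expression covariation rules, enhancer activity classes and expression
detection filters round out the regulatory layer.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "LOOP_COLUMNS",
    "filter_loops",
    "merge_loops",
    "filter_peis",
    "compute_rps",
    "classify_differential_rps",
    "covariation_genes",
    "classify_enhancer_activity",
    "filter_expressed_genes",
]

logger = logging.getLogger(__name__)

LOOP_COLUMNS = ["chrom", "start1", "end1", "start2", "end2", "q"]

_EXPRESSION_CUTOFFS = {"PCG": 0.5, "lncRNA": 0.1, "TUCP": 0.1}


def _loop_span(df: pd.DataFrame) -> pd.Series:
    mid1 = (df["start1"] + df["end1"]) / 2.0
    mid2 = (df["start2"] + df["end2"]) / 2.0
    return (mid2 - mid1).abs()


def _overlaps_any(chroms: pd.Series, starts: np.ndarray, ends: np.ndarray,
                  intervals: pd.DataFrame) -> np.ndarray:
    """Vectorized 'interval overlaps >=1 subject interval' test (half-open)."""
    out = np.zeros(len(chroms), dtype=bool)
    for chrom, sub in intervals.groupby("chrom"):
        sel = np.flatnonzero(chroms.to_numpy() == chrom)
        if sel.size == 0:
            continue
        sub = sub.sort_values("start")
        m_start = sub["start"].to_numpy()
        m_end_cummax = np.maximum.accumulate(sub["end"].to_numpy())
        idx = np.searchsorted(m_start, ends[sel], side="left")
        hit = (idx > 0) & (np.where(idx > 0, m_end_cummax[idx - 1], 0) > starts[sel])
        out[sel] = hit
    return out


def filter_loops(candidates: pd.DataFrame, ctcf_motifs: pd.DataFrame,
                 q_max: float = 0.01, min_span: int = 30_000,
                 max_span: int = 2_000_000) -> pd.DataFrame:
    """Retain loops with q < ``q_max``, both anchors on a CTCF motif, and an
    anchor-midpoint span within ``[min_span, max_span]``."""
    df = candidates.copy()
    span = _loop_span(df)
    keep = (df["q"] < q_max) & (span >= min_span) & (span <= max_span)
    keep &= _overlaps_any(df["chrom"], df["start1"].to_numpy(),
                          df["end1"].to_numpy(), ctcf_motifs)
    keep &= _overlaps_any(df["chrom"], df["start2"].to_numpy(),
                          df["end2"].to_numpy(), ctcf_motifs)
    return df[keep].reset_index(drop=True)


def _gap(s1: float, e1: float, s2: float, e2: float) -> float:
    """Gap between two intervals; 0 when they overlap or touch."""
    return max(0.0, max(s1, s2) - min(e1, e2))


def _adjacent(r1: tuple, r2: tuple, adjacency: float) -> bool:
    return (_gap(r1[1], r1[2], r2[1], r2[2]) <= adjacency
            and _gap(r1[3], r1[4], r2[3], r2[4]) <= adjacency)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def _merge_pass(records: list[tuple], adjacency: float,
                all_pairs: bool) -> list[tuple] | None:
    """One merging pass; returns the new loop list or None if nothing merged.

    ``all_pairs=False`` compares only odd-rank against even-rank loops after
    sorting by chromosome position; ``all_pairs=True`` compares every pair.
    """
    order = sorted(range(len(records)), key=lambda i: records[i][:5])
    uf = _UnionFind(len(records))
    merged_any = False
    for oi, i in enumerate(order):
        for oj in range(oi + 1, len(order)):
            j = order[oj]
            if not all_pairs and (oi % 2) == (oj % 2):
                continue
            if records[i][0] != records[j][0]:
                continue
            if _adjacent(records[i], records[j], adjacency):
                if uf.find(i) != uf.find(j):
                    uf.union(i, j)
                    merged_any = True
    if not merged_any:
        return None
    groups: dict[int, list[tuple]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(uf.find(i), []).append(rec)
    out = []
    for members in groups.values():
        chrom = members[0][0]
        s1 = min(m[1] for m in members)
        e1 = max(m[2] for m in members)
        s2 = min(m[3] for m in members)
        e2 = max(m[4] for m in members)
        q = min(m[5] for m in members)
        out.append((chrom, s1, e1, s2, e2, q))
    return out


def merge_loops(loops: pd.DataFrame, adjacency: int = 5_000,
                max_iter: int = 100) -> pd.DataFrame:
    """Iteratively merge redundant loops with near-identical anchor pairs.

    Loops are ranked by chromosome position and split into odd- and even-rank
    sets; cross-set loops whose corresponding anchors overlap or lie within
    ``adjacency`` are replaced by one loop with union anchors, and the
    procedure iterates on the result.  When an odd/even pass merges nothing,
    a final all-pairs sweep verifies the fixed point (so the output is the
    transitive closure of the adjacency relation).  Merged loops keep the
    smallest constituent q-value.
    """
    records = [tuple(r) for r in
               loops[LOOP_COLUMNS].itertuples(index=False, name=None)]
    for _ in range(max_iter):
        nxt = _merge_pass(records, adjacency, all_pairs=False)
        if nxt is None:
            nxt = _merge_pass(records, adjacency, all_pairs=True)
            if nxt is None:
                break
        records = nxt
    out = pd.DataFrame(records, columns=LOOP_COLUMNS)
    return out.sort_values(LOOP_COLUMNS[:5]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Promoter-enhancer regulation
# ---------------------------------------------------------------------------

def filter_peis(peis: pd.DataFrame, fdr_max: float = 0.001,
                min_distance: int = 40_000) -> pd.DataFrame:
    """High-confidence PEI retention: FDR < ``fdr_max`` and distance >=
    ``min_distance``."""
    keep = (peis["fdr"] < fdr_max) & (peis["distance"] >= min_distance)
    return peis[keep].reset_index(drop=True)


def compute_rps(peis: pd.DataFrame,
                genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene regulatory potential score and enhancer-count class.

    ``RPS = sum log10(l_n)`` over a gene's enhancers with ``l_n > 0``; rows
    with non-positive ``l_n`` are excluded (their count is logged) since the
    score is undefined there.  ``n`` is the retained enhancer count; genes
    with no retained enhancer have RPS 0 and class ``none``; class ``multi``
    iff n >= 2, ``single`` iff n == 1.

    Parameters
    ----------
    peis : DataFrame with columns ``gene`` and ``l_n`` (already filtered).
    genes : optional full gene universe, so enhancer-less genes appear with
        RPS 0.
    """
    usable = peis[peis["l_n"] > 0]
    n_dropped = len(peis) - len(usable)
    if n_dropped:
        logger.info("compute_rps: excluded %d PEI rows with l_n <= 0", n_dropped)
    grouped = usable.groupby("gene")["l_n"]
    rps = grouped.apply(lambda v: float(np.log10(v).sum()))
    counts = grouped.size()
    index = pd.Index(sorted(set(genes or []) | set(peis["gene"])), name="gene")
    out = pd.DataFrame(index=index)
    out["n"] = counts.reindex(index).fillna(0).astype(int)
    out["rps"] = rps.reindex(index).fillna(0.0)
    out["enhancer_class"] = np.select(
        [out["n"] >= 2, out["n"] == 1], ["multi", "single"], default="none")
    return out


def classify_differential_rps(rps_a: pd.Series, rps_b: pd.Series,
                              fc_min: float = 1.5,
                              delta_min: float = 2.0) -> pd.DataFrame:
    """Flag genes whose RPS differs between two conditions.

    Differential iff ``max(a,b)/min(a,b) > fc_min`` and ``|a-b| > delta_min``;
    when either score is <= 0 the ratio is undefined and only the absolute
    difference applies.  Symmetric under swapping the conditions.
    ``direction`` is the sign of ``b - a``.
    """
    genes = rps_a.index.union(rps_b.index)
    a = rps_a.reindex(genes).fillna(0.0)
    b = rps_b.reindex(genes).fillna(0.0)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    delta_ok = (hi - lo) > delta_min
    with np.errstate(divide="ignore", invalid="ignore"):
        fc_ok = np.where(lo > 0, hi / lo > fc_min, True)
    differential = delta_ok & fc_ok
    return pd.DataFrame({"differential": differential,
                         "direction": np.sign(b - a).astype(int)}, index=genes)


def covariation_genes(diff_rps: pd.DataFrame, deg_table: pd.DataFrame,
                      lfc_min: float = 1.0, fdr_max: float = 0.05) -> list[str]:
    """Genes whose RPS change and expression change agree.

    A gene is included iff its RPS is differential and it is a significant
    DEG (``|log2FC| > lfc_min`` and ``FDR < fdr_max``) with the same sign of
    change as the RPS direction.
    """
    deg = deg_table.set_index("gene") if "gene" in deg_table.columns else deg_table
    out = []
    for gene, row in diff_rps[diff_rps["differential"]].iterrows():
        if gene not in deg.index:
            continue
        lfc = float(deg.loc[gene, "log2fc"])
        fdr = float(deg.loc[gene, "fdr"])
        if abs(lfc) > lfc_min and fdr < fdr_max \
                and np.sign(lfc) == row["direction"] != 0:
            out.append(gene)
    return out


def classify_enhancer_activity(enhancers: pd.DataFrame,
                               high_peaks: pd.DataFrame,
                               moderate_peaks: pd.DataFrame) -> pd.Series:
    """Activity class per enhancer from peak-set overlap.

    ``highly-active`` iff the enhancer overlaps the high (super-enhancer)
    peak set; else ``moderately-active`` iff it overlaps the moderate
    (typical) set; else ``low-active``.
    """
    starts = enhancers["start"].to_numpy()
    ends = enhancers["end"].to_numpy()
    hi = _overlaps_any(enhancers["chrom"], starts, ends, high_peaks)
    mo = _overlaps_any(enhancers["chrom"], starts, ends, moderate_peaks)
    cls = np.select([hi, mo], ["highly-active", "moderately-active"],
                    default="low-active")
    return pd.Series(cls, index=enhancers.index, name="activity")


def filter_expressed_genes(expression: pd.DataFrame,
                           biotype: pd.Series) -> list[str]:
    """Detected genes under the biotype-specific TPM cutoffs.

    Protein-coding genes need > 0.5 TPM in at least one sample; lncRNA and
    TUCP transcripts need > 0.1 TPM.  Unknown biotypes are an input error.
    """
    unknown = set(biotype.unique()) - set(_EXPRESSION_CUTOFFS)
    if unknown:
        raise ValueError(f"unknown biotype(s): {sorted(unknown)}")
    max_tpm = expression.max(axis=1)
    detected = []
    for gene, mx in max_tpm.items():
        if gene not in biotype.index:
            raise ValueError(f"gene {gene!r} has no biotype annotation")
        if mx > _EXPRESSION_CUTOFFS[biotype[gene]]:
            detected.append(gene)
    return detected
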