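"""A/B compartment calling, the A-B index, and population-level classes.

Compartments are called at coarse (100-kb) resolution as the first principal
component of the Pearson correlation of the O/E matrix, sign-oriented so that
PC1 correlates positively with GC content (gene density as tie-breaker).
The A-B index refines the call to 20-kb bins as a bounded contrast ratio
``(S_A - S_B) / (S_A + S_B)`` of each bin's summed O/E contact with A- versus
B-labelled coarse bins, excluding near-diagonal pairs so distance decay does
not dominate.  Population summaries classify per-bin A-status frequency
across replicates and compare two groups for compartment switches and
variable bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ContactMatrix

__all__ = [
    "CompartmentProfile",
    "call_compartments_pc1",
    "compute_ab_index",
    "labels_from_values",
    "compartment_frequency",
    "classify_compartment_changes",
]

logger = logging.getLogger(__name__)

LABEL_A = 1
LABEL_B = -1
LABEL_NONE = 0


@dataclass
class CompartmentProfile:
    """Per-bin oriented PC1 values and A/B labels for one chromosome.

    ``labels`` uses +1 for A, -1 for B and 0 for unassigned bins.
    """

    chrom: str
    bin_size: int
    pc1: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.pc1 = np.asarray(self.pc1, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.pc1.shape != self.labels.shape:
            raise ValueError("pc1 and labels must be aligned")


def labels_from_values(values: np.ndarray) -> np.ndarray:
    """Sign-based A/B labels: +1 where > 0, -1 where < 0, 0 otherwise."""
    values = np.asarray(values, dtype=float)
    labels = np.zeros(values.shape, dtype=np.int8)
    labels[values > 0] = LABEL_A
    labels[values < 0] = LABEL_B
    return labels


def call_compartments_pc1(oe: ContactMatrix, gc: np.ndarray,
                          gene_density: np.ndarray | None = None,
                          min_bins: int = 10,
                          orientation_min_r: float = 0.1) -> CompartmentProfile:
    """Call A/B compartments from the PC1 of the O/E correlation matrix.

    Parameters
    ----------
    oe : ContactMatrix
        O/E-form matrix, typically at 100-kb resolution.
    gc : ndarray
        Per-bin GC content, aligned to the bins; primary orientation covariate.
    gene_density : ndarray, optional
        Per-bin gene count; orientation tie-breaker when the Spearman
        correlation of PC1 with GC is weaker than ``orientation_min_r``.
    min_bins : int
        Chromosomes with fewer unmasked bins are skipped with a warning
        (all-NaN profile).
    """
    if oe.form != "oe":
        raise ValueError("call_compartments_pc1 expects an O/E matrix")
    gc = np.asarray(gc, dtype=float)
    if gc.shape != (oe.n_bins,):
        raise ValueError("gc must be aligned to bins")
    valid = oe.mask & np.isfinite(np.nan_to_num(oe.values, nan=np.nan)).any(axis=1)
    pc1 = np.full(oe.n_bins, np.nan)
    if valid.sum() < min_bins:
        warnings.warn(
            f"{oe.chrom}: only {int(valid.sum())} unmasked bins (<{min_bins}); "
            "compartment call skipped", stacklevel=2)
        return CompartmentProfile(oe.chrom, oe.bin_size, pc1,
                                  labels_from_values(pc1))
    sub = oe.values[np.ix_(valid, valid)]
    sub = np.where(np.isfinite(sub), sub, 1.0)  # neutral O/E where undefined
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    centered = corr - corr.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, 0] * s[0]
    r = stats.spearmanr(scores, gc[valid]).statistic
    if (not np.isfinite(r) or abs(r) < orientation_min_r) and gene_density is not None:
        r = stats.spearmanr(scores, np.asarray(gene_density, float)[valid]).statistic
    if np.isfinite(r) and r < 0:
        scores = -scores
    pc1[valid] = scores
    return CompartmentProfile(oe.chrom, oe.bin_size, pc1, labels_from_values(pc1))


def compute_ab_index(oe20: ContactMatrix, labels100: np.ndarray,
                     coarse_bin_size: int = 100_000,
                     min_sep: int = 100_000) -> np.ndarray:
    """A-B index per fine bin from its O/E contact with A vs B coarse bins.

    For bin ``i``, ``S_A`` sums O/E over unmasked partners ``j`` whose parent
    coarse bin is labelled A and whose separation ``|i - j| * bin_size`` is at
    least ``min_sep``; ``S_B`` analogously.  The index is
    ``(S_A - S_B) / (S_A + S_B)`` in [-1, 1], NaN when ``S_A + S_B == 0``.
    """
    labels100 = np.asarray(labels100)
    if not np.any(labels100 != LABEL_NONE):
        raise ValueError("no labelled coarse bins")
    n = oe20.n_bins
    factor = coarse_bin_size // oe20.bin_size
    parent = np.arange(n) // factor
    if parent.max() >= labels100.size:
        raise ValueError("fine bins extend past the coarse label track")
    fine_labels = labels100[parent]
    v = np.where(np.isfinite(oe20.values), oe20.values, 0.0)
    # exclude pairs closer than min_sep (including the diagonal) so the
    # distance-decay-dominated near field does not swamp the contrast
    w = int(np.ceil(min_sep / oe20.bin_size))
    if w > 0:
        idx = np.arange(n)
        band = np.abs(idx[:, None] - idx[None, :]) < w
        v = np.where(band, 0.0, v)
    a_vec = ((fine_labels == LABEL_A) & oe20.mask).astype(float)
    b_vec = ((fine_labels == LABEL_B) & oe20.mask).astype(float)
    s_a = v @ a_vec
    s_b = v @ b_vec
    total = s_a + s_b
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(total > 0, (s_a - s_b) / total, np.nan)
    ab[~oe20.mask] = np.nan
    return ab


def compartment_frequency(label_sets: list[np.ndarray],
                          high: float = 0.70, low: float = 0.30) -> pd.DataFrame:
    """Per-bin frequency of A status across replicates, with classes.

    Frequency is ``#replicates with A / #replicates with an assigned status``;
    bins unassigned in every replicate get NaN.  Classes: ``high`` iff
    frequency > ``high``, ``low`` iff frequency < ``low``, else ``medium``.
    """
    if not label_sets:
        raise ValueError("need at least one replicate")
    labels = np.stack([np.asarray(ls) for ls in label_sets])
    n_a = (labels == LABEL_A).sum(axis=0)
    n_assigned = (labels != LABEL_NONE).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_assigned > 0, n_a / n_assigned, np.nan)
    cls = np.full(freq.shape, "medium", dtype=object)
    cls[freq > high] = "high"
    cls[freq < low] = "low"
    cls[~np.isfinite(freq)] = "unassigned"
    return pd.DataFrame({"frequency": freq, "n_assigned": n_assigned,
                         "class": cls})


def _group_status(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin consensus status (+1/-1/0) and consistency in [0, 1]."""
    n_a = (labels == LABEL_A).sum(axis=0)
    n_b = (labels == LABEL_B).sum(axis=0)
    assigned = n_a + n_b
    status = np.zeros(labels.shape[1], dtype=np.int8)
    status[n_a > n_b] = LABEL_A
    status[n_b > n_a] = LABEL_B
    with np.errstate(invalid="ignore", divide="ignore"):
        consistency = np.where(assigned > 0,
                               np.maximum(n_a, n_b) / assigned, np.nan)
    return status, consistency


def classify_compartment_changes(labels1: np.ndarray, ab1: np.ndarray,
                                 labels2: np.ndarray, ab2: np.ndarray,
                                 consistency_min: float = 0.80,
                                 delta_min: float = 0.75,
                                 q_max: float = 0.05) -> pd.DataFrame:
    """Classify each bin as switch / variable / stable / unclassified.

    Parameters
    ----------
    labels1, labels2 : ndarray, shape (n_replicates, n_bins)
        Per-replicate A/B labels (+1/-1/0) for the two groups.
    ab1, ab2 : ndarray, shape (n_replicates, n_bins)
        Per-replicate signed A-B index values used for the variable test.

    Rules
    -----
    * switch: both groups at least ``consistency_min`` consistent and
      consensus statuses opposite;
    * variable: same status, ``|mean dAB| > delta_min`` and BH-adjusted
      two-sided Welch t-test q < ``q_max`` (needs >= 2 replicates per group);
    * stable: same status and not variable;
    * unclassified: everything else.
    """
    labels1, labels2 = np.atleast_2d(labels1), np.atleast_2d(labels2)
    ab1, ab2 = np.atleast_2d(np.asarray(ab1, float)), np.atleast_2d(np.asarray(ab2, float))
    n_bins = labels1.shape[1]
    for arr in (labels2, ab1, ab2):
        if arr.shape[1] != n_bins:
            raise ValueError("misaligned bins between groups")
    status1, cons1 = _group_status(labels1)
    status2, cons2 = _group_status(labels2)
    mean1 = np.nanmean(ab1, axis=0)
    mean2 = np.nanmean(ab2, axis=0)
    delta = mean2 - mean1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tt = stats.ttest_ind(ab1, ab2, axis=0, equal_var=False,
                             nan_policy="omit")
        pvals = np.asarray(tt.pvalue, dtype=float)
    qvals = np.full(n_bins, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        qvals[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    cls = np.full(n_bins, "unclassified", dtype=object)
    same = (status1 == status2) & (status1 != LABEL_NONE)
    opposite = (status1 == -status2) & (status1 != LABEL_NONE)
    consistent = (cons1 >= consistency_min) & (cons2 >= consistency_min)
    cls[opposite & consistent] = "switch"
    variable = same & (np.abs(delta) > delta_min) & (qvals < q_max)
    cls[same] = "stable"
    cls[variable] = "variable"
    return pd.DataFrame({
        "class": cls, "status1": status1, "status2": status2,
        "consistency1": cons1, "consistency2": cons2,
        "delta_ab": delta, "q": qvals,
    })
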