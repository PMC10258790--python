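"""Contact-matrix data model, I/O, balancing and normalization.

This module holds the dense symmetric intra-chromosomal contact matrix used
throughout the package, together with the three matrix-level transforms the
pipeline needs before any architecture calling can happen:

* Knight-Ruiz (KR) matrix balancing, which removes per-bin coverage bias by
  finding a diagonal scaling ``diag(s) @ M @ diag(s)`` with constant row sums;
* per-distance quantile normalization across samples, which equalizes the
  value distribution at every genomic separation so that samples are
  comparable;
* the observed/expected (O/E) transform, which divides each entry by the mean
  contact frequency at its genomic separation, removing distance decay.

Matrices are stored dense (float64) with a per-bin boolean mappability mask;
masked bins carry NaN in every row/column so downstream code cannot silently
consume them.  Coordinates are 0-based, half-open; bin ``b`` covers
``[b * bin_size, (b + 1) * bin_size)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "BalancingError",
    "read_sparse_contacts",
    "write_sparse_contacts",
    "write_dense_tsv",
    "kr_balance",
    "quantile_normalize_samples",
    "oe_transform",
]

logger = logging.getLogger(__name__)

_FORMS = ("raw", "balanced", "oe")
_SYM_TOL = 1e-9


class BalancingError(RuntimeError):
    """Raised when KR balancing fails to converge; carries diagnostics."""

    def __init__(self, message: str, residual: float | None = None,
                 n_matvec: int | None = None):
        super().__init__(message)
        self.residual = residual
        self.n_matvec = n_matvec


@dataclass
class ContactMatrix:
    """Symmetric intra-chromosomal contact matrix at a fixed bin size.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    bin_size : int
        Bin width in base pairs.
    values : ndarray of shape (n_bins, n_bins)
        Symmetric non-negative matrix.  Rows/columns of masked bins are NaN.
    mask : ndarray of bool, shape (n_bins,)
        Per-bin mappability flag; ``True`` means the bin is usable.
    form : {'raw', 'balanced', 'oe'}
        Processing stage of ``values``.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    mask: np.ndarray
    form: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.mask.shape != (self.values.shape[0],):
            raise ValueError("mask length must equal matrix dimension")
        if self.form not in _FORMS:
            raise ValueError(f"form must be one of {_FORMS}, got {self.form!r}")
        # blank out masked bins so no finite value survives there
        self.values[~self.mask, :] = np.nan
        self.values[:, ~self.mask] = np.nan
        self._validate()

    def _validate(self) -> None:
        v = self.values
        sub = v[np.ix_(self.mask, self.mask)]
        scale = 1.0
        if sub.size:
            finite = sub[np.isfinite(sub)]
            if finite.size:
                scale = max(1.0, float(np.abs(finite).max()))
        asym = np.nan_to_num(v - v.T, nan=0.0)
        if np.abs(asym).max(initial=0.0) > _SYM_TOL * scale:
            raise ValueError("contact matrix is not symmetric within tolerance")
        if self.form in ("raw", "balanced") and sub.size:
            finite = sub[np.isfinite(sub)]
            if finite.size and finite.min() < 0:
                raise ValueError(f"{self.form} matrix has negative entries")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.chrom, self.bin_size, self.values.copy(),
                             self.mask.copy(), self.form)


@dataclass
class ExpectedProfile:
    """Per-distance expected contact frequency e(d), d = 0 .. n_bins - 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __getitem__(self, d: int) -> float:
        return float(self.values[d])

    def __len__(self) -> int:
        return self.values.size


def read_sparse_contacts(path: str | Path, chrom: str, bin_size: int,
                         n_bins: int) -> ContactMatrix:
    """Read a whitespace-separated ``bin_i bin_j count`` triplet file.

    Each unordered bin pair should appear once; entries are mirrored onto the
    lower triangle.  Bins with a zero marginal are flagged masked.

    Raises
    ------
    ValueError
        On out-of-range bin indices or negative counts.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["i", "j", "count"], dtype=float)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["i", "j", "count"], dtype=float)
    values = np.zeros((n_bins, n_bins), dtype=float)
    if len(df):
        i = df["i"].to_numpy()
        j = df["j"].to_numpy()
        c = df["count"].to_numpy(dtype=float)
        if not (np.all(i == np.floor(i)) and np.all(j == np.floor(j))):
            raise ValueError("bin indices must be integers")
        i = i.astype(int)
        j = j.astype(int)
        if i.min(initial=0) < 0 or j.min(initial=0) < 0 \
                or i.max(initial=0) >= n_bins or j.max(initial=0) >= n_bins:
            raise ValueError(f"bin index out of range [0, {n_bins})")
        if np.any(c < 0):
            raise ValueError("negative contact count")
        np.add.at(values, (i, j), c)
        off = i != j
        np.add.at(values, (j[off], i[off]), c[off])
    mask = values.sum(axis=0) > 0
    return ContactMatrix(chrom, bin_size, values, mask, form="raw")


def write_sparse_contacts(m: ContactMatrix, path: str | Path) -> None:
    """Write the upper triangle (incl. diagonal) as ``i j count`` triplets.

    Integer-valued matrices round-trip bit-exactly.
    """
    iu, ju = np.triu_indices(m.n_bins)
    v = m.values[iu, ju]
    keep = np.isfinite(v) & (v != 0)
    iu, ju, v = iu[keep], ju[keep], v[keep]
    integral = v.size == 0 or np.all(v == np.floor(v))
    with open(path, "w") as fh:
        for a, b, c in zip(iu, ju, v):
            fh.write(f"{a}\t{b}\t{int(c) if integral else repr(float(c))}\n")


def write_dense_tsv(m: ContactMatrix, path: str | Path) -> None:
    """Dense TSV matrix dump (debugging aid)."""
    np.savetxt(path, m.values, delimiter="\t", fmt="%.10g")


# ---------------------------------------------------------------------------
# Knight-Ruiz balancing
# ---------------------------------------------------------------------------

def _kr_scaling(a: np.ndarray, tol: float, max_matvec: int) -> tuple[np.ndarray, int]:
    """Inner-outer Newton iteration for the KR scaling vector.

    Finds x > 0 with ``x * (a @ x) = 1`` so that ``diag(x) a diag(x)`` is
    doubly stochastic.  Conjugate-gradient inner solves with the classic
    step-length safeguards keep the iterates positive.
    """
    n = a.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, big_delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol ** 2
    v = x * (a @ x)
    rk = 1.0 - v
    rho_km1 = float(rk @ rk)
    rout = rho_km1
    rold = rout
    n_matvec = 1
    while rout > rt:
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        z = p = w = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                z = rk / v
                p = z.copy()
                rho_km1 = float(rk @ z)
            else:
                beta = rho_km1 / rho_km2
                p = z + beta * p
            w = x * (a @ (x * p)) + v * p
            n_matvec += 1
            denom = float(p @ w)
            if denom <= 0:
                break
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = float(((delta - y[ind]) / ap[ind]).min())
                y = y + gamma * ap
                break
            if ynew.max() >= big_delta:
                ind = ynew > big_delta
                gamma = float(((big_delta - y[ind]) / ap[ind]).min())
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            z = rk / v
            rho_km1 = float(rk @ z)
            if n_matvec > max_matvec:
                raise BalancingError(
                    "KR balancing did not converge "
                    f"(residual {np.sqrt(rout):.3e} after {n_matvec} matrix-vector "
                    "products)", residual=float(np.sqrt(rout)), n_matvec=n_matvec)
        x = x * y
        v = x * (a @ x)
        n_matvec += 1
        rk = 1.0 - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        rat = rout / rold if rold > 0 else 0.0
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), stop_tol / res_norm if res_norm > 0 else etamax)
        if n_matvec > max_matvec:
            raise BalancingError(
                "KR balancing did not converge "
                f"(residual {res_norm:.3e} after {n_matvec} matrix-vector products)",
                residual=float(res_norm), n_matvec=n_matvec)
    return x, n_matvec


def kr_balance(m: ContactMatrix, tol: float = 1e-8,
               max_iter: int = 5000,
               sparsity_quantile: float = 0.01) -> tuple[ContactMatrix, np.ndarray]:
    """Knight-Ruiz balance a raw contact matrix.

    Bins whose marginal is below ``sparsity_quantile`` (default 1%) of the
    median positive marginal are masked before balancing, in the spirit of
    Juicer's sparsity filter.  The balanced matrix has unmasked row sums equal
    to 1 within ``tol``.

    Returns
    -------
    (balanced, scaling) : (ContactMatrix, ndarray)
        ``balanced.values == diag(s) @ m.values @ diag(s)`` on unmasked bins;
        ``scaling`` is NaN at masked bins.
    """
    if m.form != "raw":
        raise ValueError("kr_balance expects a raw matrix")
    marg = np.nansum(np.nan_to_num(m.values, nan=0.0), axis=0)
    keep = m.mask.copy()
    positive = marg[keep & (marg > 0)]
    if positive.size:
        cutoff = sparsity_quantile * np.median(positive)
        keep &= marg >= cutoff
    keep &= marg > 0
    if not keep.any():
        raise ValueError("all bins masked; nothing to balance")
    sub = np.nan_to_num(m.values[np.ix_(keep, keep)], nan=0.0)
    x, n_matvec = _kr_scaling(sub, tol=tol, max_matvec=max_iter)
    logger.info("KR balancing of %s converged after %d matrix-vector products",
                m.chrom, n_matvec)
    scaling = np.full(m.n_bins, np.nan)
    scaling[keep] = x
    balanced = np.full_like(m.values, np.nan)
    balanced[np.ix_(keep, keep)] = sub * np.outer(x, x)
    return ContactMatrix(m.chrom, m.bin_size, balanced, keep, form="balanced"), scaling


# ---------------------------------------------------------------------------
# Cross-sample quantile normalization (per genomic distance)
# ---------------------------------------------------------------------------

def quantile_normalize_samples(matrices: Sequence[ContactMatrix]) -> list[ContactMatrix]:
    """Quantile-normalize a set of matrices separately at each distance.

    For every genomic separation ``d``, the values on diagonal ``d`` are
    replaced by the rank-wise mean of the sorted per-sample values, so the
    multiset of values at each distance becomes identical across samples
    while within-sample rank order is preserved.  Ties take the average rank.
    The operation is idempotent.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.n_bins != ref.n_bins or m.bin_size != ref.bin_size \
                or m.chrom != ref.chrom:
            raise ValueError("matrices must share chromosome, bin size and shape")
        if not np.array_equal(m.mask, ref.mask):
            raise ValueError("matrices must share the same bin mask")
    if len(matrices) == 1:
        return [matrices[0].copy()]
    n = ref.n_bins
    outs = [np.full((n, n), np.nan) for _ in matrices]
    idx = np.arange(n)
    for d in range(n):
        rows = idx[: n - d]
        cols = rows + d
        valid = ref.mask[rows] & ref.mask[cols]
        if not valid.any():
            continue
        r, c = rows[valid], cols[valid]
        vals = np.stack([m.values[r, c] for m in matrices])
        finite = np.all(np.isfinite(vals), axis=0)
        if not finite.any():
            continue
        r, c, vals = r[finite], c[finite], vals[:, finite]
        k = vals.shape[1]
        mean_sorted = np.sort(vals, axis=1).mean(axis=0)
        positions = np.arange(1, k + 1)
        for s in range(len(matrices)):
            ranks = rankdata(vals[s], method="average")
            normalized = np.interp(ranks, positions, mean_sorted)
            outs[s][r, c] = normalized
            outs[s][c, r] = normalized
    return [ContactMatrix(m.chrom, m.bin_size, out, ref.mask.copy(), form=m.form)
            for m, out in zip(matrices, outs)]


# ---------------------------------------------------------------------------
# Observed / expected transform
# ---------------------------------------------------------------------------

def oe_transform(m: ContactMatrix) -> tuple[ContactMatrix, ExpectedProfile]:
    """Divide each entry by the mean contact frequency at its separation.

    ``e(d)`` is the mean of unmasked entries at separation ``d``; entries with
    ``e(d) == 0`` (or an undefined stratum) are flagged missing.  The mean of
    unmasked O/E entries at each distance is 1 by construction.
    """
    n = m.n_bins
    expected = np.full(n, np.nan)
    oe = np.full((n, n), np.nan)
    idx = np.arange(n)
    for d in range(n):
        rows = idx[: n - d]
        cols = rows + d
        valid = m.mask[rows] & m.mask[cols]
        if not valid.any():
            continue
        r, c = rows[valid], cols[valid]
        vals = m.values[r, c]
        finite = np.isfinite(vals)
        if not finite.any():
            continue
        e_d = float(vals[finite].mean())
        expected[d] = e_d
        if e_d > 0:
            ratio = vals / e_d
            oe[r, c] = ratio
            oe[c, r] = ratio
    return (ContactMatrix(m.chrom, m.bin_size, oe, m.mask.copy(), form="oe"),
            ExpectedProfile(expected))
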