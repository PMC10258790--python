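"""Seeded generators for contact maps and regulatory landscapes with truth.

Every pipeline stage in this package is exercised on synthetic data whose
ground truth is known by construction.  The contact-map generator emulates
the salient structure of a real intra-chromosomal Hi-C map:

* power-law distance decay ``|i - j|^-alpha`` (alpha = 1, the standard
  scaling regime);
* checkerboard compartmentalization ``exp(beta * e_i * e_j)`` for a planted
  A/B eigenprofile ``e in {-1, +1}``;
* TAD block enrichment ``tau`` for bin pairs inside the same planted domain;
* punctate loop enrichment (3x3-bin Gaussian multiplicative bumps);
* Poisson sampling at a stated sequencing depth.

Population generators emit replicate maps/label-sets with designed per-bin
compartment consistency, per-boundary presence probability and boundary
jitter, so population frequency estimators can be checked against exact
binomial expectations.  The regulatory generator emits PEI, expression,
peak, liftover and percentile-background tables in the same file schemas the
pipeline consumes, with planted per-gene RPS and per-enhancer conservation
classes that the classifiers must recover in the noise-free limit.

All generators are bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import ContactMatrix

__all__ = [
    "ArchitectureTruth",
    "RegulatoryTruth",
    "random_architecture",
    "simulate_contact_map",
    "simulate_population",
    "random_regulatory_truth",
    "simulate_regulatory_landscape",
    "synthetic_gc",
]


@dataclass
class ArchitectureTruth:
    """Planted chromosome architecture for the contact-map generator."""

    n_bins: int
    bin_size: int
    compartments: np.ndarray          # e in {-1, +1} per bin
    boundaries: np.ndarray            # strictly increasing interior bin indices
    loops: list[tuple[int, int, float]] = field(default_factory=list)
    alpha: float = 1.0                # distance-decay exponent
    beta: float = 0.6                 # compartment checkerboard strength
    tau: float = 1.5                  # within-domain enrichment (>= 1)
    depth: float = 1.0e6              # expected total contact count

    def __post_init__(self) -> None:
        self.compartments = np.asarray(self.compartments, dtype=np.int8)
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if self.compartments.shape != (self.n_bins,):
            raise ValueError("compartment profile must have one entry per bin")
        if not np.all(np.isin(self.compartments, (-1, 1))):
            raise ValueError("compartment profile entries must be -1 or +1")
        if self.boundaries.size and not np.all(np.diff(self.boundaries) > 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if any(amp < 0 for _, _, amp in self.loops):
            raise ValueError("loop amplitudes must be >= 0")

    @property
    def domain_ids(self) -> np.ndarray:
        return np.searchsorted(self.boundaries, np.arange(self.n_bins),
                               side="right")


def random_architecture(n_bins: int = 500, bin_size: int = 100_000,
                        seed: int = 0, mean_block: int = 12,
                        mean_domain: int = 25, n_loops: int = 0,
                        loop_amplitude: float = 2.0,
                        **kwargs) -> ArchitectureTruth:
    """Draw a random planted architecture.

    Compartment blocks alternate A/B with geometric lengths (mean
    ``mean_block`` bins); TAD boundaries are spaced geometrically (mean
    ``mean_domain`` bins); loops connect random anchor pairs 10-60 bins
    apart.  Remaining keyword arguments pass through to ArchitectureTruth.
    """
    rng = np.random.default_rng(seed)
    comp = np.empty(n_bins, dtype=np.int8)
    sign = rng.choice([-1, 1])
    i = 0
    while i < n_bins:
        length = 1 + rng.geometric(1.0 / mean_block)
        comp[i:i + length] = sign
        sign = -sign
        i += length
    boundaries = []
    pos = 0
    while True:
        pos += 2 + rng.geometric(1.0 / mean_domain)
        if pos >= n_bins - 2:
            break
        boundaries.append(pos)
    loops = []
    for _ in range(n_loops):
        i = int(rng.integers(0, max(1, n_bins - 61)))
        j = i + int(rng.integers(10, 61))
        if j < n_bins:
            loops.append((i, j, loop_amplitude))
    return ArchitectureTruth(n_bins=n_bins, bin_size=bin_size,
                             compartments=comp,
                             boundaries=np.array(boundaries, int),
                             loops=loops, **kwargs)


def _intensity(truth: ArchitectureTruth) -> np.ndarray:
    """Expected contact intensity lambda(i, j), scaled to the target depth."""
    n = truth.n_bins
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    lam = np.maximum(d, 1).astype(float) ** (-truth.alpha)
    e = truth.compartments.astype(float)
    lam *= np.exp(truth.beta * np.outer(e, e))
    dom = truth.domain_ids
    lam *= np.where(dom[:, None] == dom[None, :], truth.tau, 1.0)
    if truth.loops:
        kernel = np.exp(-0.5 * (np.array([-1, 0, 1])[:, None] ** 2
                                + np.array([-1, 0, 1])[None, :] ** 2))
        bump = np.zeros_like(lam)
        for i, j, amp in truth.loops:
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    a, b = i + di, j + dj
                    if 0 <= a < n and 0 <= b < n:
                        k = amp * kernel[di + 1, dj + 1]
                        bump[a, b] = max(bump[a, b], k)
                        bump[b, a] = max(bump[b, a], k)
        lam *= 1.0 + bump
    upper = np.triu(lam)
    lam *= truth.depth / upper.sum()
    return lam


def simulate_contact_map(truth: ArchitectureTruth, seed: int = 0) -> ContactMatrix:
    """Poisson-sample a raw contact map from the planted intensity.

    Counts are drawn once per unordered bin pair and mirrored, so the map is
    exactly symmetric; bins with a zero marginal are masked.  Deterministic
    given (truth, seed).
    """
    rng = np.random.default_rng(seed)
    lam = _intensity(truth)
    n = truth.n_bins
    iu, ju = np.triu_indices(n)
    counts = rng.poisson(lam[iu, ju])
    values = np.zeros((n, n))
    values[iu, ju] = counts
    values[ju, iu] = counts
    mask = values.sum(axis=0) > 0
    return ContactMatrix(f"chrS{seed}", truth.bin_size, values, mask, form="raw")


def simulate_population(truth: ArchitectureTruth, n_replicates: int,
                        consistency: float | np.ndarray = 1.0,
                        boundary_presence: float | np.ndarray = 1.0,
                        boundary_jitter: int = 0, seed: int = 0,
                        with_matrices: bool = False
                        ) -> tuple[list[ArchitectureTruth], list[ContactMatrix]]:
    """Replicate a planted architecture with designed population noise.

    Each replicate independently flips each bin's compartment sign with
    probability ``1 - consistency[bin]``, drops each boundary with
    probability ``1 - boundary_presence[boundary]``, and jitters every kept
    boundary uniformly within ``+/- boundary_jitter`` bins.  Matrices are
    simulated per replicate only when requested (``with_matrices``).

    Returns ``(replicate_truths, replicate_matrices)``; the matrix list is
    empty when ``with_matrices`` is False.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    p_keep = np.broadcast_to(np.asarray(consistency, float), (truth.n_bins,))
    p_bnd = np.broadcast_to(np.asarray(boundary_presence, float),
                            (truth.boundaries.size,))
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_replicates)
    truths: list[ArchitectureTruth] = []
    matrices: list[ContactMatrix] = []
    for r in range(n_replicates):
        rng = np.random.default_rng(child_seeds[2 * r])
        flip = rng.random(truth.n_bins) > p_keep
        comp = truth.compartments.copy()
        comp[flip] = -comp[flip]
        kept = rng.random(truth.boundaries.size) < p_bnd
        bnd = truth.boundaries[kept]
        if boundary_jitter and bnd.size:
            bnd = bnd + rng.integers(-boundary_jitter, boundary_jitter + 1,
                                     size=bnd.size)
            bnd = np.unique(np.clip(bnd, 1, truth.n_bins - 2))
        rep = replace(truth, compartments=comp, boundaries=np.sort(bnd))
        truths.append(rep)
        if with_matrices:
            matrices.append(simulate_contact_map(rep, seed=int(child_seeds[2 * r + 1])))
    return truths, matrices


def synthetic_gc(truth: ArchitectureTruth, seed: int = 0,
                 base: float = 0.41, effect: float = 0.03,
                 noise_sd: float = 0.005) -> np.ndarray:
    """GC-content track correlated with the planted A compartment.

    Real A compartments are GC-rich; the orientation covariate for the PC1
    sign rule is emulated as ``base + effect * e + noise``.
    """
    rng = np.random.default_rng(seed)
    return (base + effect * truth.compartments.astype(float)
            + rng.normal(0.0, noise_sd, truth.n_bins))


# ---------------------------------------------------------------------------
# Regulatory landscape
# ---------------------------------------------------------------------------

_CONSERVATION_CLASSES = ("usage-conserved", "only-sequence-conserved",
                         "sequence-specific")


@dataclass
class RegulatoryTruth:
    """Planted promoter-enhancer landscape with conservation labels."""

    genes: pd.DataFrame        # gene, promoter_bin, biotype, base_tpm
    peis: pd.DataFrame         # gene, enhancer_start, enhancer_end, true_ln,
                               # distance, activity, conservation
    bin_size: int = 5_000
    expr_coupling: float = 0.5  # log2-TPM gain per unit planted RPS

    def __post_init__(self) -> None:
        if len(self.peis) and (self.peis["true_ln"] <= 0).any():
            raise ValueError("planted l_n values must be positive")

    def planted_rps(self) -> pd.Series:
        """Exact per-gene RPS implied by the planted l_n values."""
        if not len(self.peis):
            return pd.Series(0.0, index=self.genes["gene"])
        rps = self.peis.groupby("gene")["true_ln"].apply(
            lambda v: float(np.log10(v).sum()))
        return rps.reindex(self.genes["gene"]).fillna(0.0)


def random_regulatory_truth(n_genes: int = 100, seed: int = 0,
                            bin_size: int = 5_000,
                            max_enhancers: int = 5,
                            p_none: float = 0.3) -> RegulatoryTruth:
    """Draw a random planted regulatory landscape.

    Each gene gets 0 (probability ``p_none``) to ``max_enhancers`` enhancers
    with planted l_n in (1.5, 50), distances of 40 kb to 1 Mb, an activity
    class, and a conservation class per enhancer.
    """
    rng = np.random.default_rng(seed)
    # each gene owns a 2-Mb territory so enhancer intervals never collide
    # across genes and peak/conservation classes stay unambiguous
    genes = pd.DataFrame({
        "gene": [f"G{k:04d}" for k in range(n_genes)],
        "promoter_bin": np.arange(n_genes) * 400 + rng.integers(0, 100, n_genes),
        "biotype": rng.choice(["PCG", "lncRNA", "TUCP"], n_genes,
                              p=[0.8, 0.15, 0.05]),
        "base_tpm": rng.lognormal(1.0, 1.0, n_genes),
    })
    rows = []
    for _, g in genes.iterrows():
        n_enh = 0 if rng.random() < p_none \
            else int(rng.integers(1, max_enhancers + 1))
        # distinct distances per gene keep enhancer intervals unique
        dists = rng.choice(np.arange(8, 200), size=n_enh, replace=False)
        for dist_bins in dists:
            dist = int(dist_bins) * bin_size  # >= 40 kb
            start = int(g["promoter_bin"]) * bin_size + dist
            rows.append({
                "gene": g["gene"],
                "enhancer_start": start,
                "enhancer_end": start + bin_size,
                "true_ln": float(rng.uniform(1.5, 50.0)),
                "distance": dist,
                "activity": rng.choice(["highly-active", "moderately-active",
                                        "low-active"], p=[0.25, 0.35, 0.4]),
                "conservation": rng.choice(_CONSERVATION_CLASSES,
                                           p=[0.5, 0.3, 0.2]),
            })
    peis = pd.DataFrame(rows, columns=["gene", "enhancer_start", "enhancer_end",
                                       "true_ln", "distance", "activity",
                                       "conservation"])
    return RegulatoryTruth(genes=genes, peis=peis, bin_size=bin_size)


def simulate_regulatory_landscape(truth: RegulatoryTruth, seed: int = 0,
                                  ln_noise_sd: float = 0.0,
                                  ps_noise_sd: float = 0.0,
                                  n_samples: int = 3,
                                  stratum_size: int = 99) -> dict[str, pd.DataFrame]:
    """Emit observable tables from a planted regulatory landscape.

    Returns a dict with keys:

    * ``peis``       -- gene, chrom, promoter/enhancer intervals, l_n
      (planted value times log-normal noise of sigma ``ln_noise_sd``), fdr,
      distance; all rows pass the retention filters;
    * ``expression`` -- per-gene TPM for ``n_samples`` samples, log-normally
      dispersed around a level coupled to the planted RPS;
    * ``peaks_high`` / ``peaks_moderate`` -- BED-style peak sets covering the
      planted highly-/moderately-active enhancers;
    * ``liftover``   -- mapping table (status ``mapped``/``failed`` per the
      planted conservation class) with query coordinates and the mapped
      contact value;
    * ``background`` -- per-distance percentile background such that, with
      ``ps_noise_sd == 0``, usage-conserved enhancers score PS 95 and
      only-sequence-conserved ones PS 50.

    The background stratum holds ``stratum_size`` evenly spaced contact
    values per distance, so percentile ranks are exact by construction.
    """
    rng = np.random.default_rng(seed)
    peis = truth.peis.copy()
    if len(peis):
        noise = rng.lognormal(0.0, ln_noise_sd, len(peis)) if ln_noise_sd > 0 \
            else np.ones(len(peis))
        peis["l_n"] = peis["true_ln"] * noise
        peis["fdr"] = rng.uniform(0.0, 0.001, len(peis)) * 0.99
        peis["chrom"] = "chr1"
    else:
        peis = peis.assign(l_n=[], fdr=[], chrom=[])

    rps = truth.planted_rps()
    tpm = {}
    for s in range(n_samples):
        level = (truth.genes.set_index("gene")["base_tpm"]
                 * 2.0 ** (truth.expr_coupling * rps))
        tpm[f"S{s}"] = level * rng.lognormal(0.0, 0.2, len(level))
    expression = pd.DataFrame(tpm)

    def _peak_table(activity: str) -> pd.DataFrame:
        sel = peis[peis["activity"] == activity] if len(peis) else peis
        if not len(sel):
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.DataFrame({"chrom": "chr1",
                             "start": sel["enhancer_start"].to_numpy(),
                             "end": sel["enhancer_end"].to_numpy()})

    # percentile background: stratum_size evenly spaced values per distance,
    # so value v in 1..stratum_size has exact percentile 100*v/stratum_size
    distances = sorted(peis["distance"].unique()) if len(peis) else [40_000]
    bg_rows = []
    for d in distances:
        for v in range(1, stratum_size + 1):
            bg_rows.append({"distance": d, "contact": float(v)})
    background = pd.DataFrame(bg_rows)

    hi_rank = int(round(0.95 * stratum_size))   # PS 95 > 85
    lo_rank = int(round(0.50 * stratum_size))   # PS 50 <= 85
    lift_rows = []
    for k, row in peis.iterrows():
        cls = row["conservation"]
        ok = cls != "sequence-specific"
        contact = np.nan
        if ok:
            contact = float(hi_rank if cls == "usage-conserved" else lo_rank)
            if ps_noise_sd > 0:
                contact += rng.normal(0.0, ps_noise_sd)
        lift_rows.append({
            "ref_chrom": "chr1",
            "ref_start": row["enhancer_start"],
            "ref_end": row["enhancer_end"],
            "status": "mapped" if ok else "failed",
            "query_chrom": "chrQ1" if ok else ".",
            "query_start": row["enhancer_start"] + 1_000_000 if ok else -1,
            "query_end": row["enhancer_end"] + 1_000_000 if ok else -1,
            "distance": row["distance"],
            "contact": contact,
        })
    liftover = pd.DataFrame(lift_rows, columns=[
        "ref_chrom", "ref_start", "ref_end", "status", "query_chrom",
        "query_start", "query_end", "distance", "contact"])

    return {"peis": peis, "expression": expression,
            "peaks_high": _peak_table("highly-active"),
            "peaks_moderate": _peak_table("moderately-active"),
            "liftover": liftover, "background": background}
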