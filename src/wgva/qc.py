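"""Cohort-level QC and population structure.

Covers the pre-association variant filters (per-site missingness and minor
allele frequency), identity-by-state distances with agglomerative clustering
to a Newick dendrogram, linkage-disequilibrium pruning by variance inflation
factor (VIF) in sliding windows, and the trio Mendelian-error audit used as a
genotyping-accuracy index.

The IBS distance between samples i and j is the normalized L1 distance over
sites called in both:  d(i,j) = sum_s |g_is - g_js| / (2 * n_shared_sites).
It is 0 for identical genotype vectors and 1 for opposite homozygotes
everywhere.

VIF pruning: within a sliding window of ``window_size`` variants (step
``step_size``), repeatedly compute VIF_j = 1/(1 - R^2_j) for every kept
variant j, where R^2_j is the squared multiple correlation of j's dosage
regressed on the other kept variants in the window; while any VIF exceeds the
threshold, drop the variant with the largest VIF (ties drop the larger index)
and recompute.  A variant dropped in any window is dropped globally.  Windows
never span chromosomes.  Missing dosages are mean-imputed per variant before
regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .containers import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PruneConfig:
    window_size: int = 50
    step_size: int = 5
    vif_threshold: float = 2.0

    def __post_init__(self):
        if not self.window_size >= self.step_size >= 1:
            raise ValueError("require window_size >= step_size >= 1")
        if not self.vif_threshold > 1:
            raise ValueError("vif_threshold must exceed 1")


# ---------------------------------------------------------------------------
# marginal variant filters
# ---------------------------------------------------------------------------

def filter_missingness(dosages: np.ndarray, max_missing: float = 0.10) -> np.ndarray:
    """Indices of variants whose missing fraction is <= ``max_missing``
    (strictly more than the threshold is removed)."""
    miss = (dosages == MISSING).mean(axis=1)
    return np.flatnonzero(miss <= max_missing)


def minor_allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Per-variant MAF over non-missing alleles (0 where all missing)."""
    ok = dosages != MISSING
    alt = np.where(ok, dosages, 0).sum(axis=1)
    denom = 2 * ok.sum(axis=1)
    f = np.divide(alt, denom, out=np.zeros(len(dosages)), where=denom > 0)
    return np.minimum(f, 1.0 - f)


def filter_maf(dosages: np.ndarray, min_maf: float = 0.01) -> np.ndarray:
    """Indices of variants with minor allele frequency >= ``min_maf``."""
    return np.flatnonzero(minor_allele_frequencies(dosages) >= min_maf)


# ---------------------------------------------------------------------------
# identity by state
# ---------------------------------------------------------------------------

def ibs_distance(dosages: np.ndarray, sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Pairwise 1-IBS distance matrix as a labelled DataFrame.

    Raises if any sample pair shares no non-missing site (reported by id).
    """
    n_var, n_samp = dosages.shape
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n_samp)]
    G = dosages.astype(float)
    G[dosages == MISSING] = np.nan
    dist = np.zeros((n_samp, n_samp))
    for i in range(n_samp - 1):
        diff = np.abs(G[:, i][:, None] - G[:, i + 1:])
        overlap = np.sum(~np.isnan(diff), axis=0)
        zero = np.flatnonzero(overlap == 0)
        if zero.size:
            j = i + 1 + zero[0]
            raise ValueError(f"samples {ids[i]!r} and {ids[j]!r} share no genotyped site")
        d = np.nansum(diff, axis=0) / (2.0 * overlap)
        dist[i, i + 1:] = d
        dist[i + 1:, i] = d
    return pd.DataFrame(dist, index=ids, columns=ids)


def _newick_from_linkage(Z: np.ndarray, ids: list[str]) -> str:
    """Render a scipy linkage as Newick with branch lengths equal to
    merge-height differences (leaves sit at height 0, so a two-leaf tree is a
    cherry with branches of half the pair distance under UPGMA)."""
    n = len(ids)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: ids[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        height = h / 2.0
        la = height - heights[a]
        lb = height - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g})"
        heights[n + k] = height
    return nodes[n + len(Z) - 1] + ";"


def dendrogram(dist: pd.DataFrame, method: str = "average") -> tuple[str, np.ndarray]:
    """Agglomerative tree over the distance matrix.

    Returns ``(newick, linkage_matrix)``; linkage methods are the scipy names
    (``average`` i.e. UPGMA by default, or ``complete``/``single``).
    """
    if len(dist) < 2:
        raise ValueError("need at least 2 samples for a dendrogram")
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = scipy_linkage(condensed, method=method)
    return _newick_from_linkage(Z, list(dist.index)), Z


# ---------------------------------------------------------------------------
# VIF pruning
# ---------------------------------------------------------------------------

def _mean_impute(dosages: np.ndarray) -> np.ndarray:
    X = dosages.astype(float)
    miss = dosages == MISSING
    if miss.any():
        ok = ~miss
        counts = ok.sum(axis=1)
        means = np.where(counts > 0,
                         np.where(ok, X, 0).sum(axis=1) / np.maximum(counts, 1), 0.0)
        X = np.where(miss, means[:, None], X)
    return X


def _vifs(X: np.ndarray) -> np.ndarray:
    """VIF of each row-variable of X (variables x observations).

    Monomorphic variables get VIF 1 (nothing can correlate with a constant);
    exact collinearity yields inf.
    """
    m = X.shape[0]
    if m == 1:
        return np.ones(1)
    sd = X.std(axis=1)
    const = sd == 0
    vifs = np.ones(m)
    active = np.flatnonzero(~const)
    if active.size < 2:
        return vifs
    R = np.corrcoef(X[active])
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or logdet < -30:  # numerically singular: exact collinearity
        # fall back to per-variable least squares to locate the offenders
        for k, j in enumerate(active):
            others = np.delete(active, k)
            vifs[j] = _vif_by_lstsq(X[j], X[others])
        return vifs
    diag = np.diag(np.linalg.inv(R))
    vifs[active] = diag
    return vifs


def _vif_by_lstsq(y: np.ndarray, others: np.ndarray) -> float:
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0 or others.size == 0:
        return 1.0
    A = np.column_stack([np.ones(len(y)), others.T])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sse = float(resid @ resid)
    r2 = 1.0 - sse / sst
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def _prune_window(X: np.ndarray, kept: list[int], vif_threshold: float) -> None:
    """Iteratively drop the max-VIF variant from ``kept`` (indices into X's
    rows) until all VIFs are within threshold.  Ties drop the larger index."""
    while len(kept) > 1:
        vifs = _vifs(X[kept])
        worst = np.max(vifs)
        if not (worst > vif_threshold):
            break
        ties = np.flatnonzero(np.isclose(vifs, worst) | (np.isinf(vifs) & np.isinf(worst)))
        drop_pos = int(ties.max())
        del kept[drop_pos]


def vif_prune(matrix: GenotypeMatrix, cfg: PruneConfig | None = None) -> np.ndarray:
    """Globally kept variant indices after sliding-window VIF pruning.

    Variants must be ordered by chromosome and position (the simulator and
    VCF reader both provide that ordering).
    """
    cfg = cfg or PruneConfig()
    chroms = matrix.variants["CHROM"].to_numpy()
    keep = np.ones(matrix.n_variants, dtype=bool)
    X_all = _mean_impute(matrix.dosages)
    start_of_chrom = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1]])
    bounds = list(start_of_chrom) + [matrix.n_variants]
    for c in range(len(bounds) - 1):
        lo, hi = bounds[c], bounds[c + 1]
        for start in range(lo, hi, cfg.step_size):
            window = np.arange(start, min(start + cfg.window_size, hi))
            kept = [int(j) for j in window if keep[j]]
            if len(kept) < 2:
                continue
            before = set(kept)
            _prune_window(X_all, kept, cfg.vif_threshold)
            for j in before - set(kept):
                keep[j] = False
            if start + cfg.window_size >= hi:
                break
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# Mendelian errors
# ---------------------------------------------------------------------------

def _possible_offspring(gs: np.ndarray, gd: np.ndarray, go: np.ndarray) -> np.ndarray:
    """Boolean mask: offspring dosage attainable from one allele per parent."""
    # transmitted allele sets: 0 -> {0}, 1 -> {0,1}, 2 -> {1}
    lo = (gs == 2).astype(np.int8) + (gd == 2).astype(np.int8)
    hi = (gs > 0).astype(np.int8) + (gd > 0).astype(np.int8)
    return (go >= lo) & (go <= hi)


def mendel_errors(matrix: GenotypeMatrix, design) -> pd.DataFrame:
    """Per-trio Mendelian error counts and per-meiosis rates.

    Sites where any trio member is missing are skipped.  The per-meiosis rate
    divides the error count by twice the number of evaluated trio-sites (each
    offspring genotype reflects two meioses).
    """
    rows = []
    for (o, s, d), (oi, si, di) in zip(design.trios, design.trio_indices()):
        go = matrix.dosages[:, oi]
        gs = matrix.dosages[:, si]
        gd = matrix.dosages[:, di]
        ok = (go != MISSING) & (gs != MISSING) & (gd != MISSING)
        consistent = _possible_offspring(gs[ok], gd[ok], go[ok])
        n_sites = int(ok.sum())
        n_err = int((~consistent).sum())
        rate = n_err / (2.0 * n_sites) if n_sites else np.nan
        rows.append({"offspring": o, "sire": s, "dam": d,
                     "n_sites": n_sites, "n_errors": n_err,
                     "per_meiosis_rate": rate})
    return pd.DataFrame(rows)
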