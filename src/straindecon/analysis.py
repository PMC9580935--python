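"""Downstream strain analyses.

Covers the post-inference toolbox: discretizing fuzzy genotypes,
dereplicating near-identical strains into composite strains,
co-clustering inferred strains with reference genotypes, permutation
tests for enrichment of shared / inferred-only clusters, per-sample
dominant-strain calls, and linkage-disequilibrium (LD) statistics with
their distance-decay profile.

Genotype distances throughout are masked normalized Hamming distances;
"average-neighbor" agglomeration is average linkage cut at a distance
threshold.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


def discretize(gamma: np.ndarray) -> np.ndarray:
    """Round fuzzy genotypes to {0, 1}: entry 1 iff gamma >= 0.5.

    NaN (missing) entries are preserved.  Idempotent on discrete input.
    """
    g = np.asarray(gamma, dtype=float)
    if np.nanmin(g, initial=0.0) < 0 or np.nanmax(g, initial=0.0) > 1:
        raise ValueError("fuzzy genotypes must lie in [0, 1]")
    out = np.where(g >= 0.5, 1.0, 0.0)
    return np.where(np.isnan(g), np.nan, out)


# ---------------------------------------------------------------------------
# Dereplication and co-clustering
# ---------------------------------------------------------------------------

def _consensus_genotype(members: np.ndarray) -> np.ndarray:
    """Per-site majority allele over member strains; ties -> alternative.

    Missing alleles are ignored per site; all-missing sites stay missing.
    """
    obs = ~np.isnan(members)
    n_obs = obs.sum(axis=0)
    n_alt = np.nansum(members, axis=0)
    with np.errstate(invalid="ignore"):
        cons = np.where(2 * n_alt >= n_obs, 1.0, 0.0)
    return np.where(n_obs > 0, cons, np.nan)


def _cluster_labels(genotypes: np.ndarray, threshold: float) -> np.ndarray:
    """Average-linkage cluster labels at a distance threshold (0-based)."""
    from .evaluation import masked_hamming_matrix

    k = genotypes.shape[0]
    if k == 1:
        return np.zeros(1, dtype=int)
    D = masked_hamming_matrix(genotypes, genotypes)
    D = np.nan_to_num(D, nan=1.0)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=threshold, criterion="distance")
    # relabel clusters by first appearance for determinism
    order = {}
    labels = np.empty(k, dtype=int)
    for idx, c in enumerate(raw):
        if c not in order:
            order[c] = len(order)
        labels[idx] = order[c]
    return labels


def dereplicate(
    gamma: np.ndarray, pi: np.ndarray, threshold: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Merge near-identical strains into composite strains.

    Strains are clustered by average linkage on masked Hamming distance
    and merged below ``threshold``.  Each cluster is replaced by one
    composite strain with the per-site majority allele (ties go to the
    alternative allele) and the summed relative abundance of its
    members.  Returns (gamma', pi'); pi' rows remain on the simplex.
    """
    gamma = np.asarray(gamma, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if pi.shape[1] != gamma.shape[0]:
        raise ValueError("pi and gamma disagree on the number of strains")
    labels = _cluster_labels(gamma, threshold)
    n_clusters = labels.max() + 1
    new_gamma = np.empty((n_clusters, gamma.shape[1]))
    new_pi = np.zeros((pi.shape[0], n_clusters))
    for c in range(n_clusters):
        members = labels == c
        new_gamma[c] = _consensus_genotype(gamma[members])
        new_pi[:, c] = pi[:, members].sum(axis=1)
    return new_gamma, new_pi


@dataclasses.dataclass(frozen=True)
class StrainClusterSet:
    """Co-clustering of inferred and reference strains.

    cluster : cluster id per strain (0-based, dense)
    source  : per-strain label, "inferred" or "reference"
    consensus : per-cluster consensus genotype (majority rule)
    """

    cluster: np.ndarray
    source: np.ndarray
    consensus: np.ndarray

    def __post_init__(self):
        cluster = np.asarray(self.cluster, dtype=int)
        source = np.asarray(self.source, dtype=str)
        if cluster.shape != source.shape:
            raise ValueError("cluster and source must align")
        if not set(np.unique(source)) <= {"inferred", "reference"}:
            raise ValueError("sources must be 'inferred' or 'reference'")
        object.__setattr__(self, "cluster", cluster)
        object.__setattr__(self, "source", source)

    @property
    def n_clusters(self) -> int:
        return int(self.cluster.max()) + 1

    def cluster_category(self) -> np.ndarray:
        """Per-cluster category: shared / inferred-only / reference-only."""
        cats = []
        for c in range(self.n_clusters):
            src = set(self.source[self.cluster == c])
            if src == {"inferred", "reference"}:
                cats.append("shared")
            elif src == {"inferred"}:
                cats.append("inferred-only")
            else:
                cats.append("reference-only")
        return np.asarray(cats)

    def category_tally(self) -> dict:
        cats = self.cluster_category()
        return {c: int((cats == c).sum()) for c in ("shared", "inferred-only", "reference-only")}


def cocluster(
    inferred: np.ndarray, reference: np.ndarray, threshold: float = 0.15
) -> StrainClusterSet:
    """Co-cluster (dereplicated) inferred and reference genotypes.

    Average linkage at ``threshold`` over the union of both strain sets;
    each cluster gets a majority-rule consensus genotype.
    """
    inferred = np.asarray(inferred, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if inferred.shape[0] == 0 or reference.shape[0] == 0:
        raise ValueError("both strain sets must be non-empty")
    if inferred.shape[1] != reference.shape[1]:
        raise ValueError("inferred and reference must share the site set")
    union = np.vstack([inferred, reference])
    source = np.array(
        ["inferred"] * inferred.shape[0] + ["reference"] * reference.shape[0]
    )
    labels = _cluster_labels(union, threshold)
    consensus = np.vstack(
        [_consensus_genotype(union[labels == c]) for c in range(labels.max() + 1)]
    )
    return StrainClusterSet(cluster=labels, source=source, consensus=consensus)


# ---------------------------------------------------------------------------
# Permutation enrichment
# ---------------------------------------------------------------------------

def _enrichment_statistic(cluster: np.ndarray, source: np.ndarray, statistic: str) -> int:
    n_clusters = cluster.max() + 1
    has_inf = np.zeros(n_clusters, dtype=bool)
    has_ref = np.zeros(n_clusters, dtype=bool)
    np.logical_or.at(has_inf, cluster, source == "inferred")
    np.logical_or.at(has_ref, cluster, source == "reference")
    if statistic == "shared-strain-count":
        good = has_inf & has_ref
    elif statistic == "inferred-only-strain-count":
        good = ~has_ref
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return int(good[cluster].sum())


def permutation_enrichment(
    clusters: StrainClusterSet,
    statistic: Literal["shared-strain-count", "inferred-only-strain-count"] = "shared-strain-count",
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[int, float]:
    """One-sided permutation test for cluster-membership enrichment.

    The strain -> cluster assignment vector is permuted (cluster sizes
    preserved, per-strain source labels fixed) and the statistic — the
    total number of strains in shared clusters, or in clusters without
    any reference strain — is re-tallied.  The p-value uses the add-one
    estimator (1 + #{perm >= observed}) / (n_perm + 1).
    """
    if clusters.n_clusters < 2:
        raise ValueError("need at least two clusters")
    rng = np.random.default_rng(seed)
    observed = _enrichment_statistic(clusters.cluster, clusters.source, statistic)
    at_least = 0
    labels = clusters.cluster
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _enrichment_statistic(perm, clusters.source, statistic) >= observed:
            at_least += 1
    return observed, (1 + at_least) / (n_perm + 1)


def dominant_strain(pi: np.ndarray) -> np.ndarray:
    """Per-sample index of the most abundant strain (ties -> lowest index)."""
    pi = np.asarray(pi, dtype=float)
    return np.argmax(pi, axis=1)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def pairwise_ld(gamma: np.ndarray, site_pairs) -> np.ndarray:
    """r^2 (squared Pearson correlation across strains) per site pair.

    Strains are the observations.  Missing alleles are excluded
    pairwise; a pair with a monomorphic site (or fewer than two complete
    strains) gets NaN.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape[0] < 2:
        raise ValueError("need at least two strains")
    pairs = np.asarray(list(site_pairs), dtype=int)
    out = np.full(len(pairs), np.nan)
    for k, (a, b) in enumerate(pairs):
        x, y = gamma[:, a], gamma[:, b]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 2:
            continue
        xv, yv = x[ok], y[ok]
        sx, sy = xv.std(), yv.std()
        if sx == 0 or sy == 0:
            continue
        r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
        out[k] = r * r
    return out


def _r2_matrix(gamma_cols: np.ndarray) -> np.ndarray:
    """All-pairs r^2 between columns (no missing values); NaN if monomorphic."""
    X = gamma_cols - gamma_cols.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (X.T @ X) / X.shape[0]
        R = C / np.outer(sd, sd)
    R[np.isinf(R)] = np.nan
    mono = sd == 0
    R[mono, :] = np.nan
    R[:, mono] = np.nan
    return R * R


def genomewide_ld90(
    gamma: np.ndarray, positions: np.ndarray, max_positions: int = 20000, seed: int = 0
) -> float:
    """Genome-wide LD90: 90th percentile of pairwise r^2.

    Computed over all pairs among a random sample of ``max_positions``
    SNP positions (all positions if there are fewer).  Monomorphic sites
    contribute no defined pairs; NaN if fewer than two polymorphic
    positions.
    """
    gamma = np.asarray(gamma, dtype=float)
    positions = np.asarray(positions)
    G = gamma.shape[1]
    if len(positions) != G:
        raise ValueError("positions must map every site")
    idx = np.arange(G)
    if G > max_positions:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(G, size=max_positions, replace=False))
    R2 = _r2_matrix(np.nan_to_num(gamma[:, idx], nan=0.0))
    # only use genuinely polymorphic columns: recompute monomorphism on
    # the unimputed data
    sd = np.nanstd(gamma[:, idx], axis=0)
    R2[sd == 0, :] = np.nan
    R2[:, sd == 0] = np.nan
    iu = np.triu_indices(len(idx), k=1)
    vals = R2[iu]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return float("nan")
    return float(np.percentile(vals, 90))


def ld_windows(c: int = 30, max_distance: int = 10_000) -> list[tuple[int, int]]:
    """Geometric distance windows for the LD decay profile.

    Window i (1-based) spans [floor(10**((i-1)/c)), floor(10**(i/c))];
    windows are generated until the upper bound reaches ``max_distance``.
    With c = 30, 120 windows span [1, 10^4).  Where consecutive windows
    share boundary integers at small distances, pair assignment uses the
    first matching window (see :func:`ld_decay_profile`).
    """
    windows = []
    i = 1
    while True:
        lo = int(np.floor(10.0 ** ((i - 1) / c)))
        hi = int(np.floor(10.0 ** (i / c)))
        windows.append((lo, hi))
        if hi >= max_distance:
            break
        i += 1
    return windows


@dataclasses.dataclass(frozen=True)
class LDProfile:
    """Windowed LD decay profile.

    windows        : list of (lower, upper) distance bounds in bp
    pair_counts    : SNP pairs assigned to each window
    ld90           : per-window 90th percentile r^2 (NaN if empty)
    adjacent_ld90  : LD90 over consecutive polymorphic positions
    genomewide_ld90: LD90 over all sampled pairs
    ld_half_90     : smallest window midpoint where LD90 < 0.5 * adjacent_ld90
    c              : window constant
    """

    windows: list
    pair_counts: np.ndarray
    ld90: np.ndarray
    adjacent_ld90: float
    genomewide_ld90: float
    ld_half_90: float
    c: int


def ld_decay_profile(
    gamma: np.ndarray,
    positions: np.ndarray,
    c: int = 30,
    max_distance: int = 10_000,
    max_positions: int = 20000,
    seed: int = 0,
) -> LDProfile:
    """LD decay profile over geometric distance windows.

    Pairs are assigned to the first (smallest-i) window whose bounds
    contain their genomic distance; per-window LD90 is the 90th
    percentile of defined r^2 values.  Also reports the adjacent-SNP
    LD90 (consecutive polymorphic positions), the genome-wide LD90, and
    LD_1/2,90 — the smallest window midpoint at which the window LD90
    drops below half the adjacent-SNP value (NaN if it never does).
    """
    gamma = np.asarray(gamma, dtype=float)
    positions = np.asarray(positions, dtype=int)
    G = gamma.shape[1]
    if len(positions) != G:
        raise ValueError("positions must map every site")
    order = np.argsort(positions)
    gamma = gamma[:, order]
    positions = positions[order]

    idx = np.arange(G)
    if G > max_positions:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(G, size=max_positions, replace=False))
    g = gamma[:, idx]
    pos = positions[idx]
    sd = np.nanstd(g, axis=0)
    R2 = _r2_matrix(np.nan_to_num(g, nan=0.0))
    R2[sd == 0, :] = np.nan
    R2[:, sd == 0] = np.nan

    iu, ju = np.triu_indices(len(idx), k=1)
    dist = np.abs(pos[ju] - pos[iu])
    r2 = R2[iu, ju]

    windows = ld_windows(c=c, max_distance=max_distance)
    bounds = np.asarray(windows)
    # first-match window per pair: smallest i with lo <= d <= hi
    n_w = len(windows)
    win_of_pair = np.full(len(dist), -1)
    assigned = np.zeros(len(dist), dtype=bool)
    for i in range(n_w):
        lo, hi = bounds[i]
        hit = ~assigned & (dist >= lo) & (dist <= hi)
        win_of_pair[hit] = i
        assigned |= hit

    ld90 = np.full(n_w, np.nan)
    counts = np.zeros(n_w, dtype=int)
    for i in range(n_w):
        vals = r2[(win_of_pair == i) & ~np.isnan(r2)]
        counts[i] = ((win_of_pair == i)).sum()
        if len(vals) > 0:
            ld90[i] = np.percentile(vals, 90)

    poly = np.flatnonzero(sd > 0)
    if len(poly) >= 2:
        adj = _r2_pairs(g, poly[:-1], poly[1:])
        adj = adj[~np.isnan(adj)]
        adjacent = float(np.percentile(adj, 90)) if len(adj) else float("nan")
    else:
        adjacent = float("nan")

    gw_vals = r2[~np.isnan(r2)]
    gw = float(np.percentile(gw_vals, 90)) if len(gw_vals) else float("nan")

    ld_half = float("nan")
    if np.isfinite(adjacent):
        mids = bounds.mean(axis=1)
        for i in range(n_w):
            if np.isfinite(ld90[i]) and ld90[i] < 0.5 * adjacent:
                ld_half = float(mids[i])
                break
    return LDProfile(
        windows=windows,
        pair_counts=counts,
        ld90=ld90,
        adjacent_ld90=adjacent,
        genomewide_ld90=gw,
        ld_half_90=ld_half,
        c=c,
    )


def _r2_pairs(g: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray) -> np.ndarray:
    out = np.full(len(a_idx), np.nan)
    for k in range(len(a_idx)):
        x, y = g[:, a_idx[k]], g[:, b_idx[k]]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 2:
            continue
        xv, yv = x[ok], y[ok]
        if xv.std() == 0 or yv.std() == 0:
            continue
        r = np.corrcoef(xv, yv)[0, 1]
        out[k] = r * r
    return out
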