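"""Accuracy indices for comparing inferred strains to a ground truth.

Five indices, all "lower is better" and all invariant to strain
relabeling:

* mean normalized weighted UniFrac distance between the true and
  inferred strain composition of each sample, with both strain sets
  placed on one genotype-distance tree — an integrated summary of
  genotype *and* abundance error;
* mean absolute error of all-by-all pairwise Bray-Curtis
  dissimilarities between samples (beta-diversity fidelity);
* mean absolute error of per-sample Shannon entropy in bits (strain
  heterogeneity fidelity);
* abundance-weighted mean Hamming distance from each true strain to its
  best-match inferred genotype ("were the true genotypes recovered?");
* the reverse direction ("do the inferred genotypes reflect truth?").

Genotype distances are masked, normalized Hamming distances: the
fraction of disagreeing alleles over sites observed in both genotypes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .analysis import discretize


@dataclasses.dataclass(frozen=True)
class EvaluationReport:
    unifrac_error: float
    braycurtis_error: float
    entropy_error: float
    truth_to_inferred_hamming: float
    inferred_to_truth_hamming: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Genotype distances
# ---------------------------------------------------------------------------

def masked_hamming(g1, g2) -> float:
    """Fraction of disagreeing alleles over co-observed sites.

    Inputs are equal-length discrete genotype vectors; NaN marks a
    missing (unobserved) allele and is excluded from both numerator and
    denominator.  Returns NaN if no site is observed in both.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("genotypes must have equal length")
    both = ~(np.isnan(g1) | np.isnan(g2))
    n = int(both.sum())
    if n == 0:
        return float("nan")
    return float((g1[both] != g2[both]).sum() / n)


def masked_hamming_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs masked Hamming distances between rows of A and rows of B.

    Vectorized and chunked; NaN where a pair has no co-observed site.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    out = np.empty((A.shape[0], B.shape[0]))
    a_obs = ~np.isnan(A)
    b_obs = ~np.isnan(B)
    chunk = max(1, int(2e7) // max(1, B.shape[0] * A.shape[1]))
    for start in range(0, A.shape[0], chunk):
        stop = min(start + chunk, A.shape[0])
        a = A[start:stop][:, None, :]
        both = a_obs[start:stop][:, None, :] & b_obs[None, :, :]
        diff = (a != B[None, :, :]) & both
        n = both.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[start:stop] = np.where(n > 0, diff.sum(axis=-1) / np.maximum(n, 1), np.nan)
    return out


def best_match_hamming(source: np.ndarray, target: np.ndarray, weights) -> float:
    """Abundance-weighted mean best-match Hamming distance, source -> target.

    For each source strain, the minimum masked Hamming distance over all
    target strains; averaged with weights proportional to each source
    strain's total abundance mass (normalized to sum to 1).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if target.shape[0] == 0:
        raise ValueError("target genotype set is empty")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        w = np.ones(source.shape[0])
    w = w / w.sum()
    D = masked_hamming_matrix(source, target)
    best = np.nanmin(D, axis=1)
    return float((w * best).sum())


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def genotype_linkage(genotypes: np.ndarray):
    """Average-linkage tree over discrete genotypes (masked Hamming).

    Pairs with no co-observed site are assigned distance 1.  Returns the
    scipy linkage matrix.
    """
    D = masked_hamming_matrix(genotypes, genotypes)
    D = np.nan_to_num(D, nan=1.0)
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method="average")


def _weighted_unifrac_from_linkage(Z: np.ndarray, mass_a: np.ndarray, mass_b: np.ndarray) -> float:
    """Normalized weighted UniFrac on a linkage tree.

    Edge lengths are the increments between a node's merge height and
    its parent's; the distance is sum(l * |A - B|) over edges divided by
    sum(l * (A + B)), where A and B are the fractions of each
    community's mass descending through the edge.  Zero when the
    normalizer is zero (degenerate tree).
    """
    k = len(mass_a)

    def _norm(m):
        s = m.sum()
        if s <= 0:
            return m
        # avoid introducing 1-ulp asymmetries on already-normalized input
        return m if abs(s - 1.0) < 1e-9 else m / s

    a = _norm(mass_a)
    b = _norm(mass_b)
    n_nodes = 2 * k - 1
    heights = np.zeros(n_nodes)
    parent_height = np.zeros(n_nodes)
    node_a = np.zeros(n_nodes)
    node_b = np.zeros(n_nodes)
    node_a[:k] = a
    node_b[:k] = b
    for j in range(k - 1):
        c1, c2, h = int(Z[j, 0]), int(Z[j, 1]), Z[j, 2]
        heights[k + j] = h
        parent_height[c1] = h
        parent_height[c2] = h
        node_a[k + j] = node_a[c1] + node_a[c2]
        node_b[k + j] = node_b[c1] + node_b[c2]
    lengths = parent_height[: n_nodes - 1] - heights[: n_nodes - 1]  # root excluded
    num = float((lengths * np.abs(node_a - node_b)[: n_nodes - 1]).sum())
    den = float((lengths * (node_a + node_b)[: n_nodes - 1]).sum())
    if den <= 0:
        return 0.0
    return num / den


def unifrac_error(
    pi_true: np.ndarray,
    gamma_true: np.ndarray,
    pi_est: np.ndarray,
    gamma_est: np.ndarray,
) -> float:
    """Mean per-sample normalized weighted UniFrac, truth vs estimate.

    One average-linkage tree is built over the union of the (discretized)
    true and estimated genotypes; each sample's true strain masses and
    estimated strain masses are placed on the corresponding leaves.
    """
    pi_true = np.asarray(pi_true, dtype=float)
    pi_est = np.asarray(pi_est, dtype=float)
    if pi_true.shape[0] != pi_est.shape[0]:
        raise ValueError("sample sets differ between truth and estimate")
    gt = discretize(np.asarray(gamma_true, dtype=float))
    ge = discretize(np.asarray(gamma_est, dtype=float))
    if gt.shape[1] != ge.shape[1]:
        raise ValueError("genotypes must share the site set")
    union = np.vstack([gt, ge])
    if union.shape[0] < 2:
        return 0.0
    Z = genotype_linkage(union)
    s_true, s_est = gt.shape[0], ge.shape[0]
    vals = []
    for i in range(pi_true.shape[0]):
        mass_a = np.concatenate([pi_true[i], np.zeros(s_est)])
        mass_b = np.concatenate([np.zeros(s_true), pi_est[i]])
        vals.append(_weighted_unifrac_from_linkage(Z, mass_a, mass_b))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Composition indices
# ---------------------------------------------------------------------------

def braycurtis_error(pi_true: np.ndarray, pi_est: np.ndarray) -> float:
    """Mean |BC_true(i,j) - BC_est(i,j)| over unordered sample pairs."""
    pi_true = np.asarray(pi_true, dtype=float)
    pi_est = np.asarray(pi_est, dtype=float)
    if pi_true.shape[0] != pi_est.shape[0]:
        raise ValueError("sample sets differ")
    if pi_true.shape[0] < 2:
        return float("nan")
    bc_t = pdist(pi_true, metric="braycurtis")
    bc_e = pdist(pi_est, metric="braycurtis")
    return float(np.abs(bc_t - bc_e).mean())


def _shannon_bits(rows: np.ndarray) -> np.ndarray:
    p = np.asarray(rows, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(p > 0, p * np.log2(np.maximum(p, 1e-300)), 0.0)
    return -terms.sum(axis=-1)


def entropy_error(pi_true: np.ndarray, pi_est: np.ndarray) -> float:
    """Mean absolute per-sample difference in Shannon entropy (bits)."""
    pi_true = np.asarray(pi_true, dtype=float)
    pi_est = np.asarray(pi_est, dtype=float)
    if pi_true.shape[0] != pi_est.shape[0]:
        raise ValueError("sample sets differ")
    return float(np.abs(_shannon_bits(pi_true) - _shannon_bits(pi_est)).mean())


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def evaluate(
    pi_true: np.ndarray,
    gamma_true: np.ndarray,
    pi_est: np.ndarray,
    gamma_est: np.ndarray,
) -> EvaluationReport:
    """Compute all five accuracy indices of an estimate against truth."""
    pi_true = np.asarray(pi_true, dtype=float)
    pi_est = np.asarray(pi_est, dtype=float)
    gt = discretize(np.asarray(gamma_true, dtype=float))
    ge = discretize(np.asarray(gamma_est, dtype=float))
    return EvaluationReport(
        unifrac_error=unifrac_error(pi_true, gt, pi_est, ge),
        braycurtis_error=braycurtis_error(pi_true, pi_est),
        entropy_error=entropy_error(pi_true, pi_est),
        truth_to_inferred_hamming=best_match_hamming(gt, ge, pi_true.sum(axis=0)),
        inferred_to_truth_hamming=best_match_hamming(ge, gt, pi_est.sum(axis=0)),
    )
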