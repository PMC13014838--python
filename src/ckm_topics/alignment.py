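"""Cross-chain topic matching, identifiability filtering and pooling.

Independent MCMC chains recover the same profiles up to label switching
(and occasionally fail to reproduce a profile at all).  Labels are aligned
to a reference chain by solving the balanced optimal-transport problem
with uniform marginals — i.e. a minimum-cost bijection (linear assignment)
under squared Hellinger distance between topic-vocabulary rows.  Topics
that do not replicate across chains are flagged by their silhouette score
over the cloud of per-chain topic vectors, and the surviving samples are
pooled into equal-tailed credible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .topic_model import ChainSamples

__all__ = [
    "ChainEnsemble",
    "match_topics",
    "align_ensemble",
    "silhouette_filter",
    "hellinger_sq",
    "best_matched_tv",
]


class AlignmentError(ValueError):
    pass


def hellinger_sq(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Pairwise squared Hellinger distances between rows of p and rows of q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    bc = np.sqrt(p)[:, None, :] * np.sqrt(q)[None, :, :]
    return np.clip(1.0 - bc.sum(axis=2), 0.0, 1.0)


def match_topics(reference_phi: np.ndarray, other_phi: np.ndarray):
    """Minimum-cost bijection between two chains' topics.

    Returns ``(perm, cost)`` where ``perm[b] = a`` maps topic b of the
    other chain onto topic a of the reference, minimizing total squared
    Hellinger cost.  Ties are broken deterministically (lowest index) by
    the assignment solver's fixed scan order.
    """
    reference_phi = np.asarray(reference_phi, dtype=float)
    other_phi = np.asarray(other_phi, dtype=float)
    if reference_phi.shape != other_phi.shape:
        raise AlignmentError(
            f"shape mismatch: {reference_phi.shape} vs {other_phi.shape}"
        )
    cost = hellinger_sq(reference_phi, other_phi)
    rows, cols = linear_sum_assignment(cost)
    # rows is 0..K-1 in order; cols[a] = matched other-chain topic
    perm = np.empty(reference_phi.shape[0], dtype=int)
    perm[cols] = rows
    total = float(cost[rows, cols].sum())
    return perm, total


@dataclass
class ChainEnsemble:
    """Aligned chains with pooled posterior summaries."""

    chains: list[ChainSamples]          # relabeled copies
    permutations: list[np.ndarray]      # per chain, perm[b] -> reference label
    costs: list[float]
    pooled_phi_mean: np.ndarray         # (K, V)
    pooled_phi_lower: np.ndarray        # 2.5% equal-tailed
    pooled_phi_upper: np.ndarray        # 97.5%
    silhouette: np.ndarray | None = None
    robust_topics: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.pooled_phi_mean.shape[0]


def _relabel(chain: ChainSamples, perm: np.ndarray) -> ChainSamples:
    """Relabel chain topics so topic perm[b] <- b; contents untouched."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.shape[0])
    return ChainSamples(
        K=chain.K, alpha=chain.alpha, beta_h=chain.beta_h, seed=chain.seed,
        vocabulary=chain.vocabulary,
        phi_samples=chain.phi_samples[:, inv, :],
        theta_samples=(None if chain.theta_samples is None
                       else chain.theta_samples[:, :, inv]),
        loglik_trace=chain.loglik_trace,
    )


def align_ensemble(chains: list[ChainSamples], ci: float = 0.95) -> ChainEnsemble:
    """Align every chain to the first and pool samples into credible bands.

    The reference chain is chain 0; each other chain's posterior-mean phi
    is matched against the reference's, its samples relabeled, and all
    relabeled phi samples pooled into a mean and equal-tailed
    ``ci`` credible interval per (topic, vocabulary) cell.
    """
    if len(chains) < 2:
        raise AlignmentError("need >= 2 chains to align")
    K = chains[0].K
    if any(c.K != K for c in chains):
        raise AlignmentError("all chains must share the same K")
    ref = chains[0].phi_mean
    perms, costs, aligned = [], [], []
    for c in chains:
        perm, cost = match_topics(ref, c.phi_mean)
        perms.append(perm)
        costs.append(cost)
        aligned.append(_relabel(c, perm))
    pooled = np.concatenate([c.phi_samples for c in aligned], axis=0)
    lo_q, hi_q = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    return ChainEnsemble(
        chains=aligned,
        permutations=perms,
        costs=costs,
        pooled_phi_mean=pooled.mean(axis=0),
        pooled_phi_lower=np.percentile(pooled, lo_q, axis=0),
        pooled_phi_upper=np.percentile(pooled, hi_q, axis=0),
    )


def _silhouette_points(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Plain silhouette with Euclidean distance.

    Degenerate zero-width clusters (a = b = 0) score 1: a topic replicated
    bit-for-bit across chains is the tightest possible cluster.
    """
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    n = points.shape[0]
    uniq = np.unique(labels)
    s = np.empty(n)
    for i in range(n):
        same = (labels == labels[i])
        same[i] = False
        a = d[i, same].mean() if same.any() else 0.0
        b = np.inf
        for lab in uniq:
            if lab == labels[i]:
                continue
            b = min(b, d[i, labels == lab].mean())
        m = max(a, b)
        s[i] = 1.0 if m == 0 else (b - a) / m
    return s


def best_matched_tv(phi_a: np.ndarray, phi_b: np.ndarray):
    """Mean total-variation distance under the best topic matching.

    Rows of both tables must live on a common vocabulary (same column
    order).  Returns ``(mean_tv, perm)`` with ``perm[a]`` the row of
    ``phi_b`` matched to row a of ``phi_a``.
    """
    tv = 0.5 * np.abs(
        np.asarray(phi_a)[:, None, :] - np.asarray(phi_b)[None, :, :]
    ).sum(axis=2)
    rows, cols = linear_sum_assignment(tv)
    return float(tv[rows, cols].mean()), cols


def silhouette_filter(ensemble: ChainEnsemble, threshold: float = 0.1) -> ChainEnsemble:
    """Flag topics that fail to replicate across chains.

    Each chain contributes one point per topic (its posterior-mean phi
    row); points are labeled by aligned topic id and scored with the
    standard silhouette.  A topic is robust iff its mean silhouette is at
    least ``threshold``.  Returns the ensemble with ``silhouette`` and
    ``robust_topics`` filled in.
    """
    K = ensemble.K
    if K == 1:
        import warnings

        warnings.warn("silhouette undefined for K=1; retaining the single topic")
        ensemble.silhouette = np.array([1.0])
        ensemble.robust_topics = np.array([0])
        return ensemble
    points = np.concatenate([c.phi_mean for c in ensemble.chains], axis=0)
    labels = np.tile(np.arange(K), len(ensemble.chains))
    s = _silhouette_points(points, labels)
    mean_s = np.array([s[labels == k].mean() for k in range(K)])
    ensemble.silhouette = mean_s
    ensemble.robust_topics = np.nonzero(mean_s >= threshold)[0]
    return ensemble
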