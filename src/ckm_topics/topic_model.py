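"""Bayesian mixed-membership (topic) model over discretized biomarkers.

Each participant's observed biomarker levels are encoded as tokens over a
vocabulary of (feature, level) pairs and modeled as a mixture of K latent
profiles: a profile phi_k is a distribution over the vocabulary, and a
participant's loading vector theta_i (the 0-100% profile scores) mixes the
profiles.  Inference is collapsed Gibbs sampling over token-topic
assignments; missing biomarkers simply contribute no token, which is
exactly the model's conditioning on observed data — no imputation.

The module exposes the low-level sampler surface (tokenize, gibbs_sweep,
fit_chain), held-out model selection (heldout_score, select_K), a
cross-chain convergence diagnostic on loading entropies, and a
sklearn-style estimator wrapper (:class:`TopicModel`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from . import _gibbs
from .discretize import BinnedCohort

__all__ = [
    "Vocabulary",
    "Tokenized",
    "TopicModelState",
    "PosteriorSample",
    "ChainSamples",
    "tokenize",
    "gibbs_sweep",
    "fit_chain",
    "infer_theta",
    "heldout_score",
    "select_K",
    "entropy_diagnostic",
    "expand_phi",
    "loading_entropy",
    "TopicModel",
]


class TopicModelError(ValueError):
    pass


@dataclass
class Vocabulary:
    """Ordered (feature, level) pairs observed in the data."""

    entries: list[tuple[str, int]]

    def __post_init__(self):
        if len(set(self.entries)) != len(self.entries):
            raise TopicModelError("vocabulary entries must be unique")
        self.index = {e: i for i, e in enumerate(self.entries)}

    @property
    def size(self) -> int:
        return len(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Tokenized:
    """Flat token arrays: one token per observed (participant, feature)."""

    doc_ids: np.ndarray
    word_ids: np.ndarray
    n_docs: int
    vocabulary: Vocabulary
    n_empty_docs: int = 0

    @property
    def n_tokens(self) -> int:
        return self.doc_ids.shape[0]

    def doc_token_counts(self) -> np.ndarray:
        return np.bincount(self.doc_ids, minlength=self.n_docs)


def tokenize(binned: BinnedCohort) -> Tokenized:
    """Encode observed cells as tokens; missing cells contribute nothing.

    Participants with zero observed features are retained (their loading
    posterior is the prior) and counted in ``n_empty_docs``.
    """
    entries = []
    for j, feat in enumerate(binned.feature_names):
        obs_levels = np.unique(binned.levels[:, j][binned.mask[:, j]])
        entries.extend((feat, int(l)) for l in obs_levels)
    vocab = Vocabulary(entries)
    rows, cols = np.nonzero(binned.mask)
    word_ids = np.empty(rows.shape[0], dtype=np.int32)
    for t, (i, j) in enumerate(zip(rows, cols)):
        word_ids[t] = vocab.index[(binned.feature_names[j], int(binned.levels[i, j]))]
    # sort tokens by participant, then feature order (stable ordering for
    # the deterministic even/odd held-out split)
    order = np.lexsort((cols, rows))
    doc_ids = rows[order].astype(np.int32)
    word_ids = word_ids[order]
    counts = np.bincount(doc_ids, minlength=binned.n_participants)
    return Tokenized(
        doc_ids=doc_ids,
        word_ids=word_ids,
        n_docs=binned.n_participants,
        vocabulary=vocab,
        n_empty_docs=int((counts == 0).sum()),
    )


@dataclass
class TopicModelState:
    """Mutable collapsed-sampler state: assignments plus count tables."""

    K: int
    alpha: float
    beta_h: float
    tokens: Tokenized
    z: np.ndarray
    n_dk: np.ndarray
    n_kv: np.ndarray
    n_k: np.ndarray
    rng: np.random.Generator

    @classmethod
    def initialize(cls, tokens: Tokenized, K: int, alpha: float, beta_h: float,
                   seed: int) -> "TopicModelState":
        rng = np.random.default_rng(seed)
        z = rng.integers(0, K, size=tokens.n_tokens).astype(np.int32)
        n_dk = np.zeros((tokens.n_docs, K), dtype=np.int64)
        n_kv = np.zeros((K, tokens.vocabulary.size), dtype=np.int64)
        np.add.at(n_dk, (tokens.doc_ids, z), 1)
        np.add.at(n_kv, (z, tokens.word_ids), 1)
        return cls(K=K, alpha=alpha, beta_h=beta_h, tokens=tokens, z=z,
                   n_dk=n_dk, n_kv=n_kv, n_k=n_kv.sum(axis=1), rng=rng)

    def recount(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Rebuild count tables from scratch (consistency check)."""
        n_dk = np.zeros_like(self.n_dk)
        n_kv = np.zeros_like(self.n_kv)
        np.add.at(n_dk, (self.tokens.doc_ids, self.z), 1)
        np.add.at(n_kv, (self.z, self.tokens.word_ids), 1)
        return n_dk, n_kv, n_kv.sum(axis=1)

    def validate(self) -> None:
        n_dk, n_kv, n_k = self.recount()
        if not (np.array_equal(n_dk, self.n_dk) and np.array_equal(n_kv, self.n_kv)
                and np.array_equal(n_k, self.n_k)):
            raise TopicModelError("count tables inconsistent with assignments")

    def log_likelihood(self) -> float:
        """Collapsed log p(w, z | alpha, beta_h) up to data-constant terms."""
        K, V = self.K, self.tokens.vocabulary.size
        a, b = self.alpha, self.beta_h
        ll = K * (gammaln(V * b) - V * gammaln(b))
        ll += np.sum(gammaln(self.n_kv + b)) - np.sum(gammaln(self.n_k + V * b))
        n_d = self.tokens.doc_token_counts()
        ll += self.tokens.n_docs * (gammaln(K * a) - K * gammaln(a))
        ll += np.sum(gammaln(self.n_dk + a)) - np.sum(gammaln(n_d + K * a))
        return float(ll)

    def phi(self) -> np.ndarray:
        V = self.tokens.vocabulary.size
        return (self.n_kv + self.beta_h) / (self.n_k[:, None] + V * self.beta_h)

    def theta(self) -> np.ndarray:
        n_d = self.tokens.doc_token_counts()
        return (self.n_dk + self.alpha) / (n_d[:, None] + self.K * self.alpha)


def gibbs_sweep(state: TopicModelState) -> TopicModelState:
    """Reassign every token once from its collapsed conditional (in place)."""
    u = state.rng.random(state.tokens.n_tokens)
    _gibbs.sweep(state.tokens.doc_ids, state.tokens.word_ids, state.z,
                 state.n_dk, state.n_kv, state.n_k,
                 state.alpha, state.beta_h, u)
    return state


@dataclass
class PosteriorSample:
    phi: np.ndarray    # (K, V)
    theta: np.ndarray  # (n, K)


@dataclass
class ChainSamples:
    """Retained posterior samples from one Markov chain."""

    K: int
    alpha: float
    beta_h: float
    seed: int
    vocabulary: Vocabulary
    phi_samples: np.ndarray    # (S, K, V)
    theta_samples: np.ndarray  # (S, n, K) or None
    loglik_trace: np.ndarray   # per sweep

    @property
    def n_samples(self) -> int:
        return self.phi_samples.shape[0]

    @property
    def phi_mean(self) -> np.ndarray:
        return self.phi_samples.mean(axis=0)

    @property
    def theta_mean(self) -> np.ndarray:
        return self.theta_samples.mean(axis=0)

    @property
    def samples(self) -> list[PosteriorSample]:
        return [PosteriorSample(self.phi_samples[s], self.theta_samples[s])
                for s in range(self.n_samples)]


def fit_chain(binned: BinnedCohort | Tokenized, K: int, alpha: float | None = None,
              beta_h: float = 0.1, n_burn: int = 500, n_samples: int = 100,
              thin: int = 5, seed: int = 0, store_theta: bool = True) -> ChainSamples:
    """Run one collapsed-Gibbs chain and retain thinned posterior samples.

    ``alpha`` defaults to the weakly-informative symmetric 1/K.  After
    ``n_burn`` sweeps, every ``thin``-th sweep is converted to a posterior
    sample via the Rao-Blackwellized estimates
    phi_kv = (n_kv + beta_h) / (n_k + V beta_h),
    theta_dk = (n_dk + alpha) / (n_d + K alpha).
    """
    if K < 1:
        raise TopicModelError("K must be >= 1")
    if n_burn < 0 or n_samples < 1 or thin < 1:
        raise TopicModelError("MCMC lengths must be positive")
    if alpha is None:
        alpha = 1.0 / K
    tokens = binned if isinstance(binned, Tokenized) else tokenize(binned)
    state = TopicModelState.initialize(tokens, K, alpha, beta_h, seed)
    n_sweeps = n_burn + n_samples * thin
    trace = np.empty(n_sweeps)
    V = tokens.vocabulary.size
    phi_samples = np.empty((n_samples, K, V))
    theta_samples = (np.empty((n_samples, tokens.n_docs, K))
                     if store_theta else None)
    s = 0
    for sweep_i in range(n_sweeps):
        gibbs_sweep(state)
        trace[sweep_i] = state.log_likelihood()
        if sweep_i >= n_burn and (sweep_i - n_burn) % thin == thin - 1:
            phi_samples[s] = state.phi()
            if store_theta:
                theta_samples[s] = state.theta()
            s += 1
    return ChainSamples(K=K, alpha=alpha, beta_h=beta_h, seed=seed,
                        vocabulary=tokens.vocabulary, phi_samples=phi_samples[:s],
                        theta_samples=None if not store_theta else theta_samples[:s],
                        loglik_trace=trace)


def infer_theta(doc_ids: np.ndarray, word_ids: np.ndarray, n_docs: int,
                phi: np.ndarray, alpha: float, n_burn: int = 20,
                n_samples: int = 30, seed: int = 0) -> np.ndarray:
    """Fold in new participants' tokens against a fixed phi table.

    Returns the posterior-mean loading matrix (n_docs, K); participants
    with no tokens get the uniform prior mean 1/K.
    """
    K = phi.shape[0]
    rng = np.random.default_rng(seed)
    doc_ids = np.ascontiguousarray(doc_ids, dtype=np.int32)
    word_ids = np.ascontiguousarray(word_ids, dtype=np.int32)
    z = rng.integers(0, K, size=doc_ids.shape[0]).astype(np.int32)
    n_dk = np.zeros((n_docs, K), dtype=np.int64)
    np.add.at(n_dk, (doc_ids, z), 1)
    n_d = np.bincount(doc_ids, minlength=n_docs).astype(float)
    acc = np.zeros((n_docs, K))
    for it in range(n_burn + n_samples):
        u = rng.random(doc_ids.shape[0])
        _gibbs.foldin_sweep(doc_ids, word_ids, z, n_dk, phi, alpha, u)
        if it >= n_burn:
            acc += (n_dk + alpha) / (n_d[:, None] + K * alpha)
    return acc / n_samples


@dataclass
class HeldoutResult:
    mean_log_lik: float      # mean per-token predictive log-likelihood
    n_tokens_scored: int
    n_excluded: int          # validation participants with < 2 usable tokens
    n_unseen_dropped: int    # validation tokens absent from train vocabulary


def heldout_score(binned_train: BinnedCohort, binned_valid: BinnedCohort,
                  K: int, alpha: float | None = None, beta_h: float = 0.1,
                  n_burn: int = 200, n_samples: int = 20, thin: int = 2,
                  foldin_burn: int = 20, foldin_samples: int = 30,
                  seed: int = 0) -> HeldoutResult:
    """Document-completion predictive score on held-out participants.

    Fits on the training cohort; for each validation participant the
    even-indexed half of their tokens is folded in to estimate theta and
    the odd-indexed half is scored as mean log sum_k theta_k phi_kv.
    Always <= 0; higher is better.
    """
    if alpha is None:
        alpha = 1.0 / K
    chain = fit_chain(binned_train, K, alpha=alpha, beta_h=beta_h, n_burn=n_burn,
                      n_samples=n_samples, thin=thin, seed=seed, store_theta=False)
    phi = chain.phi_mean
    vocab = chain.vocabulary

    tv = tokenize(binned_valid)
    # map validation tokens into the training vocabulary
    vmap = np.full(tv.vocabulary.size, -1, dtype=np.int64)
    for e, i in tv.vocabulary.index.items():
        vmap[i] = vocab.index.get(e, -1)
    mapped = vmap[tv.word_ids]
    keep = mapped >= 0
    n_unseen = int((~keep).sum())
    doc_ids = tv.doc_ids[keep]
    word_ids = mapped[keep].astype(np.int32)

    counts = np.bincount(doc_ids, minlength=tv.n_docs)
    usable = counts >= 2
    n_excluded = int((~usable).sum())
    sel = usable[doc_ids]
    doc_ids, word_ids = doc_ids[sel], word_ids[sel]
    if doc_ids.size == 0:
        raise TopicModelError("no validation participant with >= 2 tokens")

    # even positions within each participant's token list fold in;
    # odd positions are held back for scoring
    pos = np.zeros(doc_ids.shape[0], dtype=np.int64)
    start = np.r_[True, np.diff(doc_ids) != 0]
    idx = np.arange(doc_ids.shape[0])
    first = np.maximum.accumulate(np.where(start, idx, 0))
    pos = idx - first
    fold = pos % 2 == 0
    theta = infer_theta(doc_ids[fold], word_ids[fold], tv.n_docs, phi, alpha,
                        n_burn=foldin_burn, n_samples=foldin_samples,
                        seed=seed + 1)
    ev_docs, ev_words = doc_ids[~fold], word_ids[~fold]
    p_tok = np.einsum("tk,kt->t", theta[ev_docs], phi[:, ev_words])
    return HeldoutResult(
        mean_log_lik=float(np.mean(np.log(np.maximum(p_tok, 1e-300)))),
        n_tokens_scored=int(ev_docs.size),
        n_excluded=n_excluded,
        n_unseen_dropped=n_unseen,
    )


def _subset(binned: BinnedCohort, idx: np.ndarray) -> BinnedCohort:
    return BinnedCohort(
        participant_ids=binned.participant_ids[idx],
        feature_names=binned.feature_names,
        levels=binned.levels[idx],
        mask=binned.mask[idx],
        sex=binned.sex[idx],
        n_levels=binned.n_levels,
    )


def select_K(binned: BinnedCohort, K_grid, split_seed: int = 0,
             train_fraction: float = 1.0 / 3.0, **score_kwargs):
    """Choose the number of profiles by held-out generalization.

    Participants are split train:validation at ``train_fraction`` (default
    the literal 1:2 ratio); the K in ``K_grid`` with the best
    document-completion score wins, ties broken toward smaller K.

    Returns ``(selected_K, curve)`` where curve maps K -> mean held-out
    log-likelihood.
    """
    K_grid = sorted(set(int(k) for k in K_grid))
    if not K_grid:
        raise TopicModelError("K grid is empty")
    rng = np.random.default_rng(split_seed)
    n = binned.n_participants
    perm = rng.permutation(n)
    n_train = max(1, int(round(n * train_fraction)))
    train = _subset(binned, np.sort(perm[:n_train]))
    valid = _subset(binned, np.sort(perm[n_train:]))
    curve = {}
    for K in K_grid:
        curve[K] = heldout_score(train, valid, K, seed=split_seed, **score_kwargs).mean_log_lik
    best = max(K_grid, key=lambda k: (curve[k], -k))
    return best, curve


def expand_phi(phi: np.ndarray, vocabulary: Vocabulary, feature_names: list[str],
               n_levels: int) -> np.ndarray:
    """Embed a fitted phi table into the full (feature x level) vocabulary.

    Entries never observed in the data (hence absent from the fitted
    vocabulary) get probability zero; column order is feature-major, level
    within feature, matching the generator's joint topic table.
    """
    K = phi.shape[0]
    full = np.zeros((K, len(feature_names) * n_levels))
    fidx = {f: j for j, f in enumerate(feature_names)}
    for (feat, level), col in vocabulary.index.items():
        full[:, fidx[feat] * n_levels + level] = phi[:, col]
    return full


def uniformize_feature_marginal(phi_full: np.ndarray, n_features: int,
                                n_levels: int) -> np.ndarray:
    """Rescale each feature block of a joint phi table to mass 1/F.

    Differential missingness skews the fitted topic-vocabulary joint
    toward well-observed features (they contribute more tokens); forcing a
    uniform feature marginal makes joints comparable across observation
    regimes.  Feature blocks with zero mass stay zero.
    """
    K = phi_full.shape[0]
    blocks = phi_full.reshape(K, n_features, n_levels)
    sums = blocks.sum(axis=2, keepdims=True)
    out = np.where(sums > 0, blocks / np.maximum(sums, 1e-300) / n_features, 0.0)
    return out.reshape(K, -1)


def loading_entropy(theta: np.ndarray) -> np.ndarray:
    """Shannon entropy of each loading vector (natural log)."""
    t = np.asarray(theta, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(t > 0, t * np.log(t), 0.0).sum(axis=-1)
    return h


@dataclass
class EntropyDiagnostic:
    rhat: np.ndarray          # per participant
    frac_below: float         # fraction of participants with rhat < threshold
    threshold: float
    passed: bool


def entropy_diagnostic(chains, threshold: float = 1.1,
                       pass_fraction: float = 0.99) -> EntropyDiagnostic:
    """Potential-scale-reduction of loading entropies across chains.

    ``chains`` is a list of per-chain theta sample arrays (S, n, K) or
    :class:`ChainSamples`.  For each participant the entropy of every
    retained theta sample forms one sequence per chain; the classic
    between/within variance ratio folds into the R-hat statistic.  The
    ensemble passes when at least ``pass_fraction`` of participants have
    R-hat below ``threshold``.
    """
    arrays = [c.theta_samples if isinstance(c, ChainSamples) else np.asarray(c)
              for c in chains]
    if len(arrays) < 2:
        raise TopicModelError("entropy diagnostic needs >= 2 chains")
    S = min(a.shape[0] for a in arrays)
    H = np.stack([loading_entropy(a[:S]) for a in arrays])  # (C, S, n)
    C = H.shape[0]
    chain_mean = H.mean(axis=1)                   # (C, n)
    W = H.var(axis=1, ddof=1).mean(axis=0)        # (n,)
    B = S * chain_mean.var(axis=0, ddof=1)        # (n,)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = (S - 1) / S * W + B / S
        rhat = np.sqrt(var_plus / W)
    rhat = np.where(W > 0, rhat, np.where(B > 0, np.inf, 1.0))
    frac = float(np.mean(rhat < threshold))
    return EntropyDiagnostic(rhat=rhat, frac_below=frac, threshold=threshold,
                             passed=frac >= pass_fraction)


class TopicModel(BaseEstimator):
    """Mixed-membership profile model, sklearn-style wrapper.

    Parameters mirror the sampler defaults: symmetric Dirichlet priors
    alpha (None -> 1/K) over loadings and beta_h over the vocabulary;
    ``n_chains`` independent chains seeded ``random_state + chain``.

    Attributes (after fit)
    ----------------------
    chains_ : list of ChainSamples
    vocabulary_ : Vocabulary
    components_ : (K, V) posterior-mean phi of the reference chain
    theta_mean_ : (n, K) posterior-mean loadings of the reference chain
    """

    def __init__(self, n_topics: int = 8, alpha: float | None = None,
                 beta_h: float = 0.1, n_burn: int = 500, n_samples: int = 100,
                 thin: int = 5, n_chains: int = 8, store_theta: bool = True,
                 random_state: int = 0):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta_h = beta_h
        self.n_burn = n_burn
        self.n_samples = n_samples
        self.thin = thin
        self.n_chains = n_chains
        self.store_theta = store_theta
        self.random_state = random_state

    def fit(self, X: BinnedCohort, y=None):
        tokens = tokenize(X)
        self.chains_ = [
            fit_chain(tokens, self.n_topics, alpha=self.alpha, beta_h=self.beta_h,
                      n_burn=self.n_burn, n_samples=self.n_samples, thin=self.thin,
                      seed=self.random_state + c, store_theta=self.store_theta)
            for c in range(self.n_chains)
        ]
        self.vocabulary_ = tokens.vocabulary
        self.components_ = self.chains_[0].phi_mean
        if self.store_theta:
            self.theta_mean_ = self.chains_[0].theta_mean
        return self

    def transform(self, X: BinnedCohort) -> np.ndarray:
        """Posterior-mean loadings for (possibly new) participants."""
        tv = tokenize(X)
        vmap = np.full(tv.vocabulary.size, -1, dtype=np.int64)
        for e, i in tv.vocabulary.index.items():
            vmap[i] = self.vocabulary_.index.get(e, -1)
        mapped = vmap[tv.word_ids]
        keep = mapped >= 0
        alpha = self.alpha if self.alpha is not None else 1.0 / self.n_topics
        return infer_theta(tv.doc_ids[keep], mapped[keep].astype(np.int32),
                           tv.n_docs, self.components_, alpha,
                           seed=self.random_state)

    def fit_transform(self, X: BinnedCohort, y=None) -> np.ndarray:
        self.fit(X)
        return self.theta_mean_
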