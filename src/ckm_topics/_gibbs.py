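"""Numba kernels for the collapsed Gibbs sampler.

Tokens are stored flat (one entry per observed participant-feature cell);
the kernels mutate the assignment vector and count tables in place.
Uniform draws are pre-generated per sweep by the caller so that all
randomness flows through one numpy Generator.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sweep(doc_ids, word_ids, z, n_dk, n_kv, n_k, alpha, beta, u):
    """One full collapsed-Gibbs sweep over all tokens.

    P(z=k | rest) propto (n_dk + alpha) * (n_kv + beta) / (n_k + V*beta),
    with the current token excluded from all counts.
    """
    K = n_k.shape[0]
    V = n_kv.shape[1]
    vbeta = V * beta
    cum = np.empty(K)
    for t in range(doc_ids.shape[0]):
        d = doc_ids[t]
        v = word_ids[t]
        k0 = z[t]
        n_dk[d, k0] -= 1
        n_kv[k0, v] -= 1
        n_k[k0] -= 1
        s = 0.0
        for k in range(K):
            s += (n_dk[d, k] + alpha) * (n_kv[k, v] + beta) / (n_k[k] + vbeta)
            cum[k] = s
        r = u[t] * s
        k1 = 0
        while cum[k1] < r and k1 < K - 1:
            k1 += 1
        n_dk[d, k1] += 1
        n_kv[k1, v] += 1
        n_k[k1] += 1
        z[t] = k1


@njit(cache=True)
def foldin_sweep(doc_ids, word_ids, z, n_dk, phi, alpha, u):
    """Gibbs sweep with topic-word table fixed at ``phi`` (held-out fold-in).

    P(z=k | rest) propto (n_dk + alpha) * phi[k, v].
    """
    K = phi.shape[0]
    cum = np.empty(K)
    for t in range(doc_ids.shape[0]):
        d = doc_ids[t]
        v = word_ids[t]
        k0 = z[t]
        n_dk[d, k0] -= 1
        s = 0.0
        for k in range(K):
            s += (n_dk[d, k] + alpha) * phi[k, v]
            cum[k] = s
        r = u[t] * s
        k1 = 0
        while cum[k1] < r and k1 < K - 1:
            k1 += 1
        n_dk[d, k1] += 1
        z[t] = k1
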