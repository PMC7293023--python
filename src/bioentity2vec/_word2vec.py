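"""Numba kernels: uniform random walks over CSR adjacency and a
skip-gram-with-negative-sampling (SGNS) word2vec trainer.

Single-threaded and seeded throughout, so walk corpora and embeddings are
bit-reproducible for a given seed.  The SGNS objective is the standard
word2vec one: for each (center, context) pair within a shrunken window
(word2vec's dynamic window), maximize log sigma(u_o . v_c) plus
``negative`` samples drawn from the unigram^(3/4) noise distribution, with
a linearly decaying learning rate.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _walk_kernel(indptr, indices, starts, t, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_walks = starts.shape[0]
    out = np.full((n_walks, t), -1, dtype=np.int32)
    for i in range(n_walks):
        v = starts[i]
        out[i, 0] = v
        if indptr[v + 1] == indptr[v]:
            continue  # isolated start: walk of length 1
        for step in range(1, t):
            lo, hi = indptr[v], indptr[v + 1]
            v = indices[lo + np.random.randint(hi - lo)]
            out[i, step] = v
    return out


@njit(cache=True, fastmath=True)
def _sgns_kernel(
    walks, lengths, syn0, syn1, noise_table, window, negative,
    alpha0, min_alpha, epochs, seed,
):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_walks = walks.shape[0]
    dim = syn0.shape[1]
    table_size = noise_table.shape[0]
    total_tokens = 0
    for i in range(n_walks):
        total_tokens += lengths[i]
    total_tokens *= epochs
    processed = 0
    neu1e = np.zeros(dim, dtype=np.float32)
    one = np.float32(1.0)
    zero = np.float32(0.0)

    for _ in range(epochs):
        for wi in range(n_walks):
            L = lengths[wi]
            for j in range(L):
                alpha = np.float32(
                    alpha0 - (alpha0 - min_alpha) * (processed / total_tokens)
                )
                processed += 1
                center = walks[wi, j]
                b = np.random.randint(window)  # dynamic window shrink
                lo = j - window + b
                hi = j + window - b
                if lo < 0:
                    lo = 0
                if hi > L - 1:
                    hi = L - 1
                for k in range(lo, hi + 1):
                    if k == j:
                        continue
                    context = walks[wi, k]
                    # predict context from center: update syn0[context] against
                    # syn1[center] + negatives (word2vec sg convention)
                    for d in range(dim):
                        neu1e[d] = zero
                    for neg in range(negative + 1):
                        if neg == 0:
                            target = center
                            label = one
                        else:
                            target = noise_table[np.random.randint(table_size)]
                            if target == center:
                                continue
                            label = zero
                        dot = zero
                        for d in range(dim):
                            dot += syn0[context, d] * syn1[target, d]
                        if dot > np.float32(6.0):
                            g = (label - one) * alpha
                        elif dot < np.float32(-6.0):
                            g = label * alpha
                        else:
                            g = (label - one / (one + np.exp(-dot))) * alpha
                        for d in range(dim):
                            neu1e[d] += g * syn1[target, d]
                            syn1[target, d] += g * syn0[context, d]
                    for d in range(dim):
                        syn0[context, d] += neu1e[d]
    return syn0


def build_noise_table(counts: np.ndarray, table_size: int = 1 << 17) -> np.ndarray:
    """Unigram^(3/4) sampling table (word2vec convention)."""
    p = counts.astype(np.float64) ** 0.75
    p /= p.sum()
    bounds = np.cumsum(p) * table_size
    table = np.zeros(table_size, dtype=np.int32)
    j = 0
    for i in range(table_size):
        while j < len(bounds) - 1 and i >= bounds[j]:
            j += 1
        table[i] = j
    return table
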