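"""Numba kernel for skip-gram negative-sampling training.

Single-threaded with a fully deterministic update order and an inline
xorshift64* RNG for negative sampling, so training is exactly reproducible
for a fixed seed and corpus order. Vectors are float32; the logistic
function goes through a precomputed table (clamped at |x| = 6), the same
device the reference C implementation of word2vec uses.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EXP_TABLE_SIZE = 1000
MAX_EXP = 6.0

_EXP_TABLE = (1.0 / (1.0 + np.exp(-(
    (np.arange(EXP_TABLE_SIZE, dtype=np.float64) / EXP_TABLE_SIZE * 2.0 - 1.0) * MAX_EXP
)))).astype(np.float32)


@njit(cache=True, inline="always")
def _xorshift(state):
    state ^= state << np.uint64(13)
    state ^= state >> np.uint64(7)
    state ^= state << np.uint64(17)
    return state


@njit(cache=True)
def train_epochs(
    data,        # int32[:] token indices, sentences concatenated
    offsets,     # int64[:] sentence boundaries, len = n_sentences + 1
    syn0,        # float32[|V|, dim] input (word) vectors, updated in place
    syn1,        # float32[|V|, dim] output (context) vectors
    neg_table,   # int32[:] unigram^0.75 sampling table
    epochs,      # int
    window,      # int
    itr,         # int, gradient passes per sentence mini-batch
    negative,    # int, negative samples per pair
    lr0,         # float, initial learning rate
    lr_min,      # float, final learning rate
    exp_table,   # float32[:] logistic table
    seed,        # uint64 RNG state (non-zero)
):
    dim = syn0.shape[1]
    tsize = np.int64(neg_table.shape[0])
    state = np.uint64(seed | np.uint64(1))
    # total (center, context) pair-updates, for the linear LR schedule
    total_pairs = np.int64(0)
    for s in range(offsets.shape[0] - 1):
        n = offsets[s + 1] - offsets[s]
        for i in range(n):
            lo = i - window
            if lo < 0:
                lo = 0
            hi = i + window + 1
            if hi > n:
                hi = n
            total_pairs += hi - lo - 1
    total_updates = total_pairs * epochs * itr
    if total_updates == 0:
        return
    neu1e = np.zeros(dim, dtype=np.float32)
    upd = np.int64(0)
    for _ep in range(epochs):
        for s in range(offsets.shape[0] - 1):
            lo_s = offsets[s]
            hi_s = offsets[s + 1]
            for _it in range(itr):
                for ci in range(lo_s, hi_s):
                    center = data[ci]
                    jlo = ci - window
                    if jlo < lo_s:
                        jlo = lo_s
                    jhi = ci + window + 1
                    if jhi > hi_s:
                        jhi = hi_s
                    for cj in range(jlo, jhi):
                        if cj == ci:
                            continue
                        context = data[cj]
                        lr = np.float32(
                            lr0 + (lr_min - lr0) * (upd / total_updates)
                        )
                        upd += 1
                        for d in range(dim):
                            neu1e[d] = 0.0
                        for k in range(negative + 1):
                            if k == 0:
                                target = context
                                label = np.float32(1.0)
                            else:
                                state = _xorshift(state)
                                target = neg_table[np.int64(state % np.uint64(tsize))]
                                if target == context:
                                    continue
                                label = np.float32(0.0)
                            f = np.float32(0.0)
                            for d in range(dim):
                                f += syn0[center, d] * syn1[target, d]
                            if f > MAX_EXP:
                                g = (label - np.float32(1.0)) * lr
                            elif f < -MAX_EXP:
                                g = label * lr
                            else:
                                idx = np.int64(
                                    (f + MAX_EXP) * (EXP_TABLE_SIZE / (2.0 * MAX_EXP))
                                )
                                g = (label - exp_table[idx]) * lr
                            for d in range(dim):
                                neu1e[d] += g * syn1[target, d]
                            for d in range(dim):
                                syn1[target, d] += g * syn0[center, d]
                        for d in range(dim):
                            syn0[center, d] += neu1e[d]


def exp_table() -> np.ndarray:
    return _EXP_TABLE
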