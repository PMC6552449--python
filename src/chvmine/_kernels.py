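"""Numba-jitted inner loops for the embedding trainers.

Single-threaded by construction: given a fixed seed the trained matrices are
bit-reproducible.  The kernels implement the standard published objectives —
skip-gram / CBOW with negative sampling, GloVe's weighted least squares on
log co-occurrence with AdaGrad, and the subword-sum input representation for
the FastText variant — over pre-encoded integer token streams.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_MAX_EXP = 8.0


@njit(cache=False, fastmath=False)
def _sigmoid(x):
    if x > _MAX_EXP:
        return 1.0
    if x < -_MAX_EXP:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


@njit(cache=False, fastmath=False)
def _sample_negative(cdf):
    u = np.random.random()
    lo, hi = 0, cdf.shape[0] - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cdf[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=False, fastmath=False)
def train_sgns(
    data,
    offsets,
    syn0,
    syn1,
    window,
    negative,
    epochs,
    alpha0,
    min_alpha,
    neg_cdf,
    cbow,
    seed,
):
    """Skip-gram (cbow=0) or CBOW (cbow=1) with negative sampling.

    ``data`` is the concatenated token-id stream, ``offsets`` the message
    boundaries.  ``syn0`` (input vectors) and ``syn1`` (output vectors) are
    updated in place; the learning rate decays linearly from ``alpha0`` to
    ``min_alpha`` over all epochs.
    """
    np.random.seed(seed)
    dim = syn0.shape[1]
    neu1 = np.empty(dim, dtype=syn0.dtype)
    work = np.empty(dim, dtype=syn0.dtype)
    total_words = data.shape[0] * epochs
    words_done = 0
    n_sent = offsets.shape[0] - 1
    for _ep in range(epochs):
        for si in range(n_sent):
            start = offsets[si]
            end = offsets[si + 1]
            for i in range(start, end):
                words_done += 1
                frac = words_done / total_words
                alpha = alpha0 - (alpha0 - min_alpha) * frac
                if alpha < min_alpha:
                    alpha = min_alpha
                b = np.random.randint(1, window + 1)
                lo = i - b
                if lo < start:
                    lo = start
                hi = i + b + 1
                if hi > end:
                    hi = end
                center = data[i]
                if cbow == 1:
                    cnt = 0
                    for d in range(dim):
                        neu1[d] = 0.0
                    for j in range(lo, hi):
                        if j == i:
                            continue
                        cw = data[j]
                        for d in range(dim):
                            neu1[d] += syn0[cw, d]
                        cnt += 1
                    if cnt == 0:
                        continue
                    for d in range(dim):
                        neu1[d] /= cnt
                        work[d] = 0.0
                    for n_i in range(negative + 1):
                        if n_i == 0:
                            target = center
                            label = 1.0
                        else:
                            target = _sample_negative(neg_cdf)
                            if target == center:
                                continue
                            label = 0.0
                        f = 0.0
                        for d in range(dim):
                            f += neu1[d] * syn1[target, d]
                        g = (label - _sigmoid(f)) * alpha
                        for d in range(dim):
                            work[d] += g * syn1[target, d]
                            syn1[target, d] += g * neu1[d]
                    for j in range(lo, hi):
                        if j == i:
                            continue
                        cw = data[j]
                        for d in range(dim):
                            syn0[cw, d] += work[d]
                else:
                    for j in range(lo, hi):
                        if j == i:
                            continue
                        ctx = data[j]
                        for d in range(dim):
                            work[d] = 0.0
                        for n_i in range(negative + 1):
                            if n_i == 0:
                                target = ctx
                                label = 1.0
                            else:
                                target = _sample_negative(neg_cdf)
                                if target == ctx:
                                    continue
                                label = 0.0
                            f = 0.0
                            for d in range(dim):
                                f += syn0[center, d] * syn1[target, d]
                            g = (label - _sigmoid(f)) * alpha
                            for d in range(dim):
                                work[d] += g * syn1[target, d]
                                syn1[target, d] += g * syn0[center, d]
                        for d in range(dim):
                            syn0[center, d] += work[d]


@njit(cache=False, fastmath=False)
def train_sgns_subword(
    data,
    offsets,
    syn0,
    syn1,
    syn_sub,
    sub_idx,
    sub_off,
    window,
    negative,
    epochs,
    alpha0,
    min_alpha,
    neg_cdf,
    seed,
):
    """Skip-gram negative sampling where the input representation of a word
    is the average of its word vector and its character n-gram bucket
    vectors (FastText-style)."""
    np.random.seed(seed)
    dim = syn0.shape[1]
    vin = np.empty(dim, dtype=syn0.dtype)
    work = np.empty(dim, dtype=syn0.dtype)
    total_words = data.shape[0] * epochs
    words_done = 0
    n_sent = offsets.shape[0] - 1
    for _ep in range(epochs):
        for si in range(n_sent):
            start = offsets[si]
            end = offsets[si + 1]
            for i in range(start, end):
                words_done += 1
                frac = words_done / total_words
                alpha = alpha0 - (alpha0 - min_alpha) * frac
                if alpha < min_alpha:
                    alpha = min_alpha
                b = np.random.randint(1, window + 1)
                lo = i - b
                if lo < start:
                    lo = start
                hi = i + b + 1
                if hi > end:
                    hi = end
                center = data[i]
                s0 = sub_off[center]
                s1 = sub_off[center + 1]
                n_parts = 1 + (s1 - s0)
                for d in range(dim):
                    vin[d] = syn0[center, d]
                for k in range(s0, s1):
                    g_id = sub_idx[k]
                    for d in range(dim):
                        vin[d] += syn_sub[g_id, d]
                for d in range(dim):
                    vin[d] /= n_parts
                for j in range(lo, hi):
                    if j == i:
                        continue
                    ctx = data[j]
                    for d in range(dim):
                        work[d] = 0.0
                    for n_i in range(negative + 1):
                        if n_i == 0:
                            target = ctx
                            label = 1.0
                        else:
                            target = _sample_negative(neg_cdf)
                            if target == ctx:
                                continue
                            label = 0.0
                        f = 0.0
                        for d in range(dim):
                            f += vin[d] * syn1[target, d]
                        g = (label - _sigmoid(f)) * alpha
                        for d in range(dim):
                            work[d] += g * syn1[target, d]
                            syn1[target, d] += g * vin[d]
                    for d in range(dim):
                        upd = work[d] / n_parts
                        syn0[center, d] += upd
                        vin[d] += upd
                    for k in range(s0, s1):
                        g_id = sub_idx[k]
                        for d in range(dim):
                            syn_sub[g_id, d] += work[d] / n_parts


@njit(cache=False, fastmath=False)
def train_glove(
    i_idx,
    j_idx,
    x_val,
    w_main,
    w_ctx,
    b_main,
    b_ctx,
    epochs,
    lr,
    x_max,
    alpha,
    seed,
):
    """AdaGrad on the GloVe objective: weighted squared error between
    w_i . w~_j + b_i + b~_j and log X_ij over the nonzero co-occurrences."""
    np.random.seed(seed)
    dim = w_main.shape[1]
    nnz = x_val.shape[0]
    gw_main = np.ones_like(w_main)
    gw_ctx = np.ones_like(w_ctx)
    gb_main = np.ones_like(b_main)
    gb_ctx = np.ones_like(b_ctx)
    order = np.arange(nnz)
    for _ep in range(epochs):
        for k in range(nnz - 1, 0, -1):
            r = np.random.randint(0, k + 1)
            tmp = order[k]
            order[k] = order[r]
            order[r] = tmp
        for t in range(nnz):
            idx = order[t]
            i = i_idx[idx]
            j = j_idx[idx]
            x = x_val[idx]
            wgt = (x / x_max) ** alpha
            if wgt > 1.0:
                wgt = 1.0
            dot = b_main[i] + b_ctx[j]
            for d in range(dim):
                dot += w_main[i, d] * w_ctx[j, d]
            fdiff = wgt * (dot - math.log(x))
            for d in range(dim):
                gi = fdiff * w_ctx[j, d]
                gj = fdiff * w_main[i, d]
                gw_main[i, d] += gi * gi
                gw_ctx[j, d] += gj * gj
                w_main[i, d] -= lr * gi / math.sqrt(gw_main[i, d])
                w_ctx[j, d] -= lr * gj / math.sqrt(gw_ctx[j, d])
            gb_main[i] += fdiff * fdiff
            gb_ctx[j] += fdiff * fdiff
            b_main[i] -= lr * fdiff / math.sqrt(gb_main[i])
            b_ctx[j] -= lr * fdiff / math.sqrt(gb_ctx[j])
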