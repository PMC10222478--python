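"""Minimal deterministic regression forest for tiny training sets.

The ensemble corrector trains thousands of small random forests (one
per batch, target metabolite, hyperparameter combination and CV fold) on
a handful of QC rows each.  General-purpose implementations spend far
more time in per-tree bookkeeping than in the actual split search at
this size, so the base model is a compact numba kernel: CART regression
trees (variance-reduction splits, grown to purity), bootstrap resampling
and per-node feature subsampling -- the standard random-forest recipe --
with an explicit xorshift RNG so results are bit-reproducible from the
seed alone.  Fit and prediction are fused; the caller keeps the seed,
not the trees.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True)
def _xorshift(x):
    x ^= (x << np.uint64(13)) & _MASK
    x ^= x >> np.uint64(7)
    x ^= (x << np.uint64(17)) & _MASK
    return x


@njit(cache=True)
def _rf_kernel(Xtr, ytr, Xte, n_trees, mtry, state):
    n, p = Xtr.shape
    m = Xte.shape[0]
    out = np.zeros(m)
    max_nodes = 4 * n + 8
    feat = np.empty(max_nodes, np.int64)
    thr = np.empty(max_nodes)
    left = np.empty(max_nodes, np.int64)
    right = np.empty(max_nodes, np.int64)
    val = np.empty(max_nodes)
    idx_buf = np.empty(n * (max_nodes + 1), np.int64)
    fperm = np.empty(p, np.int64)
    seg_start = np.empty(max_nodes, np.int64)
    seg_end = np.empty(max_nodes, np.int64)
    node_of = np.empty(max_nodes, np.int64)
    for _ in range(n_trees):
        for i in range(n):  # bootstrap resample
            state = _xorshift(state)
            idx_buf[i] = int(state % np.uint64(n))
        n_nodes = 1
        feat[0] = -1
        seg_start[0] = 0
        seg_end[0] = n
        node_of[0] = 0
        top = 1
        write_ptr = n
        while top > 0:
            top -= 1
            s, e, nid = seg_start[top], seg_end[top], node_of[top]
            cnt = e - s
            sy = 0.0
            for i in range(s, e):
                sy += ytr[idx_buf[i]]
            val[nid] = sy / cnt
            pure = True
            for i in range(s, e):
                if ytr[idx_buf[i]] != ytr[idx_buf[s]]:
                    pure = False
                    break
            if cnt < 2 or pure:
                feat[nid] = -1
                continue
            for j in range(p):
                fperm[j] = j
            best_feat = -1
            best_thr = 0.0
            best_score = np.inf
            for j in range(mtry):  # partial Fisher-Yates feature draw
                state = _xorshift(state)
                k = j + int(state % np.uint64(p - j))
                fperm[j], fperm[k] = fperm[k], fperm[j]
                f = fperm[j]
                for i in range(s, e):
                    v = Xtr[idx_buf[i], f]
                    syl = 0.0
                    syl2 = 0.0
                    sl = 0
                    syr = 0.0
                    syr2 = 0.0
                    sr = 0
                    for qq in range(s, e):
                        yv = ytr[idx_buf[qq]]
                        if Xtr[idx_buf[qq], f] <= v:
                            syl += yv
                            syl2 += yv * yv
                            sl += 1
                        else:
                            syr += yv
                            syr2 += yv * yv
                            sr += 1
                    if sl == 0 or sr == 0:
                        continue
                    score = (syl2 - syl * syl / sl) + (syr2 - syr * syr / sr)
                    if score < best_score:
                        best_score = score
                        best_feat = f
                        best_thr = v
            if best_feat < 0:
                feat[nid] = -1
                continue
            ls = write_ptr
            for i in range(s, e):
                if Xtr[idx_buf[i], best_feat] <= best_thr:
                    idx_buf[write_ptr] = idx_buf[i]
                    write_ptr += 1
            le = write_ptr
            for i in range(s, e):
                if Xtr[idx_buf[i], best_feat] > best_thr:
                    idx_buf[write_ptr] = idx_buf[i]
                    write_ptr += 1
            re = write_ptr
            feat[nid] = best_feat
            thr[nid] = best_thr
            lid, rid = n_nodes, n_nodes + 1
            n_nodes += 2
            left[nid], right[nid] = lid, rid
            feat[lid] = -1
            feat[rid] = -1
            seg_start[top], seg_end[top], node_of[top] = ls, le, lid
            top += 1
            seg_start[top], seg_end[top], node_of[top] = le, re, rid
            top += 1
        for i in range(m):
            nid = 0
            while feat[nid] >= 0:
                nid = left[nid] if Xte[i, feat[nid]] <= thr[nid] else right[nid]
            out[i] += val[nid]
    return out / n_trees


def rf_fit_predict(X_train, y_train, X_pred, n_trees: int, max_features: float,
                   seed: int) -> np.ndarray:
    """Train a regression forest and predict in one call.

    Parameters
    ----------
    X_train, y_train
        Training rows (finite values only).
    X_pred
        Rows to predict.
    n_trees : int
    max_features : float
        Fraction of features examined per split (``ceil(frac * p)``).
    seed : int
        Fully determines bootstrap and feature draws.
    """
    Xtr = np.ascontiguousarray(X_train, dtype=np.float64)
    ytr = np.ascontiguousarray(y_train, dtype=np.float64)
    Xte = np.ascontiguousarray(X_pred, dtype=np.float64)
    if Xtr.ndim != 2 or Xtr.shape[0] != ytr.shape[0]:
        raise ValueError("inconsistent training shapes")
    if Xte.shape[1] != Xtr.shape[1]:
        raise ValueError("feature count mismatch between train and predict")
    if n_trees < 1:
        raise ValueError("n_trees must be positive")
    if not 0 < max_features <= 1:
        raise ValueError("max_features must be in (0, 1]")
    mtry = max(1, int(np.ceil(max_features * Xtr.shape[1])))
    state = np.uint64(seed) * np.uint64(2654435761) + np.uint64(88172645463325252)
    return _rf_kernel(Xtr, ytr, Xte, int(n_trees), mtry, state)
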