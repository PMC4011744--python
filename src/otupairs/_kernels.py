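"""Numba kernels for the curveball Markov chain.

The matrix is held as a padded row-list representation: ``rowlist[r, :k]``
are the occupied column indices of row ``r`` where ``k = rowlen[r]``. Row
sums never change under curveball trades, so ``rowlen`` is constant and the
padding width is the maximum row sum of the observed matrix.

Numba's per-thread RNG is seeded inside each entry-point kernel, so results
are reproducible for a given seed and independent of numpy's global state.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _trade(rowlist, rowlen, r1, r2, shared, pool):
    """One curveball trade between rows r1 and r2 (in place).

    The columns occupied by exactly one of the two rows are pooled and
    re-dealt uniformly at random, keeping each row's total fixed.
    """
    k1 = rowlen[r1]
    k2 = rowlen[r2]
    ns = 0
    npool = 0
    for a in range(k1):
        c = rowlist[r1, a]
        found = False
        for b in range(k2):
            if rowlist[r2, b] == c:
                found = True
                break
        if found:
            shared[ns] = c
            ns += 1
        else:
            pool[npool] = c
            npool += 1
    n_ex1 = npool
    for b in range(k2):
        c = rowlist[r2, b]
        found = False
        for a in range(k1):
            if rowlist[r1, a] == c:
                found = True
                break
        if not found:
            pool[npool] = c
            npool += 1
    n_ex2 = npool - n_ex1
    if n_ex1 == 0 or n_ex2 == 0:
        return
    # Fisher-Yates shuffle of the pooled exclusive columns
    for i in range(npool - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = pool[i]
        pool[i] = pool[j]
        pool[j] = tmp
    for a in range(ns):
        rowlist[r1, a] = shared[a]
        rowlist[r2, a] = shared[a]
    for a in range(n_ex1):
        rowlist[r1, ns + a] = pool[a]
    for a in range(n_ex2):
        rowlist[r2, ns + a] = pool[n_ex1 + a]


@njit(cache=True)
def _steps(rowlist, rowlen, n_steps, shared, pool):
    n_rows = rowlist.shape[0]
    for _ in range(n_steps):
        r1 = np.random.randint(0, n_rows)
        r2 = np.random.randint(0, n_rows)
        if r1 == r2:
            continue
        _trade(rowlist, rowlen, r1, r2, shared, pool)


@njit(cache=True)
def curveball_chain(rowlist, rowlen, n_steps, seed):
    """Advance the chain ``n_steps`` trades from a fresh seed (in place)."""
    np.random.seed(seed)
    width = rowlist.shape[1]
    shared = np.empty(width, dtype=rowlist.dtype)
    pool = np.empty(2 * width, dtype=rowlist.dtype)
    _steps(rowlist, rowlen, n_steps, shared, pool)


@njit(cache=True)
def chain_pair_s(rowlist, rowlen, burn_in, thin, m, pair_index, n_pairs, seed):
    """Run the chain and record per-pair co-occurrence counts S.

    ``pair_index`` is a symmetric (n_otus x n_otus) int32 matrix mapping a
    column pair to its slot in the output (or -1). Returns an (m, n_pairs)
    int32 array of S values, one row per saved ensemble member.
    """
    np.random.seed(seed)
    n_rows = rowlist.shape[0]
    width = rowlist.shape[1]
    shared = np.empty(width, dtype=rowlist.dtype)
    pool = np.empty(2 * width, dtype=rowlist.dtype)
    out = np.zeros((m, n_pairs), dtype=np.int32)
    _steps(rowlist, rowlen, burn_in, shared, pool)
    for t in range(m):
        _steps(rowlist, rowlen, thin, shared, pool)
        for r in range(n_rows):
            k = rowlen[r]
            for a in range(k):
                ca = rowlist[r, a]
                for b in range(a + 1, k):
                    cb = rowlist[r, b]
                    p = pair_index[ca, cb]
                    if p >= 0:
                        out[t, p] += 1
    return out


@njit(cache=True)
def chain_matrices(rowlist, rowlen, burn_in, thin, m, n_cols, seed):
    """Run the chain and materialize m dense 0/1 matrices (small inputs)."""
    np.random.seed(seed)
    n_rows = rowlist.shape[0]
    width = rowlist.shape[1]
    shared = np.empty(width, dtype=rowlist.dtype)
    pool = np.empty(2 * width, dtype=rowlist.dtype)
    out = np.zeros((m, n_rows, n_cols), dtype=np.uint8)
    _steps(rowlist, rowlen, burn_in, shared, pool)
    for t in range(m):
        _steps(rowlist, rowlen, thin, shared, pool)
        for r in range(n_rows):
            for a in range(rowlen[r]):
                out[t, r, rowlist[r, a]] = 1
    return out
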