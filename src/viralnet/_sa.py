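"""Numba kernels for simulated-annealing optimisation of Barber modularity.

The graph is a CSR adjacency over a canonical node ordering; labels are
module ids in [0, n).  Only cross-class co-membership contributes to Q, so
moving a genome node only interacts with family-degree sums and vice versa.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def q_total(indptr, indices, labels, is_genome, k, L):
    n = k.shape[0]
    kg = np.zeros(n)
    kf = np.zeros(n)
    e = np.zeros(n)
    for u in range(n):
        lab = labels[u]
        if is_genome[u]:
            kg[lab] += k[u]
            for idx in range(indptr[u], indptr[u + 1]):
                if labels[indices[idx]] == lab:
                    e[lab] += 1.0
        else:
            kf[lab] += k[u]
    q = 0.0
    for m in range(n):
        q += e[m] / L - kg[m] * kf[m] / (L * L)
    return q


@njit(cache=True)
def _count_label(indptr, indices, labels, u, lab):
    c = 0
    for idx in range(indptr[u], indptr[u + 1]):
        if labels[indices[idx]] == lab:
            c += 1
    return c


@njit(cache=True)
def _delta_q(indptr, indices, labels, is_genome, k, kg, kf, L, u, b):
    a = labels[u]
    ca = _count_label(indptr, indices, labels, u, a)
    cb = _count_label(indptr, indices, labels, u, b)
    if is_genome[u]:
        return (cb - ca) / L - k[u] * (kf[b] - kf[a]) / (L * L)
    return (cb - ca) / L - k[u] * (kg[b] - kg[a]) / (L * L)


@njit(cache=True)
def _apply_move(labels, is_genome, k, kg, kf, size, u, b):
    a = labels[u]
    if is_genome[u]:
        kg[a] -= k[u]
        kg[b] += k[u]
    else:
        kf[a] -= k[u]
        kf[b] += k[u]
    size[a] -= 1
    size[b] += 1
    labels[u] = b


@njit(cache=True)
def _find_free(size, start):
    n = size.shape[0]
    for off in range(n):
        lab = (start + off) % n
        if size[lab] == 0:
            return lab
    return start


@njit(cache=True)
def _init_sums(labels, is_genome, k, kg, kf, size):
    kg[:] = 0.0
    kf[:] = 0.0
    size[:] = 0
    for u in range(labels.shape[0]):
        if is_genome[u]:
            kg[labels[u]] += k[u]
        else:
            kf[labels[u]] += k[u]
        size[labels[u]] += 1


@njit(cache=True)
def greedy_sweep(indptr, indices, labels, is_genome, k, kg, kf, size, L):
    """Hill-climb single-node moves (to neighbour modules or a fresh one)
    until no move improves Q.  Deterministic node order."""
    n = labels.shape[0]
    improved = True
    gain = 0.0
    while improved:
        improved = False
        for u in range(n):
            if indptr[u + 1] == indptr[u]:
                continue
            a = labels[u]
            best_dq = 1e-12
            best_b = a
            for idx in range(indptr[u], indptr[u + 1]):
                b = labels[indices[idx]]
                if b == a:
                    continue
                dq = _delta_q(indptr, indices, labels, is_genome, k, kg, kf, L, u, b)
                if dq > best_dq:
                    best_dq = dq
                    best_b = b
            if size[a] > 1:
                fresh = _find_free(size, u)
                dq = _delta_q(indptr, indices, labels, is_genome, k, kg, kf, L, u, fresh)
                if dq > best_dq:
                    best_dq = dq
                    best_b = fresh
            if best_b != a:
                _apply_move(labels, is_genome, k, kg, kf, size, u, best_b)
                gain += best_dq
                improved = True
    return gain


@njit(cache=True)
def anneal(
    indptr,
    indices,
    is_genome,
    k,
    L,
    seed,
    t0,
    cooling,
    moves_per_t,
    patience,
    t_min,
    p_new,
    max_blocks,
):
    """Metropolis annealing from the all-singletons partition.

    Returns the best label vector seen (after a final greedy polish) and
    its modularity.
    """
    np.random.seed(seed)
    n = k.shape[0]
    labels = np.arange(n, dtype=np.int64)
    kg = np.zeros(n)
    kf = np.zeros(n)
    size = np.zeros(n, dtype=np.int64)
    _init_sums(labels, is_genome, k, kg, kf, size)
    q = 0.0  # all-singleton partition has Q = 0
    best_q = q
    best = labels.copy()
    t = t0
    stale = 0
    for _block in range(max_blocks):
        block_improved = False
        for _step in range(moves_per_t):
            u = np.random.randint(0, n)
            if indptr[u + 1] == indptr[u]:
                continue
            if np.random.random() < p_new:
                if size[labels[u]] == 1:
                    continue
                b = _find_free(size, np.random.randint(0, n))
            else:
                idx = indptr[u] + np.random.randint(0, indptr[u + 1] - indptr[u])
                b = labels[indices[idx]]
            a = labels[u]
            if b == a:
                continue
            dq = _delta_q(indptr, indices, labels, is_genome, k, kg, kf, L, u, b)
            if dq > 0.0 or np.random.random() < np.exp(dq / t):
                _apply_move(labels, is_genome, k, kg, kf, size, u, b)
                q += dq
                if q > best_q + 1e-12:
                    best_q = q
                    best[:] = labels
                    block_improved = True
        t *= cooling
        if block_improved:
            stale = 0
        else:
            stale += 1
        if stale >= patience or t < t_min:
            break
    labels = best
    _init_sums(labels, is_genome, k, kg, kf, size)
    greedy_sweep(indptr, indices, labels, is_genome, k, kg, kf, size, L)
    return labels, q_total(indptr, indices, labels, is_genome, k, L)


@njit(cache=True)
def calibrate_t0(indptr, indices, is_genome, k, L, seed, n_probe):
    """Temperature at which a typical uphill (Q-decreasing) move is accepted
    with probability ~1/2, probed from the all-singletons partition."""
    np.random.seed(seed)
    n = k.shape[0]
    labels = np.arange(n, dtype=np.int64)
    kg = np.zeros(n)
    kf = np.zeros(n)
    size = np.zeros(n, dtype=np.int64)
    _init_sums(labels, is_genome, k, kg, kf, size)
    total = 0.0
    count = 0
    for _ in range(n_probe):
        u = np.random.randint(0, n)
        if indptr[u + 1] == indptr[u]:
            continue
        idx = indptr[u] + np.random.randint(0, indptr[u + 1] - indptr[u])
        b = labels[indices[idx]]
        if b == labels[u]:
            continue
        dq = _delta_q(indptr, indices, labels, is_genome, k, kg, kf, L, u, b)
        if dq < 0.0:
            total += -dq
            count += 1
        # random walk so probes see varied configurations
        _apply_move(labels, is_genome, k, kg, kf, size, u, b)
    if count == 0:
        return 2.0 / L
    return (total / count) / np.log(2.0)
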