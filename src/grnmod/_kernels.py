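"""Compiled inner loops (numba).

Everything here is an implementation detail behind :mod:`grnmod.core`,
:mod:`grnmod.modularity` and :mod:`grnmod.fitness`.  States are bit-coded as
integers (bit ``j`` set = gene ``j`` active); genotypes are packed into three
base-3 int64 chunks so that (genotype, initial state) -> attractor lookups can
be memoised in a numba typed dict across generations.  The packing supports
up to 100 matrix entries, i.e. networks of at most 10 genes; larger networks
take the uncompiled path in :mod:`grnmod.fitness`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: maximum network size supported by the table-based fitness kernel
MAX_KERNEL_GENES = 14

#: table entry meaning "attractor not yet computed for this initial state"
UNKNOWN = np.int16(-2)
#: table entry meaning "trajectory enters a cycle"
CYCLIC = np.int16(-1)


def new_attractor_table(n_genes: int) -> np.ndarray:
    """Fresh per-genotype (initial state -> fixed point) lookup table."""
    return np.full(2 ** n_genes, UNKNOWN, dtype=np.int16)


@njit(cache=True)
def attractor_int(W, s_int, max_steps, stamps, version):
    """Attractor of the threshold dynamics from bit-coded state ``s_int``.

    Returns the bit-coded fixed point, or -1 if the trajectory enters a
    cycle (or ``max_steps`` is exhausted).  ``stamps``/``version`` implement
    a reset-free visited set over the 2^N state space.
    """
    N = W.shape[0]
    cur = s_int
    stamps[cur] = version
    for _ in range(max_steps):
        nxt = np.int64(0)
        for i in range(N):
            tot = 0
            for j in range(N):
                wij = W[i, j]
                if wij != 0:
                    if (cur >> j) & 1:
                        tot += wij
                    else:
                        tot -= wij
            if tot > 0:
                nxt |= np.int64(1) << i
        if nxt == cur:
            return cur
        if stamps[nxt] == version:
            return np.int64(-1)
        stamps[nxt] = version
        cur = nxt
    return np.int64(-1)


@njit(cache=True)
def genotype_gammas(W, targets, flips, p, exponent, max_steps, table, stamps, version0):
    """Mean trajectory contributions of one genotype for each target.

    W        : (N, N) int8 interaction matrix
    targets  : (T, N) int8 ±1 reference patterns
    flips    : (T, R, N) float32 uniforms; gene flipped where < p
    table    : (2^N,) int16 memo of initial state -> fixed point
               (UNKNOWN = not yet computed, CYCLIC = cycle)
    returns  : ((T,) float64 mean gamma, updated version counter)

    Trajectories reaching a fixed point A contribute
    (1 - D_H(A, target)/N) ** exponent; cyclic attractors contribute 0.
    """
    N = W.shape[0]
    T = targets.shape[0]
    R = flips.shape[1]
    gammas = np.zeros(T)
    version = version0
    for ti in range(T):
        acc = 0.0
        for ri in range(R):
            s_int = np.int64(0)
            for j in range(N):
                bit = 1 if targets[ti, j] > 0 else 0
                if flips[ti, ri, j] < p:
                    bit ^= 1
                if bit == 1:
                    s_int |= np.int64(1) << j
            a16 = table[s_int]
            if a16 == UNKNOWN:
                version += 1
                a_int = attractor_int(W, s_int, max_steps, stamps, version)
                table[s_int] = np.int16(a_int)
                a16 = table[s_int]
            if a16 >= 0:
                a_int = np.int64(a16)
                d_h = 0
                for j in range(N):
                    abit = (a_int >> j) & 1
                    tbit = 1 if targets[ti, j] > 0 else 0
                    if abit != tbit:
                        d_h += 1
                acc += (1.0 - d_h / N) ** exponent
        gammas[ti] = acc / R
    return gammas, version


# ---------------------------------------------------------------------------
# Newman modularity: Q evaluation, greedy + refinement partitioner, exhaustive
# oracle, degree-preserving rewiring.
# ---------------------------------------------------------------------------


@njit(cache=True)
def q_of_labels(A, deg, L, labels):
    """Newman's Q of a labelled partition on adjacency matrix ``A``."""
    n = A.shape[0]
    ls = np.zeros(n)
    ds = np.zeros(n)
    for v in range(n):
        ds[labels[v]] += deg[v]
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j] != 0 and labels[i] == labels[j]:
                ls[labels[i]] += 1.0
    q = 0.0
    Lf = float(L)
    for s in range(n):
        q += ls[s] / Lf - (ds[s] / (2.0 * Lf)) ** 2
    return q


@njit(cache=True)
def _refine_labels(A, deg, L, labels):
    """Hill-climb ``labels`` in place: single-node moves (including splits to
    an empty label) and pairwise module merges, until no move increases Q.
    Ties keep the incumbent; candidate order is lowest-index-first, so the
    result is deterministic."""
    n = A.shape[0]
    tol = 1e-12
    Lf = float(L)
    improved = True
    while improved:
        improved = False
        moved = True
        while moved:
            moved = False
            for v in range(n):
                a = labels[v]
                evl = np.zeros(n)
                dls = np.zeros(n)
                for u in range(n):
                    dls[labels[u]] += deg[u]
                    if u != v and A[v, u] != 0:
                        evl[labels[u]] += 1.0
                e_va = evl[a]
                d_a = dls[a]
                best_dq = tol
                best_b = -1
                seen_empty = False
                for b in range(n):
                    if b == a:
                        continue
                    if dls[b] == 0.0 and evl[b] == 0.0:
                        if seen_empty:
                            continue
                        seen_empty = True
                    dq = (evl[b] - e_va) / Lf - deg[v] * (dls[b] - d_a + deg[v]) / (2.0 * Lf * Lf)
                    if dq > best_dq:
                        best_dq = dq
                        best_b = b
                if best_b >= 0:
                    labels[v] = best_b
                    moved = True
                    improved = True
        merged = True
        while merged:
            merged = False
            est = np.zeros((n, n))
            ds = np.zeros(n)
            occupied = np.zeros(n, dtype=np.bool_)
            for v in range(n):
                ds[labels[v]] += deg[v]
                occupied[labels[v]] = True
            for i in range(n):
                for j in range(i + 1, n):
                    if A[i, j] != 0 and labels[i] != labels[j]:
                        est[labels[i], labels[j]] += 1.0
                        est[labels[j], labels[i]] += 1.0
            best_dq = tol
            bs = -1
            bt = -1
            for s in range(n):
                if not occupied[s]:
                    continue
                for t in range(s + 1, n):
                    if not occupied[t]:
                        continue
                    dq = est[s, t] / Lf - ds[s] * ds[t] / (2.0 * Lf * Lf)
                    if dq > best_dq:
                        best_dq = dq
                        bs = s
                        bt = t
            if bs >= 0:
                for v in range(n):
                    if labels[v] == bt:
                        labels[v] = bs
                merged = True
                improved = True
    return q_of_labels(A, deg, L, labels)


@njit(cache=True)
def _kl_chain(A, deg, L, labels):
    """One Kernighan-Lin pass: greedily apply the best single-node move at
    each step (accepting losses), each node moved at most once, and keep the
    best partition seen along the chain.  Returns True if Q improved."""
    n = A.shape[0]
    Lf = float(L)
    cur = labels.copy()
    cur_q = q_of_labels(A, deg, L, cur)
    start_q = cur_q
    best_q = cur_q
    best = labels.copy()
    moved = np.zeros(n, dtype=np.bool_)
    for _ in range(n):
        best_dq = -1.0e18
        best_v = -1
        best_b = -1
        dls = np.zeros(n)
        for u in range(n):
            dls[cur[u]] += deg[u]
        for v in range(n):
            if moved[v]:
                continue
            a = cur[v]
            evl = np.zeros(n)
            for u in range(n):
                if u != v and A[v, u] != 0:
                    evl[cur[u]] += 1.0
            e_va = evl[a]
            d_a = dls[a]
            seen_empty = False
            for b in range(n):
                if b == a:
                    continue
                if dls[b] == 0.0 and evl[b] == 0.0:
                    if seen_empty:
                        continue
                    seen_empty = True
                dq = (evl[b] - e_va) / Lf - deg[v] * (dls[b] - d_a + deg[v]) / (2.0 * Lf * Lf)
                if dq > best_dq:
                    best_dq = dq
                    best_v = v
                    best_b = b
        if best_v < 0:
            break
        cur[best_v] = best_b
        moved[best_v] = True
        cur_q += best_dq
        if cur_q > best_q + 1e-12:
            best_q = cur_q
            best = cur.copy()
    if best_q > start_q + 1e-12:
        for v in range(n):
            labels[v] = best[v]
        return True
    return False


@njit(cache=True)
def _polish_labels(A, deg, L, labels):
    """Refinement sweeps alternated with KL chains until neither improves."""
    q = _refine_labels(A, deg, L, labels)
    while _kl_chain(A, deg, L, labels):
        q = _refine_labels(A, deg, L, labels)
    return q


@njit(cache=True)
def _greedy_labels(A, deg, L):
    """CNM-style agglomeration from singletons; returns the labelling at the
    Q-maximum along the merge sequence (ties: lowest module pair first)."""
    n = A.shape[0]
    est = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and A[i, j] != 0:
                est[i, j] = 1.0
    ds = deg.astype(np.float64)
    active = np.ones(n, dtype=np.bool_)
    cur = np.arange(n)
    q = q_of_labels(A, deg, L, cur)
    best_q = q
    best = cur.copy()
    Lf = float(L)
    for _ in range(n - 1):
        best_dq = -1.0e18
        bs = -1
        bt = -1
        for s in range(n):
            if not active[s]:
                continue
            for t in range(s + 1, n):
                if not active[t]:
                    continue
                dq = est[s, t] / Lf - ds[s] * ds[t] / (2.0 * Lf * Lf)
                if dq > best_dq:
                    best_dq = dq
                    bs = s
                    bt = t
        if bs < 0:
            break
        for v in range(n):
            if cur[v] == bt:
                cur[v] = bs
        for u in range(n):
            if u != bs and u != bt and active[u]:
                est[bs, u] += est[bt, u]
                est[u, bs] = est[bs, u]
        ds[bs] += ds[bt]
        active[bt] = False
        q += best_dq
        if q > best_q + 1e-12:
            best_q = q
            best = cur.copy()
    return best


@njit(cache=True)
def best_partition_kernel(A, deg, L, n_restarts=8):
    """Q-maximizing partition.

    Candidates: singleton, greedy-agglomerative and one-module starts plus
    ``n_restarts`` pseudo-random starts (fixed-seed LCG, so the search is
    deterministic); each candidate is polished by node-move/merge refinement
    alternated with Kernighan-Lin chains.  The best polished candidate wins;
    earlier candidates win ties.  Returns (labels relabelled by first
    occurrence, Q).
    """
    n = A.shape[0]
    best = np.arange(n)
    bq = _polish_labels(A, deg, L, best)
    lab2 = _greedy_labels(A, deg, L)
    q2 = _polish_labels(A, deg, L, lab2)
    if q2 > bq + 1e-12:
        best = lab2
        bq = q2
    lab3 = np.zeros(n, dtype=np.int64)
    q3 = _polish_labels(A, deg, L, lab3)
    if q3 > bq + 1e-12:
        best = lab3
        bq = q3
    state = np.uint64(0x9E3779B97F4A7C15)
    for _ in range(n_restarts):
        lab4 = np.empty(n, dtype=np.int64)
        state = state * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
        k = 2 + np.int64((state >> np.uint64(33)) % np.uint64(max(n - 1, 1)))
        for v in range(n):
            state = state * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
            lab4[v] = np.int64((state >> np.uint64(33)) % np.uint64(k))
        q4 = _polish_labels(A, deg, L, lab4)
        if q4 > bq + 1e-12:
            best = lab4
            bq = q4
    out = np.empty(n, dtype=np.int64)
    mapping = -np.ones(n, dtype=np.int64)
    nxt = 0
    for v in range(n):
        lab = best[v]
        if mapping[lab] < 0:
            mapping[lab] = nxt
            nxt += 1
        out[v] = mapping[lab]
    return out, bq


@njit(cache=True)
def exhaustive_best_kernel(edges, deg, n, L):
    """Exact Q optimum by enumerating every set partition of ``n`` nodes
    (restricted growth strings).  Intended for n <= 12."""
    a = np.zeros(n, dtype=np.int64)
    mx = np.zeros(n, dtype=np.int64)  # mx[i] = max(a[0..i-1])
    best_q = -2.0
    best = a.copy()
    m = edges.shape[0]
    ls = np.zeros(n)
    ds = np.zeros(n)
    Lf = float(L)
    while True:
        for s in range(n):
            ls[s] = 0.0
            ds[s] = 0.0
        for v in range(n):
            ds[a[v]] += deg[v]
        for e in range(m):
            if a[edges[e, 0]] == a[edges[e, 1]]:
                ls[a[edges[e, 0]]] += 1.0
        q = 0.0
        for s in range(n):
            q += ls[s] / Lf - (ds[s] / (2.0 * Lf)) ** 2
        if q > best_q + 1e-12:
            best_q = q
            best = a.copy()
        i = n - 1
        while i > 0 and a[i] > mx[i]:
            i -= 1
        if i == 0:
            break
        a[i] += 1
        for j in range(i + 1, n):
            a[j] = 0
            mx[j] = mx[j - 1] if mx[j - 1] > a[j - 1] else a[j - 1]
    return best, best_q


@njit(cache=True)
def double_edge_swap_kernel(edges, adj, rand):
    """Degree-preserving double-edge swaps, in place.

    Each row of ``rand`` (uniform [0,1) triples) proposes one swap: two edge
    slots and one of the two re-pairings.  Proposals creating self-loops or
    duplicate edges are skipped, so the graph stays simple and every node
    keeps its degree.
    """
    m = edges.shape[0]
    for k in range(rand.shape[0]):
        i = int(rand[k, 0] * m)
        j = int(rand[k, 1] * m)
        if i == j:
            continue
        a = edges[i, 0]
        b = edges[i, 1]
        c = edges[j, 0]
        d = edges[j, 1]
        if rand[k, 2] < 0.5:
            x1, y1, x2, y2 = a, d, c, b
        else:
            x1, y1, x2, y2 = a, c, b, d
        if x1 == y1 or x2 == y2:
            continue
        if (x1 == x2 and y1 == y2) or (x1 == y2 and y1 == x2):
            continue
        if adj[x1, y1] != 0 or adj[x2, y2] != 0:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[x1, y1] = 1
        adj[y1, x1] = 1
        adj[x2, y2] = 1
        adj[y2, x2] = 1
        edges[i, 0] = x1
        edges[i, 1] = y1
        edges[j, 0] = x2
        edges[j, 1] = y2


@njit(cache=True)
def null_q_kernel(edges0, n, L, rand):
    """Q of the best partition for each of ``rand.shape[0]`` independent
    degree-preserving rewirings of the graph given by ``edges0``."""
    n_null = rand.shape[0]
    qs = np.empty(n_null)
    deg = np.zeros(n, dtype=np.int64)
    m = edges0.shape[0]
    for e in range(m):
        deg[edges0[e, 0]] += 1
        deg[edges0[e, 1]] += 1
    for t in range(n_null):
        edges = edges0.copy()
        adj = np.zeros((n, n), dtype=np.int8)
        for e in range(m):
            adj[edges[e, 0], edges[e, 1]] = 1
            adj[edges[e, 1], edges[e, 0]] = 1
        double_edge_swap_kernel(edges, adj, rand[t])
        _labels, q = best_partition_kernel(adj, deg, L)
        qs[t] = q
    return qs
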