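"""Numba kernels for the dynamic-programming passes and the simulator.

All kernels take dense ``(S, S)`` transition and ``(S, A)`` emission tables
with state 0 = Start and state S-1 = End (both silent) and an int64 symbol
index array.  The linear-memory kernels retain only the previous position's
column of DP values together with one cumulative count table per current
state, and report the total bytes of those retained buffers so callers can
assert sequence-length independence.  Stochastic kernels draw from numba's
own seeded legacy ``np.random`` stream (``np.random.seed`` at kernel entry),
which is independent of NumPy's Python-level global state.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -np.inf
_HASH_MULT = np.uint64(1099511628211)  # FNV prime; rolling path hash


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

@njit(cache=False)
def _simulate_kernel(trans, emit, exact_length, cap, max_tries, seed):
    np.random.seed(seed)
    S = trans.shape[0]
    A = emit.shape[1]
    end = S - 1
    states = np.empty(cap, dtype=np.int64)
    syms = np.empty(cap, dtype=np.int64)
    for _trial in range(max_tries):
        # sample the first state from the Start row
        cur = 0
        pos = 0
        dead = False
        while True:
            # transition step
            u = np.random.random()
            acc = 0.0
            nxt = -1
            last_pos = -1
            for j in range(S):
                if trans[cur, j] > 0.0:
                    last_pos = j
                acc += trans[cur, j]
                if u < acc:
                    nxt = j
                    break
            if nxt < 0:
                if last_pos < 0:
                    return states[:0], syms[:0], 2  # dead-end state
                nxt = last_pos  # numerical slack in the row sum
            cur = nxt
            if cur == end:
                break
            if pos >= cap:
                dead = True  # overshoot: reject this trial
                break
            # emission step
            u = np.random.random()
            acc = 0.0
            y = -1
            last_pos = -1
            for a in range(A):
                if emit[cur, a] > 0.0:
                    last_pos = a
                acc += emit[cur, a]
                if u < acc:
                    y = a
                    break
            if y < 0:
                y = last_pos
            states[pos] = cur
            syms[pos] = y
            pos += 1
        if dead:
            continue
        if exact_length >= 0 and pos != exact_length:
            continue
        return states[:pos].copy(), syms[:pos].copy(), 0
    return states[:0], syms[:0], 1  # retry budget exhausted


def simulate(trans, emit, exact_length, cap, max_tries, seed):
    states, syms, status = _simulate_kernel(
        np.ascontiguousarray(trans), np.ascontiguousarray(emit),
        exact_length, cap, max_tries, seed)
    return states, syms, int(status)


# --------------------------------------------------------------------------
# Viterbi: linear-memory one-pass counts
# --------------------------------------------------------------------------

@njit(cache=False)
def viterbi_linear(log_t, log_e, obs):
    """One-pass Viterbi path counts with O(M x #coordinates) retained state.

    Returns ``(T, E, log_v_end, path_hash, retained_nbytes, ok)`` where T/E
    are the transition/emission counts of the Viterbi path (ties broken
    toward the lowest previous-state index), ``log_v_end`` its log
    probability, and ``path_hash`` a rolling hash of the implied traceback
    path (for strict path-identity convergence checks).
    """
    S = log_t.shape[0]
    A = log_e.shape[1]
    L = obs.size
    end = S - 1
    v_prev = np.full(S, NEG_INF)
    v_prev[0] = 0.0
    v_new = np.full(S, NEG_INF)
    Tc = np.zeros((S, S, S))
    Ec = np.zeros((S, S, A))
    Tn = np.zeros((S, S, S))
    En = np.zeros((S, S, A))
    h_prev = np.zeros(S, dtype=np.uint64)
    h_new = np.zeros(S, dtype=np.uint64)
    nbytes = (v_prev.nbytes + v_new.nbytes + Tc.nbytes + Tn.nbytes
              + Ec.nbytes + En.nbytes + h_prev.nbytes + h_new.nbytes)

    for k in range(L):
        y = obs[k]
        for m in range(1, end):
            best = NEG_INF
            l = -1
            for n in range(end):  # End has no outgoing transitions
                s = v_prev[n] + log_t[n, m]
                if s > best:
                    best = s
                    l = n
            if l < 0:
                v_new[m] = NEG_INF
                continue
            v_new[m] = best + log_e[m, y]
            for i in range(S):
                for j in range(S):
                    Tn[m, i, j] = Tc[l, i, j]
                for a in range(A):
                    En[m, i, a] = Ec[l, i, a]
            Tn[m, l, m] += 1.0
            En[m, m, y] += 1.0
            h_new[m] = h_prev[l] * _HASH_MULT + np.uint64(m)
        v_prev, v_new = v_new, v_prev
        Tc, Tn = Tn, Tc
        Ec, En = En, Ec
        h_prev, h_new = h_new, h_prev
        for m in range(S):
            v_new[m] = NEG_INF

    best = NEG_INF
    l = -1
    for n in range(1, end):
        s = v_prev[n] + log_t[n, end]
        if s > best:
            best = s
            l = n
    T = np.zeros((S, S))
    E = np.zeros((S, A))
    if l < 0 or best == NEG_INF:
        return T, E, NEG_INF, np.uint64(0), nbytes, 0
    for i in range(S):
        for j in range(S):
            T[i, j] = Tc[l, i, j]
        for a in range(A):
            E[i, a] = Ec[l, i, a]
    T[l, end] += 1.0
    path_hash = h_prev[l] * _HASH_MULT + np.uint64(end)
    return T, E, best, path_hash, nbytes, 1


# --------------------------------------------------------------------------
# Viterbi: classical full matrix + traceback
# --------------------------------------------------------------------------

@njit(cache=False)
def viterbi_full(log_t, log_e, obs):
    """Two-step Viterbi: full (L+1, S) matrix, then traceback.

    Same tie-break (lowest previous-state index) as :func:`viterbi_linear`.
    Returns ``(path, log_v_end, ok)`` with ``path`` the emitting states at
    positions 1..L.
    """
    S = log_t.shape[0]
    L = obs.size
    end = S - 1
    v = np.full((L + 1, S), NEG_INF)
    bp = np.full((L + 1, S), -1, dtype=np.int64)
    v[0, 0] = 0.0
    for k in range(1, L + 1):
        y = obs[k - 1]
        for m in range(1, end):
            best = NEG_INF
            l = -1
            for n in range(end):
                s = v[k - 1, n] + log_t[n, m]
                if s > best:
                    best = s
                    l = n
            if l >= 0:
                v[k, m] = best + log_e[m, y]
                bp[k, m] = l
    best = NEG_INF
    l = -1
    for n in range(1, end):
        s = v[L, n] + log_t[n, end]
        if s > best:
            best = s
            l = n
    path = np.empty(L, dtype=np.int64)
    if l < 0 or best == NEG_INF:
        return path[:0], NEG_INF, 0
    cur = l
    for k in range(L, 0, -1):
        path[k - 1] = cur
        cur = bp[k, cur]
    return path, best, 1


# --------------------------------------------------------------------------
# forward algorithm (scaled) — full matrix
# --------------------------------------------------------------------------

@njit(cache=False)
def forward_full(trans, emit, obs):
    """Scaled forward matrix.

    Returns ``(fhat, c, log_p, ok)``: ``fhat[k, m]`` is the forward value
    scaled by the product of per-position factors ``c[1..k]``, and
    ``log_p = sum_k log c_k + log(sum_n fhat[L, n] t[n, End])``.
    """
    S = trans.shape[0]
    L = obs.size
    end = S - 1
    fhat = np.zeros((L + 1, S))
    c = np.ones(L + 1)
    fhat[0, 0] = 1.0
    log_p = 0.0
    for k in range(1, L + 1):
        y = obs[k - 1]
        tot = 0.0
        for m in range(1, end):
            s = 0.0
            for n in range(end):
                s += fhat[k - 1, n] * trans[n, m]
            val = emit[m, y] * s
            fhat[k, m] = val
            tot += val
        if tot <= 0.0:
            return fhat, c, NEG_INF, 0
        c[k] = tot
        for m in range(1, end):
            fhat[k, m] /= tot
        log_p += math.log(tot)
    px = 0.0
    for n in range(1, end):
        px += fhat[L, n] * trans[n, end]
    if L == 0:
        px = trans[0, end]
    if px <= 0.0:
        return fhat, c, NEG_INF, 0
    log_p += math.log(px)
    return fhat, c, log_p, 1


# --------------------------------------------------------------------------
# stochastic EM: linear-memory one-pass sampling counts
# --------------------------------------------------------------------------

@njit(cache=False)
def sem_linear(trans, emit, obs, K, seed):
    """One-pass posterior path-count sampler (K independent chains).

    At every position and reachable state the previous state is sampled
    from the stochastic back-tracing distribution (proportional to
    ``f_n(k-1) t[n, m]``) and each chain's per-current-state cumulative
    count tables are advanced; at the End termination the chain counts are
    the transition/emission counts of one path drawn from P(path | X).

    Returns ``(T, E, log_p, retained_nbytes, ok)`` with ``T`` of shape
    ``(K, S, S)`` and ``E`` of shape ``(K, S, A)``.
    """
    np.random.seed(seed)
    S = trans.shape[0]
    A = emit.shape[1]
    L = obs.size
    end = S - 1
    f_prev = np.zeros(S)
    f_prev[0] = 1.0
    f_new = np.zeros(S)
    w = np.zeros(S)
    Tc = np.zeros((K, S, S, S))
    Ec = np.zeros((K, S, S, A))
    Tn = np.zeros((K, S, S, S))
    En = np.zeros((K, S, S, A))
    nbytes = (f_prev.nbytes + f_new.nbytes + w.nbytes
              + Tc.nbytes + Tn.nbytes + Ec.nbytes + En.nbytes)
    T = np.zeros((K, S, S))
    E = np.zeros((K, S, A))
    log_p = 0.0
    for k in range(L):
        y = obs[k]
        tot = 0.0
        for m in range(1, end):
            wsum = 0.0
            for n in range(end):
                w[n] = f_prev[n] * trans[n, m]
                wsum += w[n]
            val = emit[m, y] * wsum
            f_new[m] = val
            tot += val
            if val <= 0.0 or wsum <= 0.0:
                continue
            for ch in range(K):
                u = np.random.random() * wsum
                acc = 0.0
                l = -1
                for n in range(end):
                    if w[n] > 0.0:
                        acc += w[n]
                        l = n
                        if u < acc:
                            break
                for i in range(S):
                    for j in range(S):
                        Tn[ch, m, i, j] = Tc[ch, l, i, j]
                    for a in range(A):
                        En[ch, m, i, a] = Ec[ch, l, i, a]
                Tn[ch, m, l, m] += 1.0
                En[ch, m, m, y] += 1.0
        if tot <= 0.0:
            return T, E, NEG_INF, nbytes, 0
        for m in range(1, end):
            f_new[m] /= tot
        f_new[0] = 0.0
        log_p += math.log(tot)
        f_prev, f_new = f_new, f_prev
        Tc, Tn = Tn, Tc
        Ec, En = En, Ec
    # termination in the silent End state (no emission increment)
    wsum = 0.0
    for n in range(1, end):
        w[n] = f_prev[n] * trans[n, end]
        wsum += w[n]
    if wsum <= 0.0:
        return T, E, NEG_INF, nbytes, 0
    log_p += math.log(wsum)
    for ch in range(K):
        u = np.random.random() * wsum
        acc = 0.0
        l = -1
        for n in range(1, end):
            if w[n] > 0.0:
                acc += w[n]
                l = n
                if u < acc:
                    break
        for i in range(S):
            for j in range(S):
                T[ch, i, j] = Tc[ch, l, i, j]
            for a in range(A):
                E[ch, i, a] = Ec[ch, l, i, a]
        T[ch, l, end] += 1.0
    return T, E, log_p, nbytes, 1


# --------------------------------------------------------------------------
# Baum-Welch: linear-memory one-pass expected counts
# --------------------------------------------------------------------------

@njit(cache=False)
def bw_linear(trans, emit, obs):
    """One-pass posterior-expected counts by predecessor-weighted mixing.

    The per-current-state cumulative count tables of the sampling algorithm
    are replaced by their expectations: each new table is the mixture of
    the predecessors' tables under the stochastic back-tracing
    distribution.  At termination the End-state table equals the
    forward-backward expected transition/emission counts.

    Returns ``(T, E, log_p, retained_nbytes, ok)``.
    """
    S = trans.shape[0]
    A = emit.shape[1]
    L = obs.size
    end = S - 1
    f_prev = np.zeros(S)
    f_prev[0] = 1.0
    f_new = np.zeros(S)
    w = np.zeros(S)
    Tc = np.zeros((S, S, S))
    Ec = np.zeros((S, S, A))
    Tn = np.zeros((S, S, S))
    En = np.zeros((S, S, A))
    nbytes = (f_prev.nbytes + f_new.nbytes + w.nbytes
              + Tc.nbytes + Tn.nbytes + Ec.nbytes + En.nbytes)
    T = np.zeros((S, S))
    E = np.zeros((S, A))
    log_p = 0.0
    for k in range(L):
        y = obs[k]
        tot = 0.0
        for m in range(1, end):
            wsum = 0.0
            for n in range(end):
                w[n] = f_prev[n] * trans[n, m]
                wsum += w[n]
            val = emit[m, y] * wsum
            f_new[m] = val
            tot += val
            if val <= 0.0 or wsum <= 0.0:
                continue
            for i in range(S):
                for j in range(S):
                    Tn[m, i, j] = 0.0
                for a in range(A):
                    En[m, i, a] = 0.0
            for n in range(end):
                if w[n] <= 0.0:
                    continue
                r = w[n] / wsum
                for i in range(S):
                    for j in range(S):
                        Tn[m, i, j] += r * Tc[n, i, j]
                    for a in range(A):
                        En[m, i, a] += r * Ec[n, i, a]
                Tn[m, n, m] += r
            En[m, m, y] += 1.0
        if tot <= 0.0:
            return T, E, NEG_INF, nbytes, 0
        for m in range(1, end):
            f_new[m] /= tot
        f_new[0] = 0.0
        log_p += math.log(tot)
        f_prev, f_new = f_new, f_prev
        Tc, Tn = Tn, Tc
        Ec, En = En, Ec
    wsum = 0.0
    for n in range(1, end):
        w[n] = f_prev[n] * trans[n, end]
        wsum += w[n]
    if wsum <= 0.0:
        return T, E, NEG_INF, nbytes, 0
    log_p += math.log(wsum)
    for n in range(1, end):
        if w[n] <= 0.0:
            continue
        r = w[n] / wsum
        for i in range(S):
            for j in range(S):
                T[i, j] += r * Tc[n, i, j]
            for a in range(A):
                E[i, a] += r * Ec[n, i, a]
        T[n, end] += r
    return T, E, log_p, nbytes, 1
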