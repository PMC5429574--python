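"""Compiled inner loops for the scaled forward-backward and Viterbi recursions.

All kernels take dense float64 parameter arrays and an int64 observation
vector; probabilities are kept in scaled space (per-position normalizers) so
no product over the sequence length ever underflows.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_scaled(startprob, transmat, emissionprob, obs):
    """Scaled forward pass.

    Returns (alpha, c): alpha[t] is the forward vector normalized to sum to 1
    and c[t] its normalizer, so log P(O|model) = sum(log c).
    """
    T = obs.shape[0]
    n = startprob.shape[0]
    alpha = np.empty((T, n))
    c = np.empty(T)
    s = 0.0
    for i in range(n):
        a = startprob[i] * emissionprob[i, obs[0]]
        alpha[0, i] = a
        s += a
    c[0] = s
    for i in range(n):
        alpha[0, i] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(n):
            acc = 0.0
            for i in range(n):
                acc += alpha[t - 1, i] * transmat[i, j]
            v = acc * emissionprob[j, obs[t]]
            alpha[t, j] = v
            s += v
        c[t] = s
        for j in range(n):
            alpha[t, j] /= s
    return alpha, c


@njit(cache=True)
def backward_scaled(transmat, emissionprob, obs, c):
    """Scaled backward pass using the forward normalizers c.

    beta[T-1] = 1; beta[t, i] = sum_j a_ij b_j(o_{t+1}) beta[t+1, j] / c[t+1],
    so gamma_t = alpha_t * beta_t sums to 1 at every t.
    """
    T = obs.shape[0]
    n = transmat.shape[0]
    beta = np.empty((T, n))
    for i in range(n):
        beta[T - 1, i] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += transmat[i, j] * emissionprob[j, obs[t + 1]] * beta[t + 1, j]
            beta[t, i] = acc / c[t + 1]
    return beta


@njit(cache=True)
def bw_accumulate(startprob, transmat, emissionprob, obs):
    """One E-pass over a sequence: sufficient statistics for Baum-Welch.

    Returns (loglik, gamma1, trans_num, gamma_nolast, emit_num, gamma_sum):
    gamma1 = posterior at t=0; trans_num[i,j] = sum_{t<T-1} xi_t(i,j);
    gamma_nolast[i] = sum_{t<T-1} gamma_t(i); emit_num[i,k] = sum_{t: o_t=k}
    gamma_t(i); gamma_sum[i] = sum_t gamma_t(i).
    """
    T = obs.shape[0]
    n, m = emissionprob.shape
    alpha, c = forward_scaled(startprob, transmat, emissionprob, obs)
    beta = backward_scaled(transmat, emissionprob, obs, c)
    gamma1 = np.empty(n)
    trans_num = np.zeros((n, n))
    gamma_nolast = np.zeros(n)
    emit_num = np.zeros((n, m))
    gamma_sum = np.zeros(n)
    for i in range(n):
        gamma1[i] = alpha[0, i] * beta[0, i]
    for t in range(T):
        o = obs[t]
        for i in range(n):
            g = alpha[t, i] * beta[t, i]
            emit_num[i, o] += g
            gamma_sum[i] += g
            if t < T - 1:
                gamma_nolast[i] += g
    for t in range(T - 1):
        o1 = obs[t + 1]
        inv_c = 1.0 / c[t + 1]
        for i in range(n):
            ai = alpha[t, i]
            for j in range(n):
                trans_num[i, j] += (
                    ai * transmat[i, j] * emissionprob[j, o1] * beta[t + 1, j] * inv_c
                )
    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t])
    return loglik, gamma1, trans_num, gamma_nolast, emit_num, gamma_sum


@njit(cache=True)
def viterbi_path(log_start, log_trans, log_emit, obs):
    """Most probable state path in log space; ties break to the lower index.

    Returns (path, best_log_prob).
    """
    T = obs.shape[0]
    n = log_start.shape[0]
    delta = np.empty((T, n))
    psi = np.zeros((T, n), dtype=np.int64)
    for i in range(n):
        delta[0, i] = log_start[i] + log_emit[i, obs[0]]
    for t in range(1, T):
        for j in range(n):
            best = delta[t - 1, 0] + log_trans[0, j]
            arg = 0
            for i in range(1, n):
                v = delta[t - 1, i] + log_trans[i, j]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = i
            delta[t, j] = best + log_emit[j, obs[t]]
            psi[t, j] = arg
    best = delta[T - 1, 0]
    last = 0
    for i in range(1, n):
        if delta[T - 1, i] > best:
            best = delta[T - 1, i]
            last = i
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = last
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
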