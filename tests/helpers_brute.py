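"""Independent brute-force oracles: exhaustive path enumeration for HMM
quantities, direct-series Poisson tails, and an independent probability floor.

Everything here is deliberately naive (O(n^T) enumeration, term-by-term
series) so it shares no code path with the package implementation.
"""

import itertools
import math

import numpy as np


def path_probability(pi, A, B, obs, path):
    p = pi[path[0]] * B[path[0], obs[0]]
    for t in range(1, len(obs)):
        p *= A[path[t - 1], path[t]] * B[path[t], obs[t]]
    return p


def enum_likelihood(pi, A, B, obs):
    """P(O | model) by summing over every hidden state path."""
    n = len(pi)
    return sum(path_probability(pi, A, B, obs, path)
               for path in itertools.product(range(n), repeat=len(obs)))


def enum_posteriors(pi, A, B, obs):
    """(gamma, xi) by enumeration; gamma[t, i], xi[t, i, j]."""
    n, T = len(pi), len(obs)
    gamma = np.zeros((T, n))
    xi = np.zeros((T - 1, n, n))
    Z = 0.0
    for path in itertools.product(range(n), repeat=T):
        p = path_probability(pi, A, B, obs, path)
        Z += p
        for t, s in enumerate(path):
            gamma[t, s] += p
        for t in range(T - 1):
            xi[t, path[t], path[t + 1]] += p
    return gamma / Z, xi / Z


def enum_viterbi(pi, A, B, obs):
    """(best path, best probability); ties break to the lexicographically
    smallest path (matches lowest-state-index tie-breaking)."""
    n = len(pi)
    best_p, best_path = -1.0, None
    for path in itertools.product(range(n), repeat=len(obs)):
        p = path_probability(pi, A, B, obs, path)
        if p > best_p:
            best_p, best_path = p, path
    return best_path, best_p


def enum_em_step(pi, A, B, obs_list):
    """One EM re-estimation computed from enumerated posteriors (no floor)."""
    n, m = B.shape
    pi_acc = np.zeros(n)
    a_num = np.zeros((n, n))
    a_den = np.zeros(n)
    b_num = np.zeros((n, m))
    b_den = np.zeros(n)
    for obs in obs_list:
        gamma, xi = enum_posteriors(pi, A, B, obs)
        pi_acc += gamma[0]
        a_num += xi.sum(axis=0)
        a_den += gamma[:-1].sum(axis=0)
        for t, o in enumerate(obs):
            b_num[:, o] += gamma[t]
        b_den += gamma.sum(axis=0)
    return (pi_acc / len(obs_list),
            a_num / a_den[:, None],
            b_num / b_den[:, None])


def apply_floor(rows, floor):
    """Independent re-implementation of floored row renormalization."""
    rows = np.atleast_2d(np.array(rows, dtype=float)).copy()
    for r in rows:
        r /= r.sum()
        while (r < floor).any():
            low = r < floor
            r[~low] *= (1.0 - floor * low.sum()) / r[~low].sum()
            r[low] = floor
    return rows


def poisson_tail(c, lam):
    """Pr[X >= c] under Poisson(lam) by direct series summation."""
    if c <= 0:
        return 1.0
    term = math.exp(-lam)
    cdf = term
    for k in range(1, c):
        term *= lam / k
        cdf += term
    return 1.0 - cdf


def random_toy_model(rng, n, m, floor=1e-12):
    """Dirichlet(1) toy parameters as plain arrays."""
    pi = apply_floor(rng.dirichlet(np.ones(n)), floor)[0]
    A = apply_floor(rng.dirichlet(np.ones(n), size=n), floor)
    B = apply_floor(rng.dirichlet(np.ones(m), size=n), floor)
    return pi, A, B
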