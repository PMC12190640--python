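"""Numerical kernels for the Gaussian-emission HMM.

Scaled forward/backward recursions and Viterbi decoding, compiled with
numba for per-trace fitting speed.  All kernels are pure functions of
their array arguments; the EM driver lives in :mod:`ribofret.hmm`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward_backward", "viterbi_decode", "gaussian_loglik_matrix", "em_fit"]


@njit(cache=True, fastmath=True)
def forward_backward(b, a, pi):
    """Scaled forward-backward pass.

    Parameters
    ----------
    b : (T, K) emission likelihoods p(x_t | state k)
    a : (K, K) row-stochastic transition matrix
    pi : (K,) initial state probabilities

    Returns
    -------
    loglik : float
    gamma : (T, K) posterior state probabilities
    xi_sum : (K, K) summed posterior transition counts
    """
    t_len, k = b.shape
    alpha = np.empty((t_len, k))
    scale = np.empty(t_len)
    tiny = 1e-300

    s = 0.0
    for j in range(k):
        v = pi[j] * b[0, j]
        alpha[0, j] = v
        s += v
    if s < tiny:
        s = tiny
    for j in range(k):
        alpha[0, j] /= s
    scale[0] = s
    for t in range(1, t_len):
        s = 0.0
        for j in range(k):
            acc = 0.0
            for i in range(k):
                acc += alpha[t - 1, i] * a[i, j]
            v = acc * b[t, j]
            alpha[t, j] = v
            s += v
        if s < tiny:
            s = tiny
        for j in range(k):
            alpha[t, j] /= s
        scale[t] = s

    gamma = np.empty((t_len, k))
    beta = np.empty(k)            # beta at t+1 (current), overwritten in place
    beta_next = np.empty(k)
    xi_sum = np.zeros((k, k))
    s = 0.0
    for j in range(k):
        beta[j] = 1.0
        gamma[t_len - 1, j] = alpha[t_len - 1, j]
        s += gamma[t_len - 1, j]
    if s < tiny:
        s = tiny
    for j in range(k):
        gamma[t_len - 1, j] /= s
    for t in range(t_len - 2, -1, -1):
        sc = scale[t + 1]
        for i in range(k):
            acc = 0.0
            for j in range(k):
                acc += a[i, j] * b[t + 1, j] * beta[j]
            beta_next[i] = acc / sc
        # posterior transition mass t -> t+1
        denom = 0.0
        for i in range(k):
            for j in range(k):
                denom += alpha[t, i] * a[i, j] * b[t + 1, j] * beta[j]
        if denom < tiny:
            denom = tiny
        for i in range(k):
            ai = alpha[t, i]
            for j in range(k):
                xi_sum[i, j] += ai * a[i, j] * b[t + 1, j] * beta[j] / denom
        s = 0.0
        for j in range(k):
            v = alpha[t, j] * beta_next[j]
            gamma[t, j] = v
            s += v
        if s < tiny:
            s = tiny
        for j in range(k):
            gamma[t, j] /= s
        for j in range(k):
            beta[j] = beta_next[j]

    loglik = 0.0
    for t in range(t_len):
        loglik += np.log(scale[t])
    return loglik, gamma, xi_sum


@njit(cache=True)
def viterbi_decode(logb, loga, logpi):
    """Most probable state path by the Viterbi algorithm (log domain).

    Ties are broken toward the lower state index (strict improvement is
    required to switch).  Returns (path, log joint probability).
    """
    t_len, k = logb.shape
    delta = np.empty((t_len, k))
    back = np.zeros((t_len, k), dtype=np.int64)
    delta[0] = logpi + logb[0]
    for t in range(1, t_len):
        for j in range(k):
            best_i = 0
            best = delta[t - 1, 0] + loga[0, j]
            for i in range(1, k):
                v = delta[t - 1, i] + loga[i, j]
                if v > best:
                    best = v
                    best_i = i
            delta[t, j] = best + logb[t, j]
            back[t, j] = best_i
    last = 0
    best = delta[t_len - 1, 0]
    for j in range(1, k):
        if delta[t_len - 1, j] > best:
            best = delta[t_len - 1, j]
            last = j
    path = np.empty(t_len, dtype=np.int64)
    path[t_len - 1] = last
    for t in range(t_len - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best


@njit(cache=True, fastmath=True)
def em_fit(x, means, variances, a, pi, max_iter, tol, var_floor):
    """Full Baum–Welch EM loop for a Gaussian-emission HMM.

    Iterates expectation (scaled forward-backward) and maximization
    (closed-form Gaussian and transition updates) until the log-likelihood
    improves by less than ``tol`` or ``max_iter`` is reached.  Emission
    variances are floored at ``var_floor``.

    Returns ``(means, variances, a, pi, history, n_iter, converged)``
    where ``history`` holds the log-likelihood of the parameters at the
    start of each iteration plus a final evaluation (non-decreasing).
    """
    t_len = x.shape[0]
    k = means.shape[0]
    history = np.empty(max_iter + 1)
    prev = -np.inf
    converged = False
    n_iter = 0
    b = np.empty((t_len, k))
    shift = np.empty(t_len)
    lognorm = np.empty(k)
    inv2v = np.empty(k)
    for it in range(1, max_iter + 1):
        n_iter = it
        # emission likelihoods, scaled by the per-frame max log-density
        for j in range(k):
            lognorm[j] = -0.5 * np.log(2.0 * np.pi * variances[j])
            inv2v[j] = 0.5 / variances[j]
        for t in range(t_len):
            m = -np.inf
            for j in range(k):
                d = x[t] - means[j]
                v = lognorm[j] - d * d * inv2v[j]
                b[t, j] = v
                if v > m:
                    m = v
            shift[t] = m
            for j in range(k):
                d = b[t, j] - m
                b[t, j] = np.exp(d) if d > -45.0 else 0.0
        loglik, gamma, xi_sum = forward_backward(b, a, pi)
        loglik += shift.sum()
        history[it - 1] = loglik
        # M-step
        for j in range(k):
            occ = 0.0
            num = 0.0
            for t in range(t_len):
                occ += gamma[t, j]
                num += gamma[t, j] * x[t]
            if occ < 1e-300:
                occ = 1e-300
            mu = num / occ
            var = 0.0
            for t in range(t_len):
                d = x[t] - mu
                var += gamma[t, j] * d * d
            var /= occ
            means[j] = mu
            variances[j] = var if var > var_floor else var_floor
        if k > 1:
            for i in range(k):
                row = 0.0
                for j in range(k):
                    row += xi_sum[i, j]
                if row > 1e-300:
                    for j in range(k):
                        a[i, j] = xi_sum[i, j] / row
                else:
                    for j in range(k):
                        a[i, j] = 1.0 / k
        s = 0.0
        for j in range(k):
            pi[j] = gamma[0, j] if gamma[0, j] > 1e-12 else 1e-12
            s += pi[j]
        for j in range(k):
            pi[j] /= s
        if it > 1 and loglik - prev < tol:
            converged = True
            break
        prev = loglik
    # final evaluation at the updated parameters
    for j in range(k):
        lognorm[j] = -0.5 * np.log(2.0 * np.pi * variances[j])
        inv2v[j] = 0.5 / variances[j]
    for t in range(t_len):
        m = -np.inf
        for j in range(k):
            d = x[t] - means[j]
            v = lognorm[j] - d * d * inv2v[j]
            b[t, j] = v
            if v > m:
                m = v
        shift[t] = m
        for j in range(k):
            d = b[t, j] - m
            b[t, j] = np.exp(d) if d > -45.0 else 0.0
    loglik, gamma, xi_sum = forward_backward(b, a, pi)
    loglik += shift.sum()
    history[n_iter] = loglik
    return means, variances, a, pi, history[: n_iter + 1], n_iter, converged


@njit(cache=True)
def gaussian_loglik_matrix(x, means, variances):
    """(T, K) matrix of per-frame, per-state Gaussian log-likelihoods."""
    t_len = x.shape[0]
    k = means.shape[0]
    out = np.empty((t_len, k))
    for j in range(k):
        c = -0.5 * np.log(2.0 * np.pi * variances[j])
        inv = 0.5 / variances[j]
        for t in range(t_len):
            d = x[t] - means[j]
            out[t, j] = c - d * d * inv
    return out
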