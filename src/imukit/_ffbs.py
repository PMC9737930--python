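"""Forward filtering-backward sampling kernel (numba-compiled hot loop).

The forward pass runs in linear space with per-step normalization after a
per-time max-shift of the log-likelihoods, which is numerically equivalent
to log-space message passing.  Backward sampling consumes pre-drawn
uniforms so the caller owns all randomness.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def ffbs(loglik: np.ndarray, P: np.ndarray, u: np.ndarray) -> np.ndarray:
    """One blocked draw of the state sequence.

    Parameters
    ----------
    loglik : (T, L) per-state observation log-likelihoods (rows of zeros for
        time points without a likelihood term).
    P : (L, L) row-stochastic transition matrix.
    u : (T,) uniforms for the backward draws.

    Returns the 0-based state sequence; the first entry of a degenerate
    (all-zero message) filter is flagged by returning -1 at that position.
    """
    T, L = loglik.shape
    alphas = np.empty((T, L))
    alpha = np.full(L, 1.0 / L)
    for t in range(T):
        m = loglik[t, 0]
        for k in range(1, L):
            if loglik[t, k] > m:
                m = loglik[t, k]
        if t > 0:
            pred = np.zeros(L)
            for i in range(L):
                ai = alphas[t - 1, i]
                if ai > 0.0:
                    for j in range(L):
                        pred[j] += ai * P[i, j]
            alpha = pred
        else:
            alpha = np.full(L, 1.0 / L)
        s = 0.0
        for k in range(L):
            alpha[k] = alpha[k] * np.exp(loglik[t, k] - m)
            s += alpha[k]
        if s <= 0.0 or not np.isfinite(s):
            out = np.empty(T, dtype=np.int64)
            out[0] = -1
            out[1] = t
            return out
        for k in range(L):
            alphas[t, k] = alpha[k] / s
    states = np.empty(T, dtype=np.int64)
    # draw x_{T-1} ~ alpha_{T-1}
    r = u[T - 1]
    acc = 0.0
    states[T - 1] = L - 1
    for k in range(L):
        acc += alphas[T - 1, k]
        if r < acc:
            states[T - 1] = k
            break
    for t in range(T - 2, -1, -1):
        nxt = states[t + 1]
        s = 0.0
        w = np.empty(L)
        for k in range(L):
            w[k] = alphas[t, k] * P[k, nxt]
            s += w[k]
        r = u[t] * s
        acc = 0.0
        states[t] = L - 1
        for k in range(L):
            acc += w[k]
            if r < acc:
                states[t] = k
                break
    return states
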