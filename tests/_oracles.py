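"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive: explicit double loops, recursive path
enumeration, direct formula transcription. None of it shares code with the
package internals it checks.
"""

import numpy as np


def cindex_bruteforce(time, event, score):
    """Harrell's c by enumerating every ordered pair."""
    n = len(time)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if event[i] == 1 and time[i] < time[j]:
                den += 1
                if score[i] > score[j]:
                    num += 1.0
                elif score[i] == score[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def km_by_hand(time, event):
    """Product-limit estimate via direct counting, one factor per event time."""
    times = sorted(set(t for t, e in zip(time, event) if e == 1))
    s = 1.0
    out = {}
    for tau in times:
        at_risk = sum(1 for t in time if t >= tau)
        d = sum(1 for t, e in zip(time, event) if t == tau and e == 1)
        s *= 1.0 - d / at_risk
        out[tau] = s
    return out


def cox_nll_naive(beta, X, time, event):
    """Negative Breslow partial log-likelihood by explicit risk-set sums."""
    beta = np.asarray(beta, dtype=float)
    eta = np.asarray(X, dtype=float) @ beta
    ll = 0.0
    for tau in sorted(set(t for t, e in zip(time, event) if e == 1)):
        at_risk = [j for j in range(len(time)) if time[j] >= tau]
        log_s = np.log(np.sum(np.exp(eta[at_risk])))
        for i in range(len(time)):
            if time[i] == tau and event[i] == 1:
                ll += eta[i] - log_s
    return -ll


def breslow_naive(beta, X, time, event):
    """Baseline-hazard increments d_i / sum_{R(t_i)} exp(x'beta)."""
    eta = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    out = {}
    for tau in sorted(set(t for t, e in zip(time, event) if e == 1)):
        at_risk = [j for j in range(len(time)) if time[j] >= tau]
        d = sum(1 for t, e in zip(time, event) if t == tau and e == 1)
        out[tau] = d / np.sum(np.exp(eta[at_risk]))
    return out


def gak_local_log_kernel(a, b, sigma, window_order, q, r):
    """Local log-kernel of one aligned pair (same definition as the package
    documents: Gaussian with the 2-k normalization, triangular window)."""
    d2 = float(np.sum((np.asarray(a, float) - np.asarray(b, float)) ** 2))
    half = d2 / (2.0 * sigma**2)
    logk = -half - np.log(2.0 - np.exp(-half))
    if window_order > 0:
        w = 1.0 - abs(q - r) / window_order
        if w <= 0:
            return -np.inf
        logk += np.log(w)
    return logk


def gak_kernel_enumerated(series_a, series_b, sigma, window_order=0):
    """log k_GA by recursively enumerating *all* monotone alignment paths.

    A path starts at pair (0, 0), ends at (Q-1, R-1), and advances by
    (1, 0), (0, 1) or (1, 1); its weight is the product of local kernels
    over the visited pairs. Exponential-time; only for tiny series.
    """
    A = np.atleast_2d(np.asarray(series_a, float))
    B = np.atleast_2d(np.asarray(series_b, float))
    Q, R = A.shape[0], B.shape[0]

    def walk(q, r):
        """Sum over path continuations from pair (q, r), excluding its own
        local kernel factor."""
        if q == Q - 1 and r == R - 1:
            return 1.0
        total = 0.0
        for dq, dr in ((1, 0), (0, 1), (1, 1)):
            q2, r2 = q + dq, r + dr
            if q2 < Q and r2 < R:
                lk = gak_local_log_kernel(A[q2], B[r2], sigma, window_order, q2, r2)
                if np.isfinite(lk):
                    total += np.exp(lk) * walk(q2, r2)
        return total

    lk0 = gak_local_log_kernel(A[0], B[0], sigma, window_order, 0, 0)
    if not np.isfinite(lk0):
        return -np.inf
    total = np.exp(lk0) * walk(0, 0)
    return np.log(total) if total > 0 else -np.inf


def pam_exhaustive_k2(dm):
    """Best objective over all medoid pairs for k=2 (brute force)."""
    n = dm.shape[0]
    best = np.inf
    for a in range(n):
        for b in range(a + 1, n):
            obj = float(np.minimum(dm[:, a], dm[:, b]).sum())
            best = min(best, obj)
    return best
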