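"""Triangular Global Alignment Kernel distances and PAM clustering.

A patient is a short multivariate series: a (|T| x p) matrix of signature-gene
values over the common day grid. Similarity between two patients sums, over
every monotone alignment of the two series, the product of a local kernel on
aligned observation pairs (Cuturi's global alignment kernel). The local
kernel is

    kappa(a, b) = w(q, r) * exp(-phi_sigma(a, b)),
    phi_sigma(a, b) = ||a-b||^2 / (2 sigma^2)
                      + log(2 - exp(-||a-b||^2 / (2 sigma^2))),

i.e. the Gaussian kernel with the 2-k normalization that keeps the summed
kernel positive definite, times an optional triangular integer window
w(q, r) = max(0, 1 - |q-r|/order) (w = 1 everywhere when order = 0). The
kernel is evaluated by the standard dynamic program

    M(q, r) = kappa(q, r) * [M(q-1, r) + M(q, r-1) + M(q-1, r-1)]

computed in log-space, and turned into a dissimilarity by normalization and
subtraction: d(i, j) = 1 - exp(logk(i,j) - (logk(i,i) + logk(j,j)) / 2),
which lies in [0, 1] and is 0 on identical series (it need not satisfy the
triangle inequality).

Clustering is partitional with medoid centers (PAM, Lloyd-style alternation)
on the precomputed cross-distance matrix; the number of clusters is selected
by survival separation (minimal log-rank p-value across clusters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.spatial.distance import cdist

from .imputation import CompleteSeriesSet
from .survival import (SurvivalTable, TestResult, logrank_test, newton_cox_fit)
from scipy import stats as _stats

__all__ = ["GAKParams", "Partition", "local_cost", "gak_log_kernel",
           "gak_distance", "sigma_heuristic", "cross_distance_matrix",
           "pam_cluster", "select_k", "NoAlignmentError"]


class NoAlignmentError(ValueError):
    """The triangular window admits no monotone alignment (log-kernel -inf)."""


@dataclass(frozen=True)
class GAKParams:
    sigma: float
    window_order: int = 0  # 0 = unconstrained

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.window_order < 0:
            raise ValueError("window_order must be >= 0")


@dataclass(frozen=True)
class Partition:
    """Cluster labels (1-based) with medoid patients and PAM objective."""

    labels: np.ndarray
    medoid_indices: np.ndarray
    patients: tuple
    objective: float

    @property
    def medoid_patients(self) -> tuple:
        return tuple(self.patients[i] for i in self.medoid_indices)

    @property
    def k(self) -> int:
        return len(self.medoid_indices)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def to_frame(self) -> pd.DataFrame:
        is_medoid = np.zeros(len(self.labels), dtype=bool)
        is_medoid[self.medoid_indices] = True
        return pd.DataFrame({
            "patient_id": self.patients,
            "cluster": self.labels,
            "is_medoid": is_medoid,
        })


# ---------------------------------------------------------------------------
# local cost and kernel
# ---------------------------------------------------------------------------

def local_cost(series_i: np.ndarray, series_j: np.ndarray) -> np.ndarray:
    """Local cost matrix: Euclidean norm across genes for every pair of
    grid positions of the two series."""
    a = np.atleast_2d(np.asarray(series_i, dtype=float))
    b = np.atleast_2d(np.asarray(series_j, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("series must share the gene dimension")
    return cdist(a, b)


_NEG_INF = -1.0e308


@njit(cache=True)
def _gak_dp(logK):
    """Log-space DP over monotone alignments given local log-kernels."""
    Q, R = logK.shape
    M = np.full((Q + 1, R + 1), _NEG_INF)
    M[0, 0] = 0.0
    for q in range(1, Q + 1):
        for r in range(1, R + 1):
            a = M[q - 1, r]
            b = M[q, r - 1]
            c = M[q - 1, r - 1]
            m = a if a > b else b
            if c > m:
                m = c
            if m <= _NEG_INF:
                continue
            s = np.exp(a - m) + np.exp(b - m) + np.exp(c - m)
            M[q, r] = logK[q - 1, r - 1] + m + np.log(s)
    return M[Q, R]


def _local_log_kernel(series_i, series_j, params: GAKParams) -> np.ndarray:
    lcm = local_cost(series_i, series_j)
    half = lcm**2 / (2.0 * params.sigma**2)
    logk = -half - np.log(2.0 - np.exp(-half))
    if params.window_order > 0:
        Q, R = lcm.shape
        q_idx = np.arange(Q)[:, None]
        r_idx = np.arange(R)[None, :]
        w = 1.0 - np.abs(q_idx - r_idx) / params.window_order
        with np.errstate(divide="ignore"):
            logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
        logk = logk + logw
    return logk


def gak_log_kernel(series_i, series_j, params: GAKParams) -> float:
    """log k_GA(series_i, series_j) under the triangular local kernel."""
    a = np.atleast_2d(np.asarray(series_i, dtype=float))
    b = np.atleast_2d(np.asarray(series_j, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("series must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("series must be finite")
    logk = _local_log_kernel(a, b, params)
    logk = np.where(np.isfinite(logk), logk, _NEG_INF)
    val = _gak_dp(np.ascontiguousarray(logk))
    if val <= _NEG_INF / 2:
        raise NoAlignmentError(
            "triangular window admits no monotone alignment of these series")
    return float(val)


def gak_distance(series_i, series_j, params: GAKParams) -> float:
    """Normalized-and-subtracted GAK dissimilarity in [0, 1]."""
    lk_ij = gak_log_kernel(series_i, series_j, params)
    lk_ii = gak_log_kernel(series_i, series_i, params)
    lk_jj = gak_log_kernel(series_j, series_j, params)
    d = 1.0 - np.exp(lk_ij - 0.5 * (lk_ii + lk_jj))
    return float(min(max(d, 0.0), 1.0))


def sigma_heuristic(series_set: CompleteSeriesSet, seed: int = 0,
                    c: float = 1.0, max_pairs: int = 10_000) -> float:
    """Cuturi's bandwidth rule: c * median pairwise observation distance *
    sqrt(median series length), medians over a seeded subsample of pairs."""
    obs = series_set.values.reshape(-1, series_set.values.shape[2])
    obs = obs[~np.isnan(obs).any(axis=1)]
    n = obs.shape[0]
    if n < 2:
        raise ValueError("not enough observations for the bandwidth heuristic")
    rng = np.random.default_rng(seed)
    ii = rng.integers(0, n, size=max_pairs)
    jj = rng.integers(0, n, size=max_pairs)
    keep = ii != jj
    d = np.linalg.norm(obs[ii[keep]] - obs[jj[keep]], axis=1)
    med = float(np.median(d))
    if med <= 0:
        raise ValueError("degenerate data: median pairwise distance is zero")
    return c * med * np.sqrt(series_set.values.shape[1])


def cross_distance_matrix(series_set: CompleteSeriesSet,
                          params: GAKParams) -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise GAK dissimilarities."""
    series = [series_set.values[i] for i in range(len(series_set.patients))]
    n = len(series)
    self_lk = np.array([gak_log_kernel(s, s, params) for s in series])
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lk = gak_log_kernel(series[i], series[j], params)
            d = 1.0 - np.exp(lk - 0.5 * (self_lk[i] + self_lk[j]))
            dm[i, j] = dm[j, i] = min(max(d, 0.0), 1.0)
    return dm


# ---------------------------------------------------------------------------
# PAM clustering
# ---------------------------------------------------------------------------

def _pam_once(dm: np.ndarray, k: int, rng: np.random.Generator, max_iter: int):
    n = dm.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(dm[:, medoids], axis=1)
        # re-seed any empty cluster with a random non-medoid point
        for c in range(k):
            if not np.any(labels == c):
                candidates = np.setdiff1d(np.arange(n), medoids)
                medoids[c] = rng.choice(candidates)
                labels = np.argmin(dm[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            within = dm[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            medoids = new_medoids
            break
        medoids = new_medoids
    labels = np.argmin(dm[:, medoids], axis=1)
    objective = float(dm[np.arange(n), medoids[labels]].sum())
    return labels, medoids, objective


def pam_cluster(dm: np.ndarray, k: int, seed: int = 0, max_iter: int = 100,
                n_init: int = 5, patients=None) -> Partition:
    """Partition-around-medoids on a precomputed distance matrix.

    Lloyd-style alternation (assign to nearest medoid / move each medoid to
    the member minimizing the within-cluster distance sum), repeated from
    ``n_init`` seeded random initializations; the best objective wins.
    """
    dm = np.asarray(dm, dtype=float)
    n = dm.shape[0]
    if dm.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        labels, medoids, obj = _pam_once(dm, k, rng, max_iter)
        if best is None or obj < best[2] - 1e-12:
            best = (labels, medoids, obj)
    labels, medoids, obj = best
    # order clusters by first appearance for stable labelling
    order = np.argsort([np.flatnonzero(labels == c)[0] for c in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels] + 1
    medoids = medoids[order]
    if patients is None:
        patients = tuple(range(n))
    return Partition(labels.astype(int), medoids.astype(int), tuple(patients), obj)


# ---------------------------------------------------------------------------
# cluster-number selection by survival separation
# ---------------------------------------------------------------------------

def _wald_test_clusters(labels: np.ndarray, surv: SurvivalTable) -> TestResult:
    """Global Wald test from a Cox fit on cluster indicator dummies."""
    ks = np.unique(labels)
    dummies = np.column_stack([(labels == c).astype(float) for c in ks[1:]])
    beta, cov, _ = newton_cox_fit(dummies, surv)
    try:
        stat = float(beta @ np.linalg.solve(cov, beta))
    except np.linalg.LinAlgError:
        stat = float(beta @ np.linalg.pinv(cov) @ beta)
    stat = max(stat, 0.0)
    df = len(ks) - 1
    return TestResult(stat, df, float(_stats.chi2.sf(stat, df)))


def select_k(series_set: CompleteSeriesSet, survival: SurvivalTable,
             k_range, min_cluster_size: int = 2, seed: int = 0,
             params: GAKParams | None = None, dm: np.ndarray | None = None,
             n_init: int = 5):
    """Choose the cluster count by minimal log-rank p-value.

    For every admissible k (all clusters of size >= ``min_cluster_size``)
    the set is PAM-clustered on the GAK cross-distance matrix and the
    clusters' survival curves compared by the log-rank test (plus a Wald
    companion from a Cox fit on cluster dummies). Returns
    ``(k_opt, Partition, table)`` where ``table`` is a per-k DataFrame of
    p-values (NaN for inadmissible k).
    """
    if params is None and dm is None:
        params = GAKParams(sigma=sigma_heuristic(series_set, seed=seed))
    if dm is None:
        dm = cross_distance_matrix(series_set, params)
    surv = survival.reindex(series_set.patients)
    rows = []
    best = None
    for k in k_range:
        if not 2 <= k <= len(series_set.patients):
            raise ValueError("k_range must lie within [2, n]")
        part_seed = np.random.SeedSequence(seed, spawn_key=(int(k),))
        part = pam_cluster(dm, k, seed=part_seed, n_init=n_init,
                           patients=series_set.patients)
        if part.cluster_sizes().min() < min_cluster_size:
            rows.append({"k": k, "admissible": False,
                         "logrank_p": np.nan, "wald_p": np.nan})
            continue
        lr = logrank_test(surv, part.labels)
        wald = _wald_test_clusters(part.labels, surv)
        rows.append({"k": k, "admissible": True,
                     "logrank_p": lr.p_value, "wald_p": wald.p_value})
        if best is None or lr.p_value < best[2].p_value:
            best = (k, part, lr)
    table = pd.DataFrame(rows)
    if best is None:
        raise ValueError("no admissible k: every clustering produced a "
                         "cluster smaller than min_cluster_size")
    return best[0], best[1], table
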