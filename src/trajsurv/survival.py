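"""Core survival statistics for right-censored length-of-stay data.

Implements the estimators the rest of the pipeline is built on: the
Kaplan-Meier product-limit curve, the k-sample log-rank test, Harrell's
concordance index, the Cox partial likelihood (negative log, gradient,
Hessian) with Breslow handling of tied event times, the Breslow baseline
hazard, and the Grambsch-Therneau scaled-Schoenfeld proportional-hazards
check.

The event of interest throughout is hospital *discharge*: a "good" event,
so a higher risk score means an earlier expected discharge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalTable",
    "KMCurve",
    "TestResult",
    "BaselineHazard",
    "km_estimate",
    "logrank_test",
    "concordance_index",
    "cox_neg_log_partial_likelihood",
    "cox_gradient",
    "cox_hessian",
    "breslow_baseline",
    "schoenfeld_ph_test",
    "newton_cox_fit",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalTable:
    """Per-patient follow-up time (days since injury) and discharge indicator.

    ``event == 1`` means the discharge day was observed; ``event == 0`` means
    follow-up was right-censored at ``time_days``.
    """

    patient_id: np.ndarray
    time_days: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        pid = np.asarray(self.patient_id, dtype=object)
        t = np.asarray(self.time_days, dtype=float)
        e = np.asarray(self.event, dtype=np.int8)
        if not (len(pid) == len(t) == len(e)):
            raise ValueError("patient_id, time_days, event must have equal length")
        if len(pid) == 0:
            raise ValueError("empty survival table")
        if len(set(pid)) != len(pid):
            raise ValueError("patient_id values must be unique")
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError("time_days must be finite and non-negative")
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("event must be 0/1")
        object.__setattr__(self, "patient_id", pid)
        object.__setattr__(self, "time_days", t)
        object.__setattr__(self, "event", e)

    def __len__(self) -> int:
        return len(self.patient_id)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, mask_or_ids) -> "SurvivalTable":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            mask = arr
        else:
            wanted = set(arr.tolist())
            mask = np.array([p in wanted for p in self.patient_id])
        return SurvivalTable(self.patient_id[mask], self.time_days[mask], self.event[mask])

    def reindex(self, patient_ids) -> "SurvivalTable":
        """Rows in the order of ``patient_ids`` (all must be present)."""
        pos = {p: i for i, p in enumerate(self.patient_id)}
        idx = np.array([pos[p] for p in patient_ids], dtype=int)
        return SurvivalTable(self.patient_id[idx], self.time_days[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.patient_id,
            "time_days": self.time_days,
            "event": self.event.astype(int),
        })

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurvivalTable":
        return cls(frame["patient_id"].to_numpy(dtype=object),
                   frame["time_days"].to_numpy(dtype=float),
                   frame["event"].to_numpy())

    @classmethod
    def read_csv(cls, path: str | Path) -> "SurvivalTable":
        return cls.from_frame(pd.read_csv(path, dtype={"patient_id": str}))


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct observed event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "survival": self.survival_prob,
            "at_risk": self.n_at_risk,
            "events": self.n_events,
        })


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class BaselineHazard:
    event_times: np.ndarray
    hazard_increments: np.ndarray
    cumulative: np.ndarray


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_estimate(surv: SurvivalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Steps occur only at observed event times; censored-only times reduce the
    risk set without creating a step.
    """
    t, e = surv.time_days, surv.event
    times = np.unique(t[e == 1])
    if times.size == 0:
        return KMCurve(np.empty(0), np.empty(0), np.empty(0, int), np.empty(0, int))
    sorted_t = np.sort(t)
    n_at_risk = len(t) - np.searchsorted(sorted_t, times, side="left")
    d = np.array([int(((t == tau) & (e == 1)).sum()) for tau in times])
    surv_prob = np.cumprod(1.0 - d / n_at_risk)
    return KMCurve(times, surv_prob, n_at_risk.astype(int), d)


def logrank_test(surv: SurvivalTable, group_labels) -> TestResult:
    """k-sample log-rank test across the given per-patient group labels."""
    labels = np.asarray(group_labels)
    if len(labels) != len(surv):
        raise ValueError("one group label per patient required")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    t, e = surv.time_days, surv.event
    if surv.n_events == 0:
        raise ValueError("log-rank test needs at least one event")
    G = len(groups)
    event_times = np.unique(t[e == 1])
    sorted_by_group = []
    for g in groups:
        m = labels == g
        if m.sum() == 0:
            raise ValueError(f"group {g!r} has no members")
        sorted_by_group.append((np.sort(t[m]), t[m], e[m]))

    observed = np.zeros(G)
    expected = np.zeros(G)
    cov = np.zeros((G, G))
    for tau in event_times:
        n_g = np.array([len(st) - np.searchsorted(st, tau, side="left")
                        for st, _, _ in sorted_by_group], dtype=float)
        d_g = np.array([int(((tg == tau) & (eg == 1)).sum())
                        for _, tg, eg in sorted_by_group], dtype=float)
        n = n_g.sum()
        d = d_g.sum()
        if n <= 0 or d == 0:
            continue
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            frac = n_g / n
            v = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            cov += v
    z = (observed - expected)[:-1]
    V = cov[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(V, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(V) @ z)
    stat = max(stat, 0.0)
    df = G - 1
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance_index(surv: SurvivalTable, risk_scores) -> float:
    """Harrell's c-index for right-censored data.

    A pair (i, j) is comparable when ``event_i == 1`` and ``t_i < t_j``; it is
    concordant when the earlier-discharged patient has the *higher* risk
    score. Score ties count 0.5. Pairs with equal times are non-comparable
    under this convention (including two tied events).
    """
    s = np.asarray(risk_scores, dtype=float)
    if s.shape != surv.time_days.shape:
        raise ValueError("one risk score per patient required")
    t, e = surv.time_days, surv.event
    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    diff = s[:, None] - s[None, :]
    concordant = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return float(concordant[comparable].sum() / n_comp)


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)
# ---------------------------------------------------------------------------

def _sorted_structures(surv: SurvivalTable):
    """Ascending-time sort order, distinct-time group boundaries, events/group."""
    order = np.argsort(surv.time_days, kind="stable")
    t = surv.time_days[order]
    e = surv.event[order].astype(np.int64)
    boundaries = np.flatnonzero(np.diff(t)) + 1
    group_start = np.concatenate(([0], boundaries, [len(t)])).astype(np.int64)
    G = len(group_start) - 1
    group_events = np.add.reduceat(e, group_start[:-1]) if G else np.empty(0, np.int64)
    return order, group_start, group_events


def _cox_eta_quantities(eta_sorted, e_sorted, group_start, group_events):
    """Per-subject likelihood quantities for a sorted linear predictor.

    Returns (neg_loglik, grad_eta, w) where grad_eta is d l/d eta and
    w = -d^2 l/d eta_i^2 (diagonal of the Breslow-tie Hessian in eta).
    """
    m = eta_sorted.max() if len(eta_sorted) else 0.0
    ex = np.exp(eta_sorted - m)
    G = len(group_events)
    # suffix risk sums per distinct-time group
    suffix = np.concatenate((np.cumsum(ex[::-1])[::-1], [0.0]))
    S = suffix[group_start[:-1]]
    d_g = group_events.astype(float)
    ev_groups = d_g > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio1 = np.where(ev_groups, d_g / S, 0.0)
        ratio2 = np.where(ev_groups, d_g / S**2, 0.0)
    A_g = np.cumsum(ratio1)
    B_g = np.cumsum(ratio2)
    group_of = np.repeat(np.arange(G), np.diff(group_start))
    A = A_g[group_of]
    B = B_g[group_of]
    mu = ex * A
    grad_eta = e_sorted - mu
    w = mu - ex**2 * B
    nll = float(np.sum(d_g[ev_groups] * (np.log(S[ev_groups]) + m))
                - np.sum(e_sorted * (eta_sorted)))
    return nll, grad_eta, w


def cox_neg_log_partial_likelihood(beta, X, surv: SurvivalTable) -> float:
    """Negative Cox log partial likelihood, Breslow convention for ties."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(beta)):
        raise ValueError("non-finite entries in X or beta")
    order, group_start, group_events = _sorted_structures(surv)
    eta = X @ beta
    nll, _, _ = _cox_eta_quantities(eta[order], surv.event[order].astype(float),
                                    group_start, group_events)
    return nll


def cox_gradient(beta, X, surv: SurvivalTable) -> np.ndarray:
    """Gradient of the *negative* log partial likelihood with respect to beta."""
    X = np.asarray(X, dtype=float)
    order, group_start, group_events = _sorted_structures(surv)
    eta = (X @ np.asarray(beta, dtype=float))[order]
    _, grad_eta, _ = _cox_eta_quantities(eta, surv.event[order].astype(float),
                                         group_start, group_events)
    Xs = X[order]
    return -(Xs.T @ grad_eta)


def _risk_set_moments(beta, X, surv):
    """Per-event-group risk-set mean and covariance of the covariates.

    Yields (group_time, d_g, xbar_g, V_g, members) for each distinct event
    time in ascending order, plus the sorted X/event arrays.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    order, group_start, group_events = _sorted_structures(surv)
    Xs = X[order]
    ts = surv.time_days[order]
    es = surv.event[order]
    eta = Xs @ beta
    ex = np.exp(eta - eta.max())
    n, p = Xs.shape
    # suffix sums of ex, ex*x, ex*x x^T
    S0 = np.concatenate((np.cumsum(ex[::-1])[::-1], [0.0]))
    wx = ex[:, None] * Xs
    S1 = np.vstack((np.cumsum(wx[::-1], axis=0)[::-1], np.zeros((1, p))))
    wxx = ex[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
    S2 = np.concatenate((np.cumsum(wxx[::-1], axis=0)[::-1], np.zeros((1, p, p))))
    out = []
    G = len(group_events)
    for g in range(G):
        d_g = int(group_events[g])
        if d_g == 0:
            continue
        i0 = group_start[g]
        s0 = S0[i0]
        xbar = S1[i0] / s0
        V = S2[i0] / s0 - np.outer(xbar, xbar)
        members = np.arange(i0, group_start[g + 1])
        out.append((ts[i0], d_g, xbar, V, members))
    return out, Xs, ts, es


def cox_hessian(beta, X, surv: SurvivalTable) -> np.ndarray:
    """Hessian (observed information) of the negative log partial likelihood."""
    groups, _, _, _ = _risk_set_moments(beta, X, surv)
    p = np.asarray(X).shape[1]
    H = np.zeros((p, p))
    for _, d_g, _, V, _ in groups:
        H += d_g * V
    return H


def breslow_baseline(beta, X, surv: SurvivalTable) -> BaselineHazard:
    """Breslow estimator: h0(t_i) = d_i / sum_{j in R(t_i)} exp(x_j' beta)."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(beta)):
        raise ValueError("non-finite entries in X or beta")
    order, group_start, group_events = _sorted_structures(surv)
    eta = (X @ beta)[order]
    ex = np.exp(eta)
    suffix = np.concatenate((np.cumsum(ex[::-1])[::-1], [0.0]))
    S = suffix[group_start[:-1]]
    ts = surv.time_days[order]
    times, h0 = [], []
    for g, d_g in enumerate(group_events):
        if d_g > 0:
            times.append(ts[group_start[g]])
            h0.append(d_g / S[g])
    times = np.asarray(times)
    h0 = np.asarray(h0, dtype=float)
    return BaselineHazard(times, h0, np.cumsum(h0))


def newton_cox_fit(X, surv: SurvivalTable, tol: float = 1e-9, max_iter: int = 100):
    """Unpenalized Cox fit by Newton-Raphson with step halving.

    Returns (beta, covariance, neg_loglik). Covariance is the inverse observed
    information at the optimum.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if surv.n_events == 0:
        raise ValueError("no events")
    beta = np.zeros(p)
    nll = cox_neg_log_partial_likelihood(beta, X, surv)
    for _ in range(max_iter):
        g = cox_gradient(beta, X, surv)
        H = cox_hessian(beta, X, surv)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        scale = 1.0
        for _ in range(30):
            new = beta - scale * step
            new_nll = cox_neg_log_partial_likelihood(new, X, surv)
            if new_nll <= nll + 1e-12:
                break
            scale *= 0.5
        if np.max(np.abs(beta - new)) < tol:
            beta, nll = new, new_nll
            break
        beta, nll = new, new_nll
    H = cox_hessian(beta, X, surv)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return beta, cov, nll


# ---------------------------------------------------------------------------
# proportional-hazards diagnostic
# ---------------------------------------------------------------------------

def schoenfeld_ph_test(beta, X, surv: SurvivalTable):
    """Grambsch-Therneau score test for non-proportional hazards.

    Tests, per variable and globally, whether the Schoenfeld residuals at the
    fitted ``beta`` drift with the identity time transform g(t) = t — the
    score test for theta = 0 in the time-varying-coefficient model
    beta(t) = beta + theta * (g(t) - gbar). The information matrix is the
    exact profiled form sum(g^2 V) - (sum g V)(sum V)^{-1}(sum g V) over the
    per-event risk-set covariances V. Returns
    ``(per_variable: list[TestResult], global: TestResult)``, chi-square with
    df 1 and df p respectively.
    """
    X = np.asarray(X, dtype=float)
    if surv.n_events < 2:
        raise ValueError("PH test needs at least 2 events")
    groups, Xs, ts, es = _risk_set_moments(beta, X, surv)
    p = X.shape[1]
    resid = []       # one Schoenfeld residual per event individual
    g_times = []
    per_event = []   # (g_k, V_k) per event individual
    for t_g, d_g, xbar, V, members in groups:
        for i in members:
            if es[i] == 1:
                resid.append(Xs[i] - xbar)
                g_times.append(t_g)
                per_event.append(V)
    resid = np.asarray(resid)
    g_times = np.asarray(g_times, dtype=float)
    gc = g_times - g_times.mean()
    if float(np.sum(gc**2)) <= 0:
        raise ValueError("degenerate time transform (all events tied)")
    U = resid.T @ gc
    A = np.zeros((p, p))
    B = np.zeros((p, p))
    C = np.zeros((p, p))
    for g, V in zip(gc, per_event):
        A += g * g * V
        B += g * V
        C += V
    info = A - B @ np.linalg.pinv(C) @ B
    per_var = []
    for j in range(p):
        stat = float(U[j] ** 2 / info[j, j]) if info[j, j] > 0 else 0.0
        per_var.append(TestResult(stat, 1, float(stats.chi2.sf(stat, 1))))
    try:
        stat_g = float(U @ np.linalg.solve(info, U))
    except np.linalg.LinAlgError:
        stat_g = float(U @ np.linalg.pinv(info) @ U)
    stat_g = max(stat_g, 0.0)
    global_res = TestResult(stat_g, p, float(stats.chi2.sf(stat_g, p)))
    return per_var, global_res


def schoenfeld_residuals(beta, X, surv: SurvivalTable) -> np.ndarray:
    """Unscaled Schoenfeld residuals, one row per event individual."""
    groups, Xs, ts, es = _risk_set_moments(beta, X, surv)
    rows = []
    for _, _, xbar, _, members in groups:
        for i in members:
            if es[i] == 1:
                rows.append(Xs[i] - xbar)
    return np.asarray(rows)
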