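"""Synthetic longitudinal-expression cohorts with planted survival structure.

Emulates the design of a 28-day prospective trauma transcriptomics study:
patients are sampled on an irregular day grid with day-dependent missingness,
expression is log-scale with cluster-specific smooth injury-response
trajectories for a small set of "active" genes, the hazard of hospital
discharge follows a Weibull proportional-hazards model driven by the day-0
values of the active genes, follow-up stops at discharge (records after the
event are lost), and everything is administratively censored at a fixed day.

All randomness flows from a single root seed through named
``numpy.random.SeedSequence`` spawn keys, one per generation stage, so the
same seed yields byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import validate_expression
from .survival import SurvivalTable

__all__ = ["CohortConfig", "GroundTruth", "simulate_cohort", "apply_missingness",
           "DEFAULT_DAY_GRID", "DEFAULT_SELECTED_DAYS"]

# the study's original sampling schedule S and the low-missingness subset T
DEFAULT_DAY_GRID = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 11, 13, 14, 15, 16,
                    20, 21, 22, 23, 27, 28, 29)
DEFAULT_SELECTED_DAYS = (0, 1, 4, 7, 14, 21, 28)

# spawn keys for per-stage RNG streams
_STREAMS = {"loadings": 0, "clusters": 1, "expression": 2, "events": 3, "missing": 4}


def _default_missing_frac(day_grid) -> dict:
    # low missingness on the canonical selected days, high elsewhere
    return {d: (0.25 if d in DEFAULT_SELECTED_DAYS else 0.70) for d in day_grid}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults reflect the study design being emulated.

    ``effect_sizes`` are per-active-gene log-hazard coefficients (the planted
    Cox beta). ``trajectory_params`` maps cluster index -> (baseline,
    amplitude, decay): the cluster mean curve for active genes is
    ``baseline + amplitude * exp(-decay * day)``; the defaults start all
    clusters from a nearly common acute day-0 state and let them diverge
    toward cluster-specific recovery baselines. ``noise_sd`` is log-scale
    observation noise. ``admin_censor_day`` censors the *outcome* and may
    lie beyond the sampling grid (discharge can be observed after the last
    blood draw).
    """

    n_patients: int = 168
    n_genes: int = 500
    n_active_genes: int = 10
    n_clusters: int = 3
    day_grid: tuple = DEFAULT_DAY_GRID
    effect_sizes: tuple | None = None          # default: +-1.0 alternating
    trajectory_params: dict | None = None      # default: spread amplitudes
    noise_sd: float = 0.35
    missing_frac_by_day: dict | None = None
    admin_censor_day: float = 60.0
    weibull_shape: float = 1.6
    weibull_scale: float = 21.0
    min_events: int = 2   # reject cohorts with fewer observed discharges
    seed: int = 0

    def __post_init__(self):
        if self.n_active_genes > self.n_genes:
            raise ValueError("n_active_genes must be <= n_genes")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.admin_censor_day <= min(self.day_grid):
            raise ValueError("admin_censor_day must exceed the first sampling day")
        if tuple(sorted(set(self.day_grid))) != tuple(self.day_grid):
            raise ValueError("day_grid must be strictly increasing")
        mf = self.missing_frac_by_day
        if mf is not None and any(not (0.0 <= v <= 1.0) for v in mf.values()):
            raise ValueError("missingness fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull parameters must be positive")

    @property
    def resolved_effect_sizes(self) -> np.ndarray:
        if self.effect_sizes is not None:
            es = np.asarray(self.effect_sizes, dtype=float)
            if len(es) != self.n_active_genes:
                raise ValueError("need one effect size per active gene")
            return es
        signs = np.where(np.arange(self.n_active_genes) % 2 == 0, 1.0, -1.0)
        return signs * 1.0

    @property
    def resolved_trajectory_params(self) -> dict:
        """Default cluster mean curves baseline + amplitude * exp(-decay * t).

        Clusters start from a nearly common acute day-0 state (day-0 value =
        0.2 * baseline, keeping discharge hazard ratios moderate) and diverge
        toward cluster-specific recovery baselines spread over +-1.5 on the
        log scale, which is what separates the trajectories for clustering.
        """
        if self.trajectory_params is not None:
            return self.trajectory_params
        if self.n_clusters == 1:
            bases = np.array([1.5])
        else:
            bases = np.linspace(-1.5, 1.5, self.n_clusters)
        return {c: {"baseline": float(b), "amplitude": float(-0.8 * b),
                    "decay": 0.15}
                for c, b in enumerate(bases)}

    @property
    def resolved_missing_frac(self) -> dict:
        if self.missing_frac_by_day is not None:
            return dict(self.missing_frac_by_day)
        return _default_missing_frac(self.day_grid)


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a simulated cohort (labels are 1-based)."""

    cluster_of_patient: dict
    active_genes: tuple
    true_beta: np.ndarray
    true_event_times: np.ndarray
    true_linear_predictor: np.ndarray
    patients: tuple

    def to_jsonable(self) -> dict:
        return {
            "cluster_of_patient": {k: int(v) for k, v in self.cluster_of_patient.items()},
            "active_genes": list(self.active_genes),
            "true_beta": [float(b) for b in self.true_beta],
            "true_event_times": [float(t) for t in self.true_event_times],
            "true_linear_predictor": [float(v) for v in self.true_linear_predictor],
            "patients": list(self.patients),
        }


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stage],)))


def _patient_ids(n: int):
    width = max(3, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _gene_ids(p: int):
    width = max(4, len(str(p)))
    return [f"G{i:0{width}d}" for i in range(1, p + 1)]


def simulate_cohort(config: CohortConfig):
    """Generate one cohort.

    Returns ``(expression, survival, truth)`` where ``expression`` is a long
    table (patient_id, day, gene_id, value), ``survival`` a
    :class:`SurvivalTable` (event = discharge observed) and ``truth`` the
    planted :class:`GroundTruth`.
    """
    cfg = config
    n, p, a = cfg.n_patients, cfg.n_genes, cfg.n_active_genes
    days = np.asarray(cfg.day_grid, dtype=int)
    patients = _patient_ids(n)
    genes = _gene_ids(p)
    active = tuple(genes[:a])

    rng_load = _rng(cfg.seed, "loadings")
    rng_clust = _rng(cfg.seed, "clusters")
    rng_expr = _rng(cfg.seed, "expression")
    rng_event = _rng(cfg.seed, "events")

    # per-active-gene loading on the cluster mean curve (sign + magnitude)
    loadings = rng_load.uniform(0.6, 1.4, size=a) * \
        np.where(np.arange(a) % 2 == 0, 1.0, -1.0)

    cluster = rng_clust.integers(0, cfg.n_clusters, size=n)
    traj = cfg.resolved_trajectory_params

    # latent dense expression: (n, len(days), p)
    values = rng_expr.normal(0.0, cfg.noise_sd, size=(n, len(days), p))
    curves = np.empty((cfg.n_clusters, len(days)))
    for c in range(cfg.n_clusters):
        pars = traj[c]
        curves[c] = pars["baseline"] + pars["amplitude"] * np.exp(-pars["decay"] * days)
    values[:, :, :a] += curves[cluster][:, :, None] * loadings[None, None, :]

    # discharge times: Weibull baseline PH on centered day-0 active values
    beta = cfg.resolved_effect_sizes
    day0 = values[:, 0, :a]
    eta = day0 @ beta
    eta = eta - eta.mean()
    u = rng_event.uniform(size=n)
    shape, scale = cfg.weibull_shape, cfg.weibull_scale
    event_time = scale * (-np.log(u) / np.exp(eta)) ** (1.0 / shape)

    censor = float(cfg.admin_censor_day)
    follow = np.minimum(event_time, censor)
    delta = (event_time <= censor).astype(int)
    if delta.sum() < cfg.min_events:
        raise ValueError(
            f"configuration yields {int(delta.sum())} events "
            f"(< min_events={cfg.min_events}); survival stages would "
            "degenerate. Set min_events=0 only for plumbing checks.")

    survival = SurvivalTable(np.array(patients, dtype=object), follow, delta)

    # long table, truncated at follow-up (loss of follow-up after discharge)
    frames = []
    day_index = {d: q for q, d in enumerate(days)}
    for i, pid in enumerate(patients):
        keep = days[days <= follow[i]]
        if keep.size == 0:
            continue
        block = pd.DataFrame({
            "patient_id": pid,
            "day": np.repeat(keep, p),
            "gene_id": np.tile(genes, keep.size),
            "value": values[i, [day_index[d] for d in keep], :].ravel(),
        })
        frames.append(block)
    expression = pd.concat(frames, ignore_index=True)
    expression = apply_missingness(expression, cfg.resolved_missing_frac, cfg.seed)

    truth = GroundTruth(
        cluster_of_patient={pid: int(c) + 1 for pid, c in zip(patients, cluster)},
        active_genes=active,
        true_beta=beta.copy(),
        true_event_times=event_time,
        true_linear_predictor=eta,
        patients=tuple(patients),
    )
    return expression, survival, truth


def apply_missingness(table: pd.DataFrame, missing_frac_by_day: dict,
                      seed: int) -> pd.DataFrame:
    """Drop whole (patient, day) blocks independently with per-day probability.

    Missingness is draw-level: one blood draw carries all genes, so a dropped
    day removes every gene row of that patient-day.
    """
    validate_expression(table)
    if any(not (0.0 <= v <= 1.0) for v in missing_frac_by_day.values()):
        raise ValueError("missingness fractions must lie in [0, 1]")
    rng = _rng(seed, "missing")
    blocks = table[["patient_id", "day"]].drop_duplicates().sort_values(
        ["patient_id", "day"], kind="stable")
    fracs = blocks["day"].map(lambda d: missing_frac_by_day.get(int(d), 0.0)).to_numpy()
    drop = rng.uniform(size=len(blocks)) < fracs
    dropped = blocks[drop]
    if dropped.empty:
        return table.reset_index(drop=True)
    key = pd.MultiIndex.from_frame(table[["patient_id", "day"]])
    bad = pd.MultiIndex.from_frame(dropped)
    return table[~key.isin(bad)].reset_index(drop=True)
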