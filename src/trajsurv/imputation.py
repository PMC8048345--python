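"""Mixed carry/interpolation imputation for irregular short time series.

The study design samples every patient on a nominal day grid S, but draws are
skipped or shifted and follow-up ends at discharge. This module reduces S to
the days with tolerable missingness, then builds complete per-patient series
on that reduced grid T:

1. keep a required day's own draw when present;
2. otherwise carry the nearest draw within a window (2 days by default) —
   last observation carried forward (LOCF) from the past, next observation
   carried backward (NOCB) from the future, nearest wins, past preferred on
   ties;
3. otherwise linearly interpolate between the closest past and closest
   future draws, whatever their distance;
4. cells with no bracketing observations (typically after discharge) stay
   missing and are resolved by the complete-case horizon split.

Carrying moves whole per-day draw vectors: all genes from one blood draw
travel together, because missingness is draw-level in this design.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import validate_expression
from .survival import SurvivalTable

__all__ = ["TimeGrid", "CompleteSeriesSet", "select_time_points", "impute_mixed",
           "impute_locf", "split_complete_cases", "log_transform",
           "PROVENANCE_CODES"]

PROVENANCE_CODES = {
    "observed": 0,
    "carried_forward": 1,
    "carried_backward": 2,
    "interpolated": 3,
    "missing": -1,
}
_PROVENANCE_NAMES = {v: k for k, v in PROVENANCE_CODES.items()}


@dataclass(frozen=True)
class TimeGrid:
    """Ordered subset T of the original sampling days."""

    selected_days: tuple

    def __post_init__(self):
        days = tuple(int(d) for d in self.selected_days)
        if len(days) == 0:
            raise ValueError("time grid must be non-empty")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "selected_days", days)

    def __len__(self):
        return len(self.selected_days)


@dataclass(frozen=True)
class CompleteSeriesSet:
    """Per-patient dense matrices over a common grid x gene signature.

    ``values`` has shape (n_patients, len(grid), n_genes); ``provenance`` the
    same shape with integer codes from :data:`PROVENANCE_CODES` (−1 marks a
    cell that could not be resolved and must be removed by
    :func:`split_complete_cases` before analysis).
    """

    values: np.ndarray
    provenance: np.ndarray
    patients: tuple
    genes: tuple
    grid: TimeGrid

    def __post_init__(self):
        if self.values.shape != self.provenance.shape:
            raise ValueError("values and provenance shapes differ")
        if self.values.shape != (len(self.patients), len(self.grid), len(self.genes)):
            raise ValueError("values shape inconsistent with patients/grid/genes")

    def series(self, patient_id) -> np.ndarray:
        return self.values[self.patients.index(patient_id)]

    @property
    def n_missing_cells(self) -> int:
        return int((self.provenance == PROVENANCE_CODES["missing"]).sum())

    def to_frame(self) -> pd.DataFrame:
        """Long frame (patient_id, day, gene_id, value, provenance)."""
        n, q, g = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.patients, self.grid.selected_days, self.genes],
            names=["patient_id", "day", "gene_id"])
        return pd.DataFrame({
            "value": self.values.ravel(),
            "provenance": [_PROVENANCE_NAMES[c] for c in self.provenance.ravel()],
        }, index=idx).reset_index()

    def write_csv(self, values_path: str | Path, provenance_path: str | Path) -> None:
        frame = self.to_frame()
        frame[["patient_id", "day", "gene_id", "value"]].to_csv(values_path, index=False)
        frame[["patient_id", "day", "gene_id", "provenance"]].to_csv(
            provenance_path, index=False)


def log_transform(table: pd.DataFrame, base: float = 2.0,
                  pseudocount: float = 0.0) -> pd.DataFrame:
    """Log-transform expression values (base 2 by default)."""
    validate_expression(table)
    out = table.copy()
    out["value"] = np.log(out["value"] + pseudocount) / np.log(base)
    return out


def _followup_proxy(table: pd.DataFrame) -> dict:
    return table.groupby("patient_id")["day"].max().to_dict()


def select_time_points(table: pd.DataFrame, max_missing_frac: float = 0.5,
                       survival: SurvivalTable | None = None,
                       denominator: str = "under_followup") -> TimeGrid:
    """Days whose missingness fraction is *strictly* below the threshold.

    The fraction for day d is (# under-follow-up patients with no draw at d)
    / (# under-follow-up patients at d). "Under follow-up" uses the survival
    table when given, else each patient's last observed day as a proxy.
    ``denominator="all"`` instead counts every cohort patient at every day.
    """
    validate_expression(table)
    if not 0.0 < max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in (0, 1]")
    if table.empty:
        raise ValueError("empty expression table")
    if denominator not in ("under_followup", "all"):
        raise ValueError("denominator must be 'under_followup' or 'all'")
    patients = table["patient_id"].unique()
    days = np.sort(table["day"].unique())
    observed = set(map(tuple, table[["patient_id", "day"]].drop_duplicates().values))
    if denominator == "under_followup":
        if survival is not None:
            fu = {p: t for p, t in zip(survival.patient_id, survival.time_days)}
        else:
            fu = _followup_proxy(table)
    selected = []
    for d in days:
        if denominator == "all":
            at_risk = list(patients)
        else:
            at_risk = [p for p in patients if fu.get(p, -np.inf) >= d]
        if not at_risk:
            continue
        n_missing = sum((p, d) not in observed for p in at_risk)
        if n_missing / len(at_risk) < max_missing_frac:
            selected.append(int(d))
    if not selected:
        raise ValueError("no day satisfies the missingness threshold")
    return TimeGrid(tuple(selected))


def _patient_blocks(table: pd.DataFrame, genes):
    """Per patient: (sorted observed days, day -> gene-value vector)."""
    gene_pos = {g: i for i, g in enumerate(genes)}
    blocks = {}
    for (pid, day), sub in table.groupby(["patient_id", "day"], sort=True):
        vec = np.full(len(genes), np.nan)
        vec[[gene_pos[g] for g in sub["gene_id"]]] = sub["value"].to_numpy()
        blocks.setdefault(pid, {})[int(day)] = vec
    return blocks


def impute_mixed(table: pd.DataFrame, grid: TimeGrid, max_carry_days: int = 2,
                 prefer: str = "past", day_universe=None) -> CompleteSeriesSet:
    """Windowed LOCF/NOCB carrying with linear-interpolation fallback.

    ``prefer`` breaks the tie when past and future draws are equidistant
    within the carry window ("past" = LOCF first, the default).
    ``day_universe`` optionally names the nominal design schedule S; when
    given, the grid must be a subset of it.
    """
    validate_expression(table)
    if max_carry_days < 0:
        raise ValueError("max_carry_days must be non-negative")
    if prefer not in ("past", "future"):
        raise ValueError("prefer must be 'past' or 'future'")
    if day_universe is not None and not set(grid.selected_days) <= set(day_universe):
        raise ValueError("grid must be a subset of the design schedule")
    genes = tuple(sorted(table["gene_id"].unique()))
    patients = tuple(sorted(table["patient_id"].unique()))
    blocks = _patient_blocks(table, genes)
    Q = len(grid)
    values = np.full((len(patients), Q, len(genes)), np.nan)
    prov = np.full((len(patients), Q, len(genes)), PROVENANCE_CODES["missing"],
                   dtype=np.int8)
    for i, pid in enumerate(patients):
        obs = blocks.get(pid, {})
        obs_days = np.array(sorted(obs), dtype=int)
        for q, day in enumerate(grid.selected_days):
            if day in obs:
                values[i, q] = obs[day]
                prov[i, q] = PROVENANCE_CODES["observed"]
                continue
            past = obs_days[obs_days < day]
            future = obs_days[obs_days > day]
            d_past = day - past[-1] if past.size else np.inf
            d_future = future[0] - day if future.size else np.inf
            # windowed carry, nearest observation wins
            best = min(d_past, d_future)
            if best <= max_carry_days:
                take_past = d_past < d_future or (
                    d_past == d_future and prefer == "past")
                if take_past:
                    values[i, q] = obs[int(past[-1])]
                    prov[i, q] = PROVENANCE_CODES["carried_forward"]
                else:
                    values[i, q] = obs[int(future[0])]
                    prov[i, q] = PROVENANCE_CODES["carried_backward"]
                continue
            # linear interpolation between closest bracketing observations
            if past.size and future.size:
                t0, t1 = int(past[-1]), int(future[0])
                frac = (day - t0) / (t1 - t0)
                values[i, q] = obs[t0] + (obs[t1] - obs[t0]) * frac
                prov[i, q] = PROVENANCE_CODES["interpolated"]
            # else: unresolved, stays missing (handled by the horizon split)
    # per-gene NaNs inside resolved draws propagate; mark them missing
    nan_mask = np.isnan(values) & (prov != PROVENANCE_CODES["missing"])
    prov[nan_mask] = PROVENANCE_CODES["missing"]
    return CompleteSeriesSet(values, prov, patients, genes, grid)


def impute_locf(table: pd.DataFrame, grid: TimeGrid) -> CompleteSeriesSet:
    """Pure last-observation-carried-forward baseline (unbounded carry).

    Used as the comparison method for the mixed strategy; leading cells with
    no past observation stay missing.
    """
    validate_expression(table)
    genes = tuple(sorted(table["gene_id"].unique()))
    patients = tuple(sorted(table["patient_id"].unique()))
    blocks = _patient_blocks(table, genes)
    Q = len(grid)
    values = np.full((len(patients), Q, len(genes)), np.nan)
    prov = np.full((len(patients), Q, len(genes)), PROVENANCE_CODES["missing"],
                   dtype=np.int8)
    for i, pid in enumerate(patients):
        obs = blocks.get(pid, {})
        obs_days = np.array(sorted(obs), dtype=int)
        for q, day in enumerate(grid.selected_days):
            if day in obs:
                values[i, q] = obs[day]
                prov[i, q] = PROVENANCE_CODES["observed"]
                continue
            past = obs_days[obs_days < day]
            if past.size:
                values[i, q] = obs[int(past[-1])]
                prov[i, q] = PROVENANCE_CODES["carried_forward"]
    nan_mask = np.isnan(values) & (prov != PROVENANCE_CODES["missing"])
    prov[nan_mask] = PROVENANCE_CODES["missing"]
    return CompleteSeriesSet(values, prov, patients, genes, grid)


def split_complete_cases(series_set: CompleteSeriesSet,
                         horizon_day: int) -> CompleteSeriesSet:
    """Complete cases up to a horizon: keep patients fully resolved at every
    grid day <= horizon, truncating the grid at the horizon."""
    if horizon_day not in series_set.grid.selected_days:
        raise ValueError("horizon_day must be a day of the grid")
    days = series_set.grid.selected_days
    q_keep = [q for q, d in enumerate(days) if d <= horizon_day]
    sub_vals = series_set.values[:, q_keep, :]
    sub_prov = series_set.provenance[:, q_keep, :]
    complete = ~(sub_prov == PROVENANCE_CODES["missing"]).any(axis=(1, 2))
    idx = np.flatnonzero(complete)
    return CompleteSeriesSet(
        sub_vals[idx].copy(), sub_prov[idx].copy(),
        tuple(series_set.patients[i] for i in idx), series_set.genes,
        TimeGrid(tuple(days[q] for q in q_keep)))
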