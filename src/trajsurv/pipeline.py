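"""End-to-end orchestration: per-day sparse gene selection with alpha tuning,
LOOCV-intersection stability selection, union signature, mixed imputation,
GAK/PAM clustering per horizon, and survival validation.

The framework has two phases. The *static* phase looks at single-day
expression snapshots (days 0, 1 and 4 by default): an elastic-net Cox model
is tuned on a 70/30 split (alpha by held-out c-index, lambda by
cross-validation), then refit n times leaving one patient out; genes with a
nonzero coefficient in every leave-one-out refit form that day's stable set,
and the union over days is the gene signature. The *longitudinal* phase
restricts the cohort to the signature, imputes complete short series on the
low-missingness day grid, splits into complete-case horizon datasets, and
clusters patient trajectories with PAM on GAK distances, choosing the
cluster count by log-rank survival separation.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coxnet import CoxnetFit, cv_coxnet, linear_predictor
from .imputation import (impute_mixed, log_transform, select_time_points,
                         split_complete_cases)
from .gak import GAKParams, cross_distance_matrix, select_k, sigma_heuristic
from .io import validate_expression, write_json
from .survival import (SurvivalTable, concordance_index, km_estimate,
                       logrank_test)

__all__ = ["PipelineConfig", "SelectionReport", "day_snapshot", "select_alpha",
           "loocv_intersection", "build_union_signature", "risk_stratify",
           "run_pipeline"]


def _derive_seed(root: int, *keys) -> int:
    """Deterministic per-stage child seed (< 2**31) from the root seed."""
    spawn = tuple(
        int.from_bytes(hashlib.sha256(k.encode()).digest()[:4], "big")
        if isinstance(k, str) else int(k)
        for k in keys)
    return int(np.random.SeedSequence(root, spawn_key=spawn).generate_state(1)[0]
               % (2**31))


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration mirroring the framework's tunable choices."""

    selection_days: tuple = (0, 1, 4)
    alpha_grid: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    train_frac: float = 0.7
    grid_threshold: float = 0.5
    max_carry_days: int = 2
    horizons: tuple = (7, 28)
    k_range: tuple = (2, 3, 4, 5, 6)
    min_cluster_size: int = 2
    n_folds: int = 10
    n_lambda: int = 30
    lambda_min_ratio: float = 0.05
    stratify_split: bool = False     # stratify the 70/30 split by event status
    shared_split: bool = False       # one split reused across selection days
    sigma: float | None = None       # None = median heuristic
    window_order: int = 0
    pam_n_init: int = 5
    log_base: float | None = None    # None = values are already log-scale
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        if len(self.alpha_grid) == 0:
            raise ValueError("alpha_grid must be non-empty")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SelectionReport:
    """Static-phase outcome: per-day tuning and stability results."""

    alpha_opt: float
    cindex_table: pd.DataFrame          # rows: day, columns: alpha
    per_day_stable: dict                # day -> tuple of gene ids
    per_day_test_cindex: dict           # day -> c-index at alpha_opt
    union_signature: tuple
    gene_provenance: dict               # gene -> list of days that selected it
    seeds: dict

    def to_jsonable(self) -> dict:
        return {
            "alpha_opt": self.alpha_opt,
            "cindex_table": {str(day): {str(a): float(v)
                                        for a, v in row.items()}
                             for day, row in self.cindex_table.iterrows()},
            "per_day_stable": {str(d): list(g) for d, g in self.per_day_stable.items()},
            "per_day_test_cindex": {str(d): float(v)
                                    for d, v in self.per_day_test_cindex.items()},
            "union_signature": list(self.union_signature),
            "gene_provenance": {g: list(d) for g, d in self.gene_provenance.items()},
            "seeds": self.seeds,
        }


# ---------------------------------------------------------------------------
# static phase
# ---------------------------------------------------------------------------

def day_snapshot(expression: pd.DataFrame, day: int, genes=None):
    """One-row-per-patient expression matrix for a single day.

    Patients without a draw that day are excluded (they are not imputed in
    the static phase). Returns (X, patient_ids, gene_ids).
    """
    validate_expression(expression)
    sub = expression[expression["day"] == day]
    if sub.empty:
        raise ValueError(f"no measurements on day {day}")
    wide = sub.pivot_table(index="patient_id", columns="gene_id", values="value")
    if genes is not None:
        wide = wide[[g for g in genes if g in wide.columns]]
    wide = wide.dropna(axis=0)
    return (wide.to_numpy(), tuple(wide.index), tuple(wide.columns))


def _train_test_split(patient_ids, surv: SurvivalTable, train_frac: float,
                      seed: int, stratify: bool):
    n = len(patient_ids)
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    if stratify:
        ev = surv.reindex(patient_ids).event
        train = []
        for val in (0, 1):
            grp = idx[ev == val]
            grp = rng.permutation(grp)
            train.extend(grp[:int(round(train_frac * len(grp)))])
        train = np.sort(np.asarray(train, dtype=int))
    else:
        perm = rng.permutation(idx)
        train = np.sort(perm[:int(round(train_frac * n))])
    test = np.setdiff1d(idx, train)
    return train, test


def select_alpha(snapshots: dict, surv: SurvivalTable, alpha_grid=(0.2, 0.4, 0.6, 0.8, 1.0),
                 train_frac: float = 0.7, seed: int = 0, n_folds: int = 10,
                 n_lambda: int = 30, lambda_min_ratio: float = 0.05,
                 stratify: bool = False, shared_split: bool = False):
    """Tune the elastic-net mixing parameter on held-out c-index.

    ``snapshots`` maps day -> (X, patient_ids, gene_ids). Each day gets a
    seeded train/test split; per alpha, lambda is chosen by cross-validation
    on the training part and the test c-index of the linear predictor is
    recorded. The winning alpha maximizes the mean c-index across days
    (a single shared choice); ties go to the larger, sparser alpha.

    Returns ``(alpha_opt, cindex_table, details)`` with ``details[day]``
    holding the split indices and the per-alpha fits for reuse.
    """
    alpha_grid = tuple(dict.fromkeys(alpha_grid))  # dedupe, keep order
    table = {}
    details = {}
    for day, (X, pids, genes) in sorted(snapshots.items()):
        surv_day = surv.reindex(pids)
        split_seed = (_derive_seed(seed, "split") if shared_split
                      else _derive_seed(seed, "split", day))
        train, test = _train_test_split(pids, surv_day, train_frac,
                                        split_seed, stratify)
        surv_train = surv_day.subset(np.isin(np.arange(len(pids)), train))
        surv_test = surv_day.subset(np.isin(np.arange(len(pids)), test))
        row = {}
        fits = {}
        for alpha in alpha_grid:
            _, fit = cv_coxnet(X[train], surv_train, alpha, n_folds=n_folds,
                               seed=_derive_seed(seed, "cv", day),
                               n_lambda=n_lambda,
                               lambda_min_ratio=lambda_min_ratio,
                               feature_names=genes)
            scores = linear_predictor(fit, X[test])
            try:
                row[alpha] = concordance_index(surv_test, scores)
            except ValueError:
                row[alpha] = np.nan
            fits[alpha] = fit
        table[day] = row
        details[day] = {"train": train, "test": test, "fits": fits,
                        "patients": pids, "genes": genes,
                        "surv_test": surv_test, "X": X}
    cindex_table = pd.DataFrame(table).T[list(alpha_grid)]
    mean_c = cindex_table.mean(axis=0)
    best = mean_c.max()
    alpha_opt = max(a for a in alpha_grid if mean_c[a] >= best - 1e-12)
    return float(alpha_opt), cindex_table, details


def loocv_intersection(X, surv: SurvivalTable, alpha: float, seed: int = 0,
                       n_folds: int = 10, n_lambda: int = 30,
                       lambda_min_ratio: float = 0.05, rule: str = "1se",
                       feature_names=None):
    """Stability selection: genes with nonzero coefficients in *every*
    leave-one-out refit (lambda re-chosen by CV inside each refit).

    Lambda inside each refit follows the one-standard-error rule by default:
    stability selection wants the sparsest model the data support, and the
    deviance minimum is known to overselect, which would leak chance
    correlates into every refit and hence into the intersection.

    Leave-one-out training sets without events are skipped with a warning;
    the intersection is over the completed refits. Returns
    ``(stable_genes, n_completed)``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV stability selection needs n >= 3")
    names = tuple(feature_names) if feature_names is not None else tuple(range(X.shape[1]))
    stable = None
    completed = 0
    for i in range(n):
        keep = np.arange(n) != i
        surv_i = SurvivalTable(surv.patient_id[keep], surv.time_days[keep],
                               surv.event[keep])
        if surv_i.n_events == 0:
            warnings.warn(f"LOO fold {i} has no events; skipped", stacklevel=2)
            continue
        _, fit = cv_coxnet(X[keep], surv_i, alpha, n_folds=min(n_folds, n - 1),
                           seed=_derive_seed(seed, "loo", i),
                           n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
                           rule=rule, feature_names=names)
        support = set(fit.support_names)
        stable = support if stable is None else (stable & support)
        completed += 1
        if stable is not None and len(stable) == 0:
            break  # intersection can only shrink
    if stable is None:
        raise ValueError("no completed leave-one-out refit")
    return tuple(sorted(stable, key=list(names).index)), completed


def build_union_signature(per_day_sets: dict):
    """Sorted union of the per-day stable sets with per-gene provenance."""
    if not per_day_sets or all(len(s) == 0 for s in per_day_sets.values()):
        raise ValueError("all per-day stable sets are empty")
    provenance: dict = {}
    for day, genes in sorted(per_day_sets.items()):
        for g in genes:
            provenance.setdefault(g, []).append(day)
    signature = tuple(sorted(provenance))
    return signature, provenance


def risk_stratify(fit: CoxnetFit, X_test, surv_test: SurvivalTable):
    """Median split of the linear predictor into high/low risk with KM curves
    and a two-group log-rank test. High risk = earlier expected discharge."""
    scores = linear_predictor(fit, X_test)
    if np.ptp(scores) == 0:
        raise ValueError("degenerate split: all risk scores equal")
    order = np.argsort(-scores, kind="stable")
    n = len(scores)
    labels = np.empty(n, dtype=object)
    labels[order[: n // 2]] = "high"
    labels[order[n // 2:]] = "low"
    km_high = km_estimate(surv_test.subset(labels == "high"))
    km_low = km_estimate(surv_test.subset(labels == "low"))
    test = logrank_test(surv_test, labels)
    return km_high, km_low, test


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, expression: pd.DataFrame,
                 survival: SurvivalTable, out_dir: str | Path | None = None):
    """Run the full framework; optionally write the report bundle to disk.

    Returns a dict with the selection report, imputation products, per-horizon
    clustering results, and the run manifest. Outputs are deterministic for a
    fixed config and inputs (the manifest carries no timestamps).
    """
    validate_expression(expression)
    cfg = config
    if cfg.log_base is not None:
        expression = log_transform(expression, base=cfg.log_base)

    # --- static phase -----------------------------------------------------
    snapshots = {}
    for day in cfg.selection_days:
        try:
            snapshots[day] = day_snapshot(expression, day)
        except ValueError as exc:
            raise ValueError(f"selection stage failed for day {day}: {exc}") from exc
    alpha_opt, cindex_table, details = select_alpha(
        snapshots, survival, cfg.alpha_grid, cfg.train_frac, cfg.seed,
        n_folds=cfg.n_folds, n_lambda=cfg.n_lambda,
        lambda_min_ratio=cfg.lambda_min_ratio, stratify=cfg.stratify_split,
        shared_split=cfg.shared_split)

    per_day_stable = {}
    per_day_cindex = {}
    stratification = {}
    for day, (X, pids, genes) in sorted(snapshots.items()):
        stable, _ = loocv_intersection(
            X, survival.reindex(pids), alpha_opt,
            seed=_derive_seed(cfg.seed, "loocv", day), n_folds=cfg.n_folds,
            n_lambda=cfg.n_lambda, lambda_min_ratio=cfg.lambda_min_ratio,
            feature_names=genes)
        per_day_stable[day] = stable
        det = details[day]
        fit = det["fits"][alpha_opt]
        per_day_cindex[day] = float(cindex_table.loc[day, alpha_opt])
        try:
            km_h, km_l, lr = risk_stratify(fit, det["X"][det["test"]],
                                           det["surv_test"])
            stratification[day] = {"km_high": km_h, "km_low": km_l, "logrank": lr}
        except ValueError as exc:
            stratification[day] = {"error": str(exc)}

    signature, provenance = build_union_signature(per_day_stable)
    report = SelectionReport(
        alpha_opt=alpha_opt, cindex_table=cindex_table,
        per_day_stable=per_day_stable, per_day_test_cindex=per_day_cindex,
        union_signature=signature, gene_provenance=provenance,
        seeds={"root": cfg.seed})

    # --- longitudinal phase ----------------------------------------------
    expr_sig = expression[expression["gene_id"].isin(signature)].reset_index(drop=True)
    grid = select_time_points(expr_sig, cfg.grid_threshold, survival=survival)
    complete = impute_mixed(expr_sig, grid, max_carry_days=cfg.max_carry_days)

    clustering = {}
    for horizon in cfg.horizons:
        if horizon not in grid.selected_days:
            warnings.warn(f"horizon {horizon} not on the selected grid "
                          f"{grid.selected_days}; skipped", stacklevel=2)
            continue
        ds = split_complete_cases(complete, horizon)
        if len(ds.patients) < max(cfg.k_range) + 1:
            warnings.warn(f"horizon {horizon}: only {len(ds.patients)} complete "
                          "cases; clustering skipped", stacklevel=2)
            continue
        sigma = cfg.sigma or sigma_heuristic(ds, seed=_derive_seed(cfg.seed, "sigma", horizon))
        params = GAKParams(sigma=sigma, window_order=cfg.window_order)
        dm = cross_distance_matrix(ds, params)
        k_opt, partition, k_table = select_k(
            ds, survival, cfg.k_range, min_cluster_size=cfg.min_cluster_size,
            seed=_derive_seed(cfg.seed, "pam", horizon), dm=dm,
            n_init=cfg.pam_n_init)
        surv_h = survival.reindex(ds.patients)
        cluster_km = {int(c): km_estimate(surv_h.subset(partition.labels == c))
                      for c in np.unique(partition.labels)}
        clustering[horizon] = {
            "dataset": ds, "sigma": float(sigma), "distance_matrix": dm,
            "k_opt": int(k_opt), "partition": partition, "k_table": k_table,
            "logrank": logrank_test(surv_h, partition.labels),
            "cluster_km": cluster_km,
        }

    manifest = {
        "package_version": __version__,
        "config": cfg.to_jsonable(),
        "config_hash": cfg.config_hash(),
        "n_patients": int(expression["patient_id"].nunique()),
        "n_genes": int(expression["gene_id"].nunique()),
        "signature_size": len(signature),
        "grid": list(grid.selected_days),
    }
    bundle = {
        "selection": report,
        "stratification": stratification,
        "grid": grid,
        "complete_series": complete,
        "clustering": clustering,
        "manifest": manifest,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report: SelectionReport = bundle["selection"]
    write_json(report.to_jsonable(), out_dir / "selection_report.json")
    write_json(bundle["manifest"], out_dir / "manifest.json")
    bundle["complete_series"].write_csv(out_dir / "complete_series.csv",
                                        out_dir / "complete_series_provenance.csv")
    for day, strat in bundle["stratification"].items():
        if "error" in strat:
            continue
        strat["km_high"].to_frame().to_csv(out_dir / f"km_day{day}_high.csv", index=False)
        strat["km_low"].to_frame().to_csv(out_dir / f"km_day{day}_low.csv", index=False)
    for horizon, res in bundle["clustering"].items():
        res["partition"].to_frame().to_csv(
            out_dir / f"partition_h{horizon}.csv", index=False)
        res["k_table"].to_csv(out_dir / f"k_selection_h{horizon}.csv", index=False)
        pd.DataFrame(res["distance_matrix"],
                     index=list(res["dataset"].patients),
                     columns=list(res["dataset"].patients)).to_csv(
            out_dir / f"gak_distance_h{horizon}.csv")
        lr = res["logrank"]
        write_json({"horizon": horizon, "k_opt": res["k_opt"],
                    "sigma": res["sigma"],
                    "logrank": {"statistic": lr.statistic, "df": lr.df,
                                "p_value": lr.p_value}},
                   out_dir / f"clustering_summary_h{horizon}.json")
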