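"""Repeated-cross-validation random-forest ensembles.

The prediction engine of the pipeline: for each input set (taxa, gene
functions, demographics) and target (composite score, subscale, or
brain-region volume fraction), many independent regression forests are
fit under a repeated-CV scheme — ``n_repetitions`` fresh fold
partitions x ``n_folds`` folds x ``n_rng_states`` forest seeds — and
their per-feature mean-decrease-in-impurity importances are averaged
with weights given by each model's *fitness*,

    fitness = max(r_train, 0) * max(r_test, 0),

which up-weights generalizing models and zeroes both overfit
(r_test <= 0) and underfit (r_train <= 0) ones. Feature selection
reports the shortest prefix of descending-importance features reaching
a cumulative fraction (0.6 for cognition models, 0.5 for brain-region
models in the reported analyses).

Determinism: every forest and every fold partition is seeded from
``base_seed`` through a ``SeedSequence`` keyed on (base_seed,
repetition, fold, rng-state), so results are independent of execution
order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .core_data import CohortTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleConfig:
    """Repeated-CV scheme and forest hyperparameters.

    Defaults follow the classical Breiman regression settings:
    100 trees, ceil(p/3) candidate features per split, minimum leaf
    size 5, unlimited depth.
    """

    n_repetitions: int = 100
    n_folds: int = 3
    n_rng_states: int = 10
    base_seed: int = 0
    n_trees: int = 100
    min_samples_leaf: int = 5
    predictors: tuple[str, ...] = ("taxa",)  # subset of {taxa, genes, demographics}
    target: str = "cognitive_score"
    include_age: bool = True  # age is a covariate for all models unless overridden

    def __post_init__(self) -> None:
        for name in ("n_repetitions", "n_folds", "n_rng_states", "n_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        unknown = set(self.predictors) - {"taxa", "genes", "demographics"}
        if unknown:
            raise ValueError(f"unknown predictor blocks: {sorted(unknown)}")

    @property
    def total_models(self) -> int:
        return self.n_repetitions * self.n_folds * self.n_rng_states


@dataclass
class ModelRecord:
    """Metrics and importances of one fitted forest."""

    repetition: int
    fold: int
    rng_state: int
    r_train: float
    r_test: float
    rmse_train: float
    rmse_test: float
    mape_test: float | None
    importances: np.ndarray  # per-feature MDI, sums to 1


@dataclass
class RFEnsembleResult:
    config: EnsembleConfig
    feature_names: list[str]
    records: list[ModelRecord]
    aggregate_importances: np.ndarray
    selected_features: list[str]
    summary: dict[str, float]
    n_constant_prediction_models: int = 0

    def importance_series(self) -> pd.Series:
        return pd.Series(
            self.aggregate_importances, index=self.feature_names
        ).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# primitives


def fitness(r_train: float, r_test: float) -> float:
    """Model fitness: max(r_train, 0) * max(r_test, 0). NaN counts as 0."""
    rt = 0.0 if np.isnan(r_train) else r_train
    rv = 0.0 if np.isnan(r_test) else r_test
    return max(rt, 0.0) * max(rv, 0.0)


def regression_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float]:
    """(rmse, mape, pearson_r); r is 0 with a warning if either side is
    constant; mape requires all y_true nonzero (NaN otherwise)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    if y_true.size < 2:
        raise ValueError("need at least 2 points")
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    if (y_true == 0).any():
        mape = float("nan")
    else:
        mape = float(np.mean(np.abs(y_pred - y_true) / np.abs(y_true)))
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        warnings.warn("constant vector in correlation; returning r = 0", stacklevel=2)
        r = 0.0
    else:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return rmse, mape, r


def aggregate_importances(records: Sequence[ModelRecord]) -> np.ndarray:
    """Fitness-weighted mean of per-model importances, renormalized to
    sum 1; falls back to the unweighted mean if every fitness is 0."""
    if not records:
        raise ValueError("no model records")
    imp = np.stack([m.importances for m in records])
    w = np.array([fitness(m.r_train, m.r_test) for m in records])
    if w.sum() == 0:
        logger.warning("all model fitnesses are 0; using unweighted mean importances")
        agg = imp.mean(axis=0)
    else:
        agg = (w[:, None] * imp).sum(axis=0) / w.sum()
    total = agg.sum()
    return agg / total if total > 0 else agg


def cumulative_select(
    weights: Sequence[float], feature_names: Sequence[str], fraction: float
) -> list[str]:
    """Shortest prefix of descending-weight features whose weights sum
    to at least ``fraction`` (ties broken lexicographically by name)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    w = np.asarray(weights, dtype=float)
    order = sorted(range(w.size), key=lambda i: (-w[i], feature_names[i]))
    total = 0.0
    selected = []
    for i in order:
        selected.append(feature_names[i])
        total += w[i]
        if total >= fraction - 1e-12:
            break
    return selected


# ---------------------------------------------------------------------------
# design assembly


def build_design(
    cohort: CohortTable,
    predictors: Sequence[str] = ("taxa",),
    include_age: bool = True,
    gene_table=None,
) -> tuple[np.ndarray, list[str]]:
    """Predictor matrix for the ensemble.

    ``predictors`` picks blocks: "taxa" and/or "genes" use the raw
    relative abundances of the cohort's feature table (or the
    sample-aligned ``gene_table``), "demographics" adds sex and
    maternal education. Age in months is appended unless
    ``include_age=False``.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for block in predictors:
        if block in ("taxa", "genes"):
            table = cohort.table
            if block == "genes" and gene_table is not None:
                table = gene_table.select_samples([r.sample_id for r in cohort.records])
            if (block == "taxa") != (table.feature_kind == "taxon"):
                raise ValueError(
                    f"predictor block {block!r} does not match table kind {table.feature_kind!r}"
                )
            blocks.append(table.values)
            names.extend(table.feature_ids)
        elif block == "demographics":
            demo = cohort.covariates(("sex", "maternal_education"))
            blocks.append(demo.to_numpy())
            names.extend(demo.columns)
    if include_age:
        blocks.append(np.array([[r.age_months] for r in cohort.records]))
        names.append("age_months")
    if not blocks:
        raise ValueError("empty predictor design")
    return np.column_stack(blocks), names


# ---------------------------------------------------------------------------
# the ensemble


def _seed_for(base_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence((int(base_seed),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def run_ensemble_matrix(
    x: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    config: EnsembleConfig,
    compute_mape: bool = False,
    cumulative_fraction: float = 0.6,
) -> RFEnsembleResult:
    """Repeated-CV forest ensemble on an explicit design matrix."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if n < 3 * config.n_folds:
        raise ValueError(f"need at least {3 * config.n_folds} samples, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("constant target")
    max_features = min(p, max(1, ceil(p / 3)))
    records: list[ModelRecord] = []
    n_constant = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-split correlation warnings tallied below
        for rep in range(config.n_repetitions):
            kf = KFold(
                n_splits=config.n_folds, shuffle=True,
                random_state=_seed_for(config.base_seed, rep, 10**6, 0),
            )
            for fold, (tr_idx, te_idx) in enumerate(kf.split(x)):
                for rng_state in range(config.n_rng_states):
                    forest = RandomForestRegressor(
                        n_estimators=config.n_trees,
                        max_features=max_features,
                        min_samples_leaf=config.min_samples_leaf,
                        random_state=_seed_for(config.base_seed, rep, fold, rng_state),
                        n_jobs=1,
                    )
                    forest.fit(x[tr_idx], y[tr_idx])
                    pred_tr = forest.predict(x[tr_idx])
                    pred_te = forest.predict(x[te_idx])
                    rmse_tr, _, r_tr = regression_metrics(y[tr_idx], pred_tr)
                    rmse_te, mape_te, r_te = regression_metrics(y[te_idx], pred_te)
                    if np.std(pred_te) == 0 or np.std(pred_tr) == 0:
                        n_constant += 1
                    imp = forest.feature_importances_
                    total = imp.sum()
                    imp = imp / total if total > 0 else np.full(p, 1.0 / p)
                    records.append(ModelRecord(
                        repetition=rep, fold=fold, rng_state=rng_state,
                        r_train=r_tr, r_test=r_te,
                        rmse_train=rmse_tr, rmse_test=rmse_te,
                        mape_test=mape_te if compute_mape else None,
                        importances=imp,
                    ))
    agg = aggregate_importances(records)
    summary = summarize_records(records, compute_mape=compute_mape)
    selected = cumulative_select(agg, list(feature_names), cumulative_fraction)
    if n_constant:
        logger.info("%d of %d models produced constant predictions", n_constant, len(records))
    return RFEnsembleResult(
        config=config, feature_names=list(feature_names), records=records,
        aggregate_importances=agg, selected_features=selected, summary=summary,
        n_constant_prediction_models=n_constant,
    )


def run_ensemble(
    cohort: CohortTable,
    config: EnsembleConfig,
    gene_table=None,
    cumulative_fraction: float = 0.6,
) -> RFEnsembleResult:
    """Repeated-CV forest ensemble on a cohort, per the config's
    predictor blocks and target."""
    x, names = build_design(
        cohort, config.predictors, include_age=config.include_age, gene_table=gene_table
    )
    y = cohort.outcome(config.target)
    return run_ensemble_matrix(
        x, y, names, config, compute_mape=False, cumulative_fraction=cumulative_fraction
    )


def summarize_records(
    records: Sequence[ModelRecord], compute_mape: bool = False
) -> dict[str, float]:
    """Mean and empirical 95% interval (2.5/97.5 percentiles) of test
    metrics across all records; NaN correlations are excluded from the
    metric means (their count is reported)."""
    r_test = np.array([m.r_test for m in records])
    rmse_test = np.array([m.rmse_test for m in records])
    valid = ~np.isnan(r_test)
    out = {
        "n_models": float(len(records)),
        "n_nan_correlations": float((~valid).sum()),
        "mean_test_correlation": float(r_test[valid].mean()) if valid.any() else float("nan"),
        "test_correlation_lo": float(np.percentile(r_test[valid], 2.5)) if valid.any() else float("nan"),
        "test_correlation_hi": float(np.percentile(r_test[valid], 97.5)) if valid.any() else float("nan"),
        "mean_test_rmse": float(np.nanmean(rmse_test)),
        "test_rmse_lo": float(np.nanpercentile(rmse_test, 2.5)),
        "test_rmse_hi": float(np.nanpercentile(rmse_test, 97.5)),
        "mean_train_correlation": float(np.nanmean([m.r_train for m in records])),
        "mean_train_rmse": float(np.nanmean([m.rmse_train for m in records])),
    }
    if compute_mape:
        mapes = np.array([m.mape_test for m in records], dtype=float)
        out["mean_test_mape"] = float(np.nanmean(mapes))
    return out


def brain_region_battery(
    cohort: CohortTable,
    normalized_volumes: pd.DataFrame,
    config: EnsembleConfig,
    cumulative_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, RFEnsembleResult]]:
    """One ensemble per brain region (targets are volume fractions of
    total brain volume); returns a summary table (region, mean test
    MAPE, mean test r) and the per-region results with their aggregate
    importances for the importance-matrix display.

    The uniform-importance baseline for that display is 1/n_features.
    """
    sample_ids = [r.sample_id for r in cohort.records]
    missing = [s for s in sample_ids if s not in normalized_volumes.index]
    if missing:
        raise ValueError(f"brain volumes missing for samples {missing[:5]}")
    vols = normalized_volumes.loc[sample_ids]
    x, names = build_design(cohort, config.predictors, include_age=config.include_age)
    rows = []
    results: dict[str, RFEnsembleResult] = {}
    for region in vols.columns:
        y = vols[region].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            logger.warning("region %s skipped: zero variance", region)
            continue
        res = run_ensemble_matrix(
            x, y, names, config, compute_mape=True,
            cumulative_fraction=cumulative_fraction,
        )
        results[region] = res
        rows.append({
            "region": region,
            "mean_test_mape": res.summary["mean_test_mape"],
            "mean_test_correlation": res.summary["mean_test_correlation"],
            "n_models": int(res.summary["n_models"]),
            "n_selected_features": len(res.selected_features),
        })
    if not rows:
        raise ValueError("no brain region had variance to model")
    return pd.DataFrame(rows), results
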