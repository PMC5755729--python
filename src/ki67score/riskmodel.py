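"""Random-forest harness predicting Oncotype DX Recurrence Scores.

A regression forest is trained on clinico-pathological variables (optionally
augmented with the RT-PCR ER/PgR/HER2 expression scores from the Oncotype DX
report) to predict the 0-100 Recurrence Score. Clinical performance is read
off the *risk groups* implied by the predicted scores, under repeated 50/50
train/test splits, and variable importance is the percent increase in mean
squared error (%IncMSE) when one predictor's held-out column is randomly
permuted.

Forest hyperparameters follow the published harness: 1000 trees, bootstrap
draws of 40 records per tree (with replacement), m_try of 15 with the RT-PCR
scores or 12 without, minimum node size 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .concordance import assign_risk_group, confusion_summary
from .errors import ConfigurationError, InvalidInputError, MissingDataError, SchemaError

__all__ = [
    "ForestParams",
    "FitResult",
    "ImportanceReport",
    "CVReport",
    "fit_forest",
    "predict_rs",
    "permutation_importance",
    "cross_validate",
]

METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class ForestParams:
    """Published harness hyperparameters.

    ``m_try`` defaults to 12 (the no-RT-PCR predictor set); pass 15 when the
    three Oncotype DX expression scores are included. ``m_try`` larger than
    the number of predictors is clipped with a warning.
    """

    n_tree: int = 1000
    m_try: int = 12
    sampsize: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tree < 1 or self.m_try < 1 or self.sampsize < 1:
            raise ConfigurationError("n_tree, m_try and sampsize must be >= 1")


@dataclass
class FitResult:
    """A fitted forest plus the context needed to apply and audit it."""

    model: RandomForestRegressor
    predictors: list[str]
    n_train: int


@dataclass
class ImportanceReport:
    """Per-predictor %IncMSE (mean +/- sd over rounds, descending rank)."""

    table: pd.DataFrame  # columns: predictor, mean_pct_inc_mse, sd_pct_inc_mse, rank
    zero_baseline: bool = False  # MSE_base was 0; values are absolute MSE increases


@dataclass
class CVReport:
    """Aggregated cross-validation outcome.

    ``aggregate`` maps each metric to (mean, sd, n_rounds_defined); per-round
    values (NaN where undefined) live in ``per_round``.
    """

    per_round: pd.DataFrame
    aggregate: dict[str, tuple[float, float, int]]
    n_rounds: int
    n_empty_rounds: int
    importance: ImportanceReport | None = None


def _check_matrix(records: pd.DataFrame, predictors: list[str], need_rs: bool) -> None:
    missing_cols = [c for c in predictors + (["rs"] if need_rs else []) if c not in records.columns]
    if missing_cols:
        raise SchemaError(f"cohort table is missing columns: {missing_cols}")
    if records[predictors].isna().any().any():
        raise MissingDataError(
            "records contain missing predictor values; the forest does not "
            "tolerate missing data — drop incomplete records first"
        )


def fit_forest(
    records: pd.DataFrame, predictors: list[str], params: ForestParams
) -> FitResult:
    """Grow a regression forest of ``n_tree`` trees on the given records.

    Each tree sees a bootstrap draw of ``sampsize`` records (with
    replacement) and considers ``m_try`` predictors per split; variance
    reduction splitting, minimum node size 5. Deterministic given the seed.
    """
    _check_matrix(records, predictors, need_rs=True)
    if records["rs"].isna().any():
        raise MissingDataError("records contain missing Recurrence Scores")
    if len(records) < 2:
        raise InvalidInputError("need at least 2 records to fit")
    m_try = params.m_try
    if m_try > len(predictors):
        warnings.warn(
            f"m_try={m_try} exceeds {len(predictors)} predictors; clipping",
            stacklevel=2,
        )
        m_try = len(predictors)
    model = RandomForestRegressor(
        n_estimators=params.n_tree,
        max_features=m_try,
        max_samples=min(params.sampsize, len(records)),
        bootstrap=True,
        min_samples_leaf=5,
        random_state=params.seed,
        n_jobs=1,
    )
    model.fit(records[predictors].to_numpy(dtype=float), records["rs"].to_numpy(dtype=float))
    return FitResult(model=model, predictors=list(predictors), n_train=len(records))


def predict_rs(fit: FitResult, records: pd.DataFrame) -> np.ndarray:
    """Forest-mean prediction, clipped into the score's [0, 100] range."""
    if len(records) == 0:
        return np.empty(0)
    _check_matrix(records, fit.predictors, need_rs=False)
    raw = fit.model.predict(records[fit.predictors].to_numpy(dtype=float))
    return np.clip(raw, 0.0, 100.0)


def permutation_importance(
    fit: FitResult, records: pd.DataFrame, seed: int
) -> ImportanceReport:
    """Single-round %IncMSE on held-out records.

    For each predictor v: %IncMSE_v = 100 * (MSE_perm(v) - MSE_base) / MSE_base,
    where MSE_perm permutes only column v (seeded). Noise predictors score
    near 0 and may go negative. A zero baseline MSE (perfect fit) is guarded
    by reporting absolute MSE increases with ``zero_baseline=True``.
    """
    if len(records) < 2:
        raise InvalidInputError("need at least 2 records for permutation importance")
    _check_matrix(records, fit.predictors, need_rs=True)
    X = records[fit.predictors].to_numpy(dtype=float)
    y = records["rs"].to_numpy(dtype=float)
    base_mse = float(np.mean((fit.model.predict(X) - y) ** 2))
    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(fit.predictors):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        mse = float(np.mean((fit.model.predict(Xp) - y) ** 2))
        if base_mse > 0:
            rows.append((name, 100.0 * (mse - base_mse) / base_mse))
        else:
            rows.append((name, mse - base_mse))
    table = pd.DataFrame(rows, columns=["predictor", "mean_pct_inc_mse"])
    table["sd_pct_inc_mse"] = 0.0
    table["rank"] = table["mean_pct_inc_mse"].rank(ascending=False, method="first").astype(int)
    table = table.sort_values("rank").reset_index(drop=True)
    return ImportanceReport(table=table, zero_baseline=base_mse == 0)


def cross_validate(
    cohort: pd.DataFrame,
    predictors: list[str],
    params: ForestParams,
    *,
    n_rounds: int = 1000,
    train_frac: float = 0.5,
    master_seed: int = 0,
    compute_importance: bool = True,
) -> CVReport:
    """Repeated 50/50 cross-validation with risk-group evaluation.

    Per round: a seeded split without replacement (train gets the ceiling
    half of an odd cohort); fit on train; predict the held-out half; map both
    predicted and actual scores to risk groups; tally the asymmetric
    confusion matrix (intermediates excluded). Rounds whose evaluation is
    empty contribute NaN and are excluded from the aggregates. Importance is
    computed on the held-out half each round and averaged.
    """
    if n_rounds < 1:
        raise ConfigurationError("n_rounds must be >= 1")
    if not 0 < train_frac < 1:
        raise ConfigurationError("train_frac must lie in (0, 1)")
    _check_matrix(cohort, predictors, need_rs=True)
    n = len(cohort)
    n_train = int(np.ceil(n * train_frac))
    if n - n_train < 1:
        raise InvalidInputError("cohort too small to split")
    if n_train < params.sampsize:
        warnings.warn(
            f"training half ({n_train}) smaller than sampsize ({params.sampsize})",
            stacklevel=2,
        )

    ss = np.random.SeedSequence(master_seed)
    round_seeds = ss.generate_state(3 * n_rounds, dtype=np.uint32).reshape(n_rounds, 3)
    per_round = []
    importances = []
    n_empty = 0
    for i in range(n_rounds):
        split_seed, fit_seed, perm_seed = (int(s) % (2**31) for s in round_seeds[i])
        rng = np.random.default_rng(split_seed)
        order = rng.permutation(n)
        train = cohort.iloc[order[:n_train]]
        test = cohort.iloc[order[n_train:]]
        fit = fit_forest(train, predictors, ForestParams(
            n_tree=params.n_tree, m_try=min(params.m_try, len(predictors)),
            sampsize=min(params.sampsize, n_train), seed=fit_seed,
        ))
        pred = predict_rs(fit, test)
        pred_groups = [assign_risk_group(v) for v in pred]
        actual_groups = [assign_risk_group(v) for v in test["rs"]]
        try:
            cs = confusion_summary(pred_groups, actual_groups)
            row = {m: getattr(cs, m) for m in METRICS}
        except InvalidInputError:
            n_empty += 1
            row = {m: np.nan for m in METRICS}
        per_round.append(row)
        if compute_importance:
            imp = permutation_importance(fit, test, perm_seed)
            importances.append(
                imp.table.set_index("predictor")["mean_pct_inc_mse"]
            )

    per_round_df = pd.DataFrame(per_round, dtype=float)
    aggregate = {}
    for m in METRICS:
        vals = per_round_df[m].dropna()
        aggregate[m] = (
            float(vals.mean()) if len(vals) else float("nan"),
            float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            int(len(vals)),
        )

    importance_report = None
    if compute_importance and importances:
        imp_df = pd.DataFrame(importances)  # rounds x predictors
        table = pd.DataFrame({
            "predictor": imp_df.columns,
            "mean_pct_inc_mse": imp_df.mean().to_numpy(),
            "sd_pct_inc_mse": imp_df.std(ddof=1).to_numpy(),
        })
        table["rank"] = table["mean_pct_inc_mse"].rank(ascending=False, method="first").astype(int)
        table = table.sort_values("rank").reset_index(drop=True)
        importance_report = ImportanceReport(table=table)

    return CVReport(
        per_round=per_round_df,
        aggregate=aggregate,
        n_rounds=n_rounds,
        n_empty_rounds=n_empty,
        importance=importance_report,
    )
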