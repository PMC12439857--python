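"""Case-grouped nested cross-validation against two end-tidal CO2 baselines.

The estimator of interest is a gradient-boosted decision-tree regressor
(LightGBM backend behind a small fit/predict contract, handling categorical
features natively).  Hyperparameters are chosen per outer fold by seeded
random search minimizing mean MAE over the inner validation folds.  Two
baselines anchor the comparison: a fixed offset (ETCO2 + 5 mmHg) and
ordinary least squares of PaCO2 on ETCO2 alone, refit inside each outer
training fold.  Partitioning is at the surgical-case level throughout, so
no case ever contributes events to both sides of a split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import lightgbm as lgb

from paco2est.config import SearchSpec
from paco2est.features import (
    CATEGORICAL_FEATURES,
    ScalerState,
    continuous_features,
    robust_scale_apply,
    robust_scale_fit,
)

MODEL_OFFSET = "offset"
MODEL_LINEAR = "linear"
MODEL_GBM = "gbm"
OFFSET_MMHG = 5.0


@dataclass
class FoldAssignment:
    """Case-level fold layout: outer folds 1..k_outer, inner folds 1..k_inner
    within each outer training set."""

    outer: dict[str, int]
    inner: dict[int, dict[str, int]]
    k_outer: int
    k_inner: int
    seed: int

    def outer_test_cases(self, fold: int) -> set[str]:
        return {c for c, f in self.outer.items() if f == fold}

    def outer_train_cases(self, fold: int) -> set[str]:
        return {c for c, f in self.outer.items() if f != fold}


def make_folds(case_ids: Sequence[str], k_outer: int = 7, k_inner: int = 6,
               seed: int = 0) -> FoldAssignment:
    """Randomly partition cases into outer folds, and each outer training
    set into inner folds; balanced within one case, deterministic in seed."""
    case_ids = sorted(set(case_ids))
    if len(case_ids) < k_outer:
        raise ValueError(f"need >= {k_outer} cases, got {len(case_ids)}")
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(case_ids))
    outer = {c: (i % k_outer) + 1 for i, c in enumerate(shuffled)}
    inner: dict[int, dict[str, int]] = {}
    for f in range(1, k_outer + 1):
        train = sorted(c for c in case_ids if outer[c] != f)
        sh = list(rng.permutation(train))
        inner[f] = {c: (i % k_inner) + 1 for i, c in enumerate(sh)}
    return FoldAssignment(outer=outer, inner=inner, k_outer=k_outer,
                          k_inner=k_inner, seed=seed)


def baseline_offset(etco2) -> np.ndarray:
    """Fixed-gradient estimate: ETCO2 + 5 mmHg, no fitting."""
    return np.asarray(etco2, dtype=float) + OFFSET_MMHG


def baseline_linear_fit(etco2, paco2) -> tuple[float, float]:
    """OLS of PaCO2 on ETCO2 (training fold only): returns (slope, intercept)."""
    x = np.asarray(etco2, dtype=float)
    y = np.asarray(paco2, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: need >= 2 distinct ETCO2 values")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def baseline_linear_predict(params: tuple[float, float], etco2) -> np.ndarray:
    slope, intercept = params
    return slope * np.asarray(etco2, dtype=float) + intercept


class GBMBackend:
    """Gradient-boosted decision trees (LightGBM) behind a fit/predict
    contract with native categorical handling and additive attributions."""

    def __init__(self, params: dict, seed: int = 0):
        self.params = dict(params)
        self.seed = seed
        self._model: Optional[lgb.LGBMRegressor] = None
        self._columns: Optional[list[str]] = None

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "GBMBackend":
        depth = int(self.params["depth"])
        self._model = lgb.LGBMRegressor(
            n_estimators=int(self.params["iterations"]),
            learning_rate=float(self.params["learning_rate"]),
            max_depth=depth,
            num_leaves=min(2 ** depth - 1, 64),
            reg_lambda=float(self.params["l2_leaf_reg"]),
            min_child_samples=10,
            random_state=self.seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
        )
        self._columns = list(X.columns)
        self._model.fit(X, y, categorical_feature=[
            c for c in X.columns if isinstance(X[c].dtype, pd.CategoricalDtype)])
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self._model.predict(X[self._columns])

    def attributions(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Per-row additive attributions and base values.

        Row prediction = base + sum(attributions); exact by construction
        for tree ensembles.
        """
        contrib = self._model.predict(X[self._columns], pred_contrib=True)
        return contrib[:, :-1], contrib[:, -1]

    @property
    def feature_names(self) -> list[str]:
        return list(self._columns)


def _sample_trial(rng: np.random.Generator, spec: SearchSpec) -> dict:
    return {
        "depth": int(rng.integers(spec.depth[0], spec.depth[1] + 1)),
        "learning_rate": float(np.exp(rng.uniform(
            math.log(spec.learning_rate[0]), math.log(spec.learning_rate[1])))),
        "iterations": int(rng.integers(spec.iterations[0],
                                       spec.iterations[1] + 1)),
        "l2_leaf_reg": float(rng.uniform(*spec.l2_leaf_reg)),
    }


def _prepare_design(frame: pd.DataFrame, include_co: bool) -> pd.DataFrame:
    """Select predictors; categoricals become pandas category dtype."""
    cont = [c for c in continuous_features(include_co) if c in frame.columns]
    cats = [c for c in CATEGORICAL_FEATURES if c in frame.columns]
    X = frame[cont + cats].copy()
    for c in cats:
        X[c] = X[c].astype("category")
    return X


def tune_and_train(train: pd.DataFrame, inner_assignment: dict[str, int],
                   spec: SearchSpec, include_co: bool = True,
                   seed: int = 0) -> tuple[GBMBackend, ScalerState, dict, list[dict]]:
    """Random-search hyperparameters on the inner folds, then refit.

    Each trial configuration is scored by its mean MAE across the inner
    validation folds (scaler refit on every inner training subset); the
    minimizing configuration is retrained on the full outer training set.
    Returns (backend, scaler fitted on the outer training set, chosen
    params, trial log).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    cont = [c for c in continuous_features(include_co) if c in train.columns]
    y_col = "paco2"
    inner_ids = sorted(set(inner_assignment.values()))

    trials = [_sample_trial(rng, spec) for _ in range(spec.n_trials)]
    log: list[dict] = []
    for t_idx, params in enumerate(trials):
        fold_maes = []
        for j in inner_ids:
            tr = train[train["case_id"].map(inner_assignment) != j]
            va = train[train["case_id"].map(inner_assignment) == j]
            if va.empty or tr.empty:
                continue
            scaler = robust_scale_fit(tr, cont)
            Xtr = _prepare_design(robust_scale_apply(scaler, tr), include_co)
            Xva = _prepare_design(robust_scale_apply(scaler, va), include_co)
            backend = GBMBackend(params, seed=seed).fit(
                Xtr, tr[y_col].to_numpy(dtype=float))
            pred = backend.predict(Xva)
            fold_maes.append(float(np.mean(np.abs(
                va[y_col].to_numpy(dtype=float) - pred))))
        mean_mae = float(np.mean(fold_maes)) if fold_maes else float("inf")
        log.append({"trial": t_idx, "params": params, "inner_mae": mean_mae})

    best = min(log, key=lambda r: r["inner_mae"])
    scaler = robust_scale_fit(train, cont)
    Xfull = _prepare_design(robust_scale_apply(scaler, train), include_co)
    backend = GBMBackend(best["params"], seed=seed).fit(
        Xfull, train[y_col].to_numpy(dtype=float))
    return backend, scaler, best["params"], log


@dataclass
class FoldModel:
    backend: GBMBackend
    scaler: ScalerState
    params: dict
    linear: tuple[float, float]


@dataclass
class NestedCVResult:
    """Out-of-fold predictions for all three models plus per-fold artifacts."""

    predictions: pd.DataFrame
    fold_models: dict[int, FoldModel]
    tuning_log: dict[int, list[dict]]
    folds: FoldAssignment
    include_co: bool = True
    features: Optional[pd.DataFrame] = field(default=None, repr=False)


def run_nested_cv(features: pd.DataFrame, folds: FoldAssignment,
                  spec: SearchSpec, include_co: bool = True) -> NestedCVResult:
    """Train and predict out-of-fold for the offset, linear and GBM models.

    Every modeled event is predicted exactly once per model, always by a
    model whose training data excluded the event's case.
    """
    missing = set(features["case_id"]) - set(folds.outer)
    if missing:
        raise KeyError(f"cases missing a fold assignment: {sorted(missing)[:5]}")
    pred_rows = []
    fold_models: dict[int, FoldModel] = {}
    tuning: dict[int, list[dict]] = {}
    for f in range(1, folds.k_outer + 1):
        test_cases = folds.outer_test_cases(f)
        train = features[~features["case_id"].isin(test_cases)]
        test = features[features["case_id"].isin(test_cases)]
        if test.empty:
            raise ValueError(f"outer fold {f} has no test events")
        lin = baseline_linear_fit(train["etco2"], train["paco2"])
        backend, scaler, params, log = tune_and_train(
            train, folds.inner[f], spec, include_co=include_co,
            seed=folds.seed * 1000 + f)
        Xte = _prepare_design(robust_scale_apply(scaler, test), include_co)
        preds = {
            MODEL_OFFSET: baseline_offset(test["etco2"]),
            MODEL_LINEAR: baseline_linear_predict(lin, test["etco2"]),
            MODEL_GBM: backend.predict(Xte),
        }
        for model, yhat in preds.items():
            pred_rows.append(pd.DataFrame({
                "event_id": test["event_id"].to_numpy(),
                "case_id": test["case_id"].to_numpy(),
                "actual": test["paco2"].to_numpy(dtype=float),
                "predicted": np.asarray(yhat, dtype=float),
                "model": model,
                "fold": f,
            }))
        fold_models[f] = FoldModel(backend=backend, scaler=scaler,
                                   params=params, linear=lin)
        tuning[f] = log
    predictions = pd.concat(pred_rows, ignore_index=True)
    return NestedCVResult(predictions=predictions, fold_models=fold_models,
                          tuning_log=tuning, folds=folds,
                          include_co=include_co, features=features)
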