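"""Clinical agreement evaluation of the out-of-fold predictions.

Everything an anesthesia method-comparison reads: fold-averaged MAE/MSE/RMSE
with Student-t 95% CIs, breakdowns by capnia subgroup (hypocapnic <35,
normocapnic 35-45, hypercapnic >45 mmHg of actual PaCO2), Bland-Altman bias
and limits of agreement, the intraclass correlation coefficient ICC(2,1)
(two-way random effects, absolute agreement, single measurement) with
F-based CI and p-value, clinical-utility error bins at 5 and 10 mmHg, and
additive per-feature attributions of the tree model with their additivity
identity checked.

Sign convention everywhere: difference = predicted - actual, so a model
that overpredicts has positive bias.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from paco2est.config import EvalConfig
from paco2est.model import (
    MODEL_GBM,
    MODEL_LINEAR,
    MODEL_OFFSET,
    NestedCVResult,
    _prepare_design,
)
from paco2est.features import robust_scale_apply

MODELS = (MODEL_OFFSET, MODEL_LINEAR, MODEL_GBM)
SUBGROUPS = ("all", "hypocapnic", "normocapnic", "hypercapnic")


def error_metrics(actual, predicted) -> tuple[float, float, float]:
    """(MAE, MSE, RMSE) of predicted vs actual."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.size == 0:
        raise ValueError("error_metrics requires at least one row")
    err = a - p
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err ** 2))
    return mae, mse, float(np.sqrt(mse))


def fold_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Student-t confidence interval for the mean across outer folds.

    Returns (mean, ci_low, ci_high); with a single fold the CI is undefined
    (NaN) and a warning is issued.
    """
    x = np.asarray(values, dtype=float)
    mean = float(np.mean(x))
    k = x.size
    if k < 2:
        warnings.warn("fewer than 2 fold values: CI undefined")
        return mean, float("nan"), float("nan")
    half = float(stats.t.ppf(0.5 + level / 2.0, k - 1)
                 * np.std(x, ddof=1) / np.sqrt(k))
    return mean, mean - half, mean + half


def assign_subgroup(paco2: float) -> str:
    """Capnia subgroup by actual PaCO2: <35 / 35-45 inclusive / >45 mmHg."""
    if paco2 < 35.0:
        return "hypocapnic"
    if paco2 <= 45.0:
        return "normocapnic"
    return "hypercapnic"


def bland_altman(actual, predicted) -> dict:
    """Bias and limits of agreement, plus the per-point plot table.

    difference = predicted - actual; limits = bias +/- 1.96 sample SD of
    the differences.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.size < 2:
        raise ValueError("bland_altman requires >= 2 rows")
    diff = p - a
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd_diff": sd,
        "points": pd.DataFrame({"mean": (a + p) / 2.0, "difference": diff}),
    }


def icc_absolute_agreement(actual, predicted, ci_level: float = 0.95
                           ) -> tuple[float, float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA mean squares of the n x 2 table whose
    columns are the two measurement methods; the CI and p-value follow the
    standard F-based construction.  Returns (icc, ci_low, ci_high, p).
    Degenerate tables (zero total variance) return NaN ICC.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    n = a.size
    if n < 5:
        raise ValueError("icc requires >= 5 pairs")
    X = np.column_stack([a, p])
    k = 2
    grand = X.mean()
    if np.allclose(X, grand):
        warnings.warn("zero total variance: ICC undefined")
        return float("nan"), float("nan"), float("nan"), float("nan")
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((X - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    if mse <= 0:
        return float(icc), float(icc), float(icc), 0.0
    # p-value from the between-subjects F test
    fval = msr / mse
    pval = float(stats.f.sf(fval, n - 1, (n - 1) * (k - 1)))
    # F-based CI (Satterthwaite df for the column effect)
    alpha = 1.0 - ci_level
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc)
                              - k * icc) ** 2
    vd = ((n - 1) * k ** 2 * icc ** 2 * fj ** 2
          + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
    v = vn / vd
    f_upper = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_upper * mse) / (
        f_upper * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_lower * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr)
    return float(icc), float(lo), float(hi), pval


def utility_bins(actual, predicted) -> dict:
    """Percentage of events by |error| band: <5, 5-10, >10 mmHg."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.size == 0:
        raise ValueError("utility_bins requires at least one row")
    e = np.abs(p - a)
    n = e.size
    lt5 = float(np.sum(e < 5.0)) / n * 100.0
    gt10 = float(np.sum(e > 10.0)) / n * 100.0
    mid = 100.0 - lt5 - gt10
    return {"pct_lt5": lt5, "pct_5to10": mid, "pct_gt10": gt10}


def attribution_summary(result: NestedCVResult,
                        features: Optional[pd.DataFrame] = None) -> dict:
    """Out-of-fold additive attributions of the tree model.

    Each outer fold's model scores its own held-out rows, so attributions
    are leakage-free.  Features are ranked by mean |attribution|; a signed
    dependence (Spearman correlation of attribution with feature value) is
    reported for continuous features.  The additivity identity
    base + sum(attributions) = prediction is checked row by row and its
    maximum violation reported.
    """
    feats = features if features is not None else result.features
    if feats is None:
        raise ValueError("feature table required for attribution")
    contribs, values, preds = [], [], []
    feat_names: list[str] = []
    for f, fm in result.fold_models.items():
        test_cases = result.folds.outer_test_cases(f)
        rows = feats[feats["case_id"].isin(test_cases)]
        if rows.empty:
            continue
        X = _prepare_design(robust_scale_apply(fm.scaler, rows),
                            result.include_co)
        feat_names = fm.backend.feature_names
        attr, base = fm.backend.attributions(X)
        yhat = fm.backend.predict(X)
        contribs.append(attr)
        preds.append(yhat - base)   # residual after base: must equal row sums
        values.append(X)
    attr = np.vstack(contribs)
    add_err = float(np.max(np.abs(np.concatenate(preds) - attr.sum(axis=1))))
    Xall = pd.concat(values, ignore_index=True)

    mean_abs = np.mean(np.abs(attr), axis=0)
    order = np.argsort(-mean_abs)
    ranking = []
    for rank, j in enumerate(order, start=1):
        name = feat_names[j]
        col = Xall[name]
        if not pd.api.types.is_numeric_dtype(col):
            corr = float("nan")
        else:
            x = col.to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(attr[:, j]) == 0:
                corr = float("nan")
            else:
                corr = float(stats.spearmanr(x, attr[:, j]).statistic)
        ranking.append({"feature": name, "rank": rank,
                        "mean_abs_attribution": float(mean_abs[j]),
                        "value_dependence": corr})
    return {"features": ranking, "additivity_max_error": add_err}


def _metric_block(pred: pd.DataFrame, subgroup: str,
                  ci_level: float) -> Optional[dict]:
    """Per-fold metrics within a subgroup, then t-CI across folds."""
    if subgroup != "all":
        pred = pred[pred["subgroup"] == subgroup]
    if pred.empty:
        return None
    per_fold = {"mae": [], "mse": [], "rmse": []}
    for _, grp in pred.groupby("fold", sort=True):
        mae, mse, rmse = error_metrics(grp["actual"], grp["predicted"])
        per_fold["mae"].append(mae)
        per_fold["mse"].append(mse)
        per_fold["rmse"].append(rmse)
    block: dict = {"n_events": int(len(pred)),
                   "n_folds": int(pred["fold"].nunique())}
    for m, vals in per_fold.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean, lo, hi = fold_ci(vals, ci_level)
        block[m] = {"mean": mean, "ci_low": lo, "ci_high": hi}
    return block


def build_report(result, config: Optional[EvalConfig] = None,
                 provenance: Optional[dict] = None,
                 attribution: Optional[dict] = None) -> dict:
    """Full evaluation report over all three models.

    Metric blocks per model and capnia subgroup (fold-wise CIs), agreement
    (Bland-Altman + ICC), utility bins, attribution summary, provenance.
    ``result`` is a :class:`NestedCVResult`, or a bare prediction table if a
    precomputed ``attribution`` summary is supplied (staged execution).
    """
    config = config or EvalConfig()
    config.validate()
    if isinstance(result, pd.DataFrame):
        if attribution is None:
            raise ValueError("a bare prediction table needs a precomputed "
                             "attribution summary (run the train stage first)")
        pred = result.copy()
        cv = None
    else:
        cv = result
        pred = cv.predictions.copy()
    present = set(pred["model"].unique())
    missing = set(MODELS) - present
    if missing:
        raise ValueError(f"prediction set lacks models: {sorted(missing)}")
    pred["subgroup"] = pred["actual"].map(assign_subgroup)

    report: dict = {"models": {}, "conventions": {
        "difference": "predicted - actual",
        "icc_form": config.icc_form,
        "ci_level": config.ci_level,
    }}
    for model in MODELS:
        pm = pred[pred["model"] == model]
        blocks = {}
        for sg in SUBGROUPS:
            b = _metric_block(pm, sg, config.ci_level)
            if b is None:
                warnings.warn(f"{model}: subgroup {sg} empty, skipped")
                continue
            blocks[sg] = b
        ba = bland_altman(pm["actual"], pm["predicted"])
        icc, lo, hi, p = icc_absolute_agreement(pm["actual"], pm["predicted"],
                                                config.ci_level)
        report["models"][model] = {
            "metrics": blocks,
            "agreement": {"bias": ba["bias"], "loa_low": ba["loa_low"],
                          "loa_high": ba["loa_high"], "sd_diff": ba["sd_diff"],
                          "icc": icc, "icc_ci_low": lo, "icc_ci_high": hi,
                          "icc_p": p},
            "utility": utility_bins(pm["actual"], pm["predicted"]),
        }
    report["attribution"] = (attribution if attribution is not None
                             else attribution_summary(cv))
    prov = dict(provenance or {})
    prov.setdefault("n_events", int(pred["event_id"].nunique()))
    prov.setdefault("n_cases", int(pred["case_id"].nunique()))
    if cv is not None:
        prov.setdefault("k_outer", cv.folds.k_outer)
        prov.setdefault("k_inner", cv.folds.k_inner)
        prov.setdefault("fold_seed", cv.folds.seed)
    report["provenance"] = prov
    return report


def report_json(report: dict) -> str:
    """Canonical serialization: identical inputs give identical bytes."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=True)


def config_hash(config_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def bland_altman_tables(result: NestedCVResult) -> dict[str, pd.DataFrame]:
    """Plot-ready Bland-Altman point tables, one per model."""
    out = {}
    for model in MODELS:
        pm = result.predictions[result.predictions["model"] == model]
        out[model] = bland_altman(pm["actual"], pm["predicted"])["points"]
    return out
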