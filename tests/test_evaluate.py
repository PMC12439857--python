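"""Agreement statistics: metrics, CIs, Bland-Altman, ICC, utility bins."""

import numpy as np
import pandas as pd
import pytest

from paco2est.evaluate import (
    assign_subgroup,
    bland_altman,
    build_report,
    error_metrics,
    fold_ci,
    icc_absolute_agreement,
    utility_bins,
)


class TestErrorMetrics:
    def test_unit_errors(self):
        a = np.array([1.0, -1, 1, -1])
        mae, mse, rmse = error_metrics(a, np.zeros(4))
        assert (mae, mse, rmse) == (1.0, 1.0, 1.0)

    def test_perfect_prediction(self):
        x = np.arange(5.0)
        assert error_metrics(x, x) == (0.0, 0.0, 0.0)

    def test_matches_direct_summation(self, rng):
        for _ in range(100):
            a = rng.normal(42, 5, size=50)
            p = a + rng.normal(0, 2, size=50)
            mae, mse, rmse = error_metrics(a, p)
            assert mae == pytest.approx(sum(abs(a - p)) / 50, abs=1e-12)
            assert mse == pytest.approx(sum((a - p) ** 2) / 50, abs=1e-12)
            assert rmse == pytest.approx(mse ** 0.5, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            error_metrics([], [])


class TestFoldCI:
    def test_zero_variance_collapses(self):
        mean, lo, hi = fold_ci([3.0] * 7)
        assert (mean, lo, hi) == (3.0, 3.0, 3.0)

    def test_closed_form_t_interval(self):
        """Folds 1..7: mean 4, half-width t6(.975)*sd/sqrt(7) -> [2.00, 6.00]."""
        mean, lo, hi = fold_ci([1, 2, 3, 4, 5, 6, 7])
        assert mean == 4.0
        assert lo == pytest.approx(2.00, abs=0.005)
        assert hi == pytest.approx(6.00, abs=0.005)

    def test_widens_with_spread(self):
        _, lo1, hi1 = fold_ci([3.9, 4.0, 4.1, 4.0])
        _, lo2, hi2 = fold_ci([3.0, 4.0, 5.0, 4.0])
        assert hi2 - lo2 > hi1 - lo1

    def test_single_fold_flagged(self):
        with pytest.warns(UserWarning):
            mean, lo, hi = fold_ci([2.5])
        assert mean == 2.5 and np.isnan(lo) and np.isnan(hi)


class TestSubgroups:
    @pytest.mark.parametrize("paco2,expect", [
        (34.0, "hypocapnic"), (34.999, "hypocapnic"),
        (35.0, "normocapnic"), (45.0, "normocapnic"),
        (45.5, "hypercapnic"), (60.0, "hypercapnic")])
    def test_boundaries(self, paco2, expect):
        assert assign_subgroup(paco2) == expect


class TestBlandAltman:
    def test_constant_difference(self):
        a = np.array([40.0, 42, 44])
        out = bland_altman(a, a + 2.0)
        assert out["bias"] == 2.0
        assert out["loa_low"] == out["loa_high"] == 2.0

    def test_hand_computed_loa(self):
        """diffs {-1, +1}: bias 0, sd sqrt(2), LoA +/- 2.7719."""
        out = bland_altman([40.0, 40.0], [39.0, 41.0])
        assert out["bias"] == 0.0
        assert out["loa_high"] == pytest.approx(1.96 * np.sqrt(2), abs=1e-12)
        assert out["loa_low"] == pytest.approx(-1.96 * np.sqrt(2), abs=1e-12)

    def test_overprediction_is_positive_bias(self):
        out = bland_altman([40.0, 41.0, 42.0], [45.0, 46.0, 47.0])
        assert out["bias"] > 0

    def test_loa_cover_95pct_of_gaussian_differences(self, rng):
        a = rng.normal(42, 4, size=4000)
        p = a + rng.normal(1, 2, size=4000)
        out = bland_altman(a, p)
        d = p - a
        cover = np.mean((d >= out["loa_low"]) & (d <= out["loa_high"]))
        assert cover == pytest.approx(0.95, abs=0.015)


class TestICC:
    def test_perfect_agreement(self):
        x = np.arange(10.0) + 30
        icc, lo, hi, p = icc_absolute_agreement(x, x)
        assert icc == pytest.approx(1.0)

    def test_offset_penalized_below_correlation(self):
        x = np.arange(20.0) + 30
        icc, *_ = icc_absolute_agreement(x, x + 8.0)
        assert icc < 0.7   # Pearson correlation would be exactly 1

    def test_order_invariance(self, rng):
        a = rng.normal(42, 4, size=40)
        b = a + rng.normal(0, 2, size=40)
        assert icc_absolute_agreement(a, b)[0] == \
            pytest.approx(icc_absolute_agreement(b, a)[0], abs=1e-12)

    def test_matches_anova_oracle(self, rng):
        """Brute-force two-way ANOVA mean squares reproduce the ICC."""
        for _ in range(100):
            n = int(rng.integers(6, 40))
            a = rng.normal(40, 5, size=n)
            b = a + rng.normal(1, 3, size=n)
            icc, *_ = icc_absolute_agreement(a, b)
            X = np.column_stack([a, b])
            mu = X.mean()
            msr = 2 * np.sum((X.mean(1) - mu) ** 2) / (n - 1)
            msc = n * np.sum((X.mean(0) - mu) ** 2) / 1
            mse = (np.sum((X - mu) ** 2)
                   - 2 * np.sum((X.mean(1) - mu) ** 2)
                   - n * np.sum((X.mean(0) - mu) ** 2)) / (n - 1)
            expect = (msr - mse) / (msr + mse + 2 * (msc - mse) / n)
            assert icc == pytest.approx(expect, abs=1e-10)

    def test_matches_pingouin(self, rng):
        """Independent library oracle for value, CI and p."""
        pingouin = pytest.importorskip("pingouin")
        for seed in range(5):
            r = np.random.default_rng(seed)
            a = r.normal(42, 4, size=30)
            b = a + r.normal(1, 2.5, size=30)
            icc, lo, hi, p = icc_absolute_agreement(a, b)
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(30), 2),
                "raters": np.tile(["x", "y"], 30),
                "score": np.column_stack([a, b]).ravel()})
            ref = pingouin.intraclass_corr(df, "targets", "raters", "score")
            mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
            row = ref[mask].iloc[0]
            assert icc == pytest.approx(row["ICC"], abs=1e-8)
            ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
            assert (lo, hi) == pytest.approx(tuple(row[ci_col]), abs=6e-3)
            assert p == pytest.approx(row["pval"], abs=1e-8)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement([1, 2], [1, 2])

    def test_degenerate_flagged(self):
        with pytest.warns(UserWarning):
            icc, *_ = icc_absolute_agreement([5.0] * 6, [5.0] * 6)
        assert np.isnan(icc)


class TestUtilityBins:
    def test_boundaries(self):
        a = np.zeros(3)
        out = utility_bins(a, np.array([4.9, 10.0, 10.1]))
        assert out["pct_lt5"] == pytest.approx(100 / 3)
        assert out["pct_5to10"] == pytest.approx(100 / 3)
        assert out["pct_gt10"] == pytest.approx(100 / 3)

    def test_partition_sums_to_100(self, rng):
        a = rng.normal(42, 4, 500)
        p = a + rng.normal(0, 6, 500)
        out = utility_bins(a, p)
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-9)


def _synthetic_predictions(rng, n_cases=21, per_case=4):
    rows = []
    eid = 0
    for i in range(n_cases):
        cid, fold = f"S{i}", i % 7 + 1
        for _ in range(per_case):
            actual = rng.normal(42, 5)
            for model, sd in (("offset", 3.0), ("linear", 2.0), ("gbm", 1.0)):
                rows.append({"event_id": eid, "case_id": cid, "actual": actual,
                             "predicted": actual + rng.normal(0, sd),
                             "model": model, "fold": fold})
            eid += 1
    return pd.DataFrame(rows)


class TestBuildReport:
    def test_report_structure_and_accounting(self, rng):
        pred = _synthetic_predictions(rng)
        report = build_report(pred, attribution={"features": [],
                                                 "additivity_max_error": 0.0})
        assert set(report["models"]) == {"offset", "linear", "gbm"}
        n_blocks = sum(len(m["metrics"]) for m in report["models"].values())
        assert n_blocks == 12   # 3 models x 4 subgroups
        for m in report["models"].values():
            counts = [b["n_events"] for sg, b in m["metrics"].items()
                      if sg != "all"]
            assert sum(counts) == m["metrics"]["all"]["n_events"]
            assert sum(m["utility"].values()) == pytest.approx(100.0)

    def test_pooled_error_identity(self, rng):
        """Within each fold, subgroup absolute-error sums add to the total."""
        pred = _synthetic_predictions(rng)
        pred["subgroup"] = pred["actual"].map(assign_subgroup)
        for (model, fold), grp in pred.groupby(["model", "fold"]):
            total = np.sum(np.abs(grp["actual"] - grp["predicted"]))
            parts = sum(
                np.sum(np.abs(g["actual"] - g["predicted"]))
                for _, g in grp.groupby("subgroup"))
            assert parts == pytest.approx(total, abs=1e-9)

    def test_missing_model_rejected(self, rng):
        pred = _synthetic_predictions(rng)
        with pytest.raises(ValueError):
            build_report(pred[pred["model"] != "gbm"],
                         attribution={"features": []})

    def test_bare_frame_requires_attribution(self, rng):
        with pytest.raises(ValueError):
            build_report(_synthetic_predictions(rng))
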