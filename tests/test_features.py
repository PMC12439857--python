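"""Feature extraction: filtering, medians, engineered indices, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paco2est.align import STATUS_ALIGNED, STATUS_MISSING, EventPoint
from paco2est.config import FeatureConfig
from paco2est.features import (
    assemble_feature_table,
    classify_pft,
    continuous_features,
    engineered_ratios,
    filter_outliers_iqr,
    filter_plausibility,
    ideal_body_weight,
    respiratory_compliance,
    robust_scale_apply,
    robust_scale_fit,
    robust_scale_invert,
    slice_window,
    window_median,
)
from paco2est.synth import generate_cohort
from paco2est.types import BiosignalTrace, CaseRecord, Cohort

from conftest import tiny_generator


class TestSliceWindow:
    T = np.arange(0.0, 2000.0, 1.0)

    def test_sixty_samples_at_1hz(self):
        out = slice_window(self.T, self.T, 880.0, 940.0)
        assert out.size == 60

    def test_half_open_boundaries(self):
        out = slice_window(self.T, self.T, 880.0, 940.0)
        assert 880.0 in out and 940.0 not in out

    def test_window_beyond_trace_empty(self):
        assert slice_window(self.T, self.T, 5000.0, 5060.0).size == 0


class TestIqrFilter:
    def test_identical_values_survive(self):
        x = np.full(20, 7.0)
        np.testing.assert_array_equal(filter_outliers_iqr(x), x)

    def test_worked_example(self):
        """Q1=2, Q3=4, IQR=2, fence [-4, 10]: 100 removed."""
        out = filter_outliers_iqr(np.array([1.0, 2, 3, 4, 100]), k=3.0)
        np.testing.assert_array_equal(out, [1, 2, 3, 4])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_cauchy(size=int(rng.integers(2, 60)))
        q1, q3 = np.percentile(x, [25, 75])
        lo, hi = q1 - 3 * (q3 - q1), q3 + 3 * (q3 - q1)
        expect = np.array([v for v in x if lo <= v <= hi])
        np.testing.assert_allclose(filter_outliers_iqr(x, 3.0), expect)


class TestPlausibility:
    def test_out_of_range_removed(self):
        out = filter_plausibility(np.array([98.0, 250.0, 55.0]), (50.0, 100.0))
        np.testing.assert_array_equal(out, [98.0, 55.0])

    def test_in_range_identity(self):
        x = np.array([96.0, 97.5, 99.0])
        np.testing.assert_array_equal(filter_plausibility(x, (50, 100)), x)

    def test_combined_order_matches_brute_force(self, rng):
        """Plausibility first, then IQR, equals direct predicate chaining."""
        for _ in range(200):
            x = rng.normal(75, 30, size=40)
            b = (40.0, 110.0)
            step1 = np.array([v for v in x if b[0] <= v <= b[1]])
            q1, q3 = np.percentile(step1, [25, 75])
            lo, hi = q1 - 3 * (q3 - q1), q3 + 3 * (q3 - q1)
            expect = np.array([v for v in step1 if lo <= v <= hi])
            got = filter_outliers_iqr(filter_plausibility(x, b), 3.0)
            np.testing.assert_allclose(got, expect)


class TestMediansAndIndices:
    def test_window_median(self):
        assert window_median(np.array([3.0, 1, 2])) == 2.0
        assert window_median(np.array([1.0, 2, 3, 4])) == 2.5
        assert np.isnan(window_median(np.array([])))

    def test_ideal_body_weight_devine(self):
        assert ideal_body_weight(177.8, "male") == pytest.approx(73.0)
        assert ideal_body_weight(152.4, "female") == pytest.approx(45.5)
        assert 500.0 / ideal_body_weight(177.8, "male") == pytest.approx(6.85, abs=0.01)
        with pytest.raises(ValueError):
            ideal_body_weight(0.0, "male")

    def test_compliance(self):
        assert respiratory_compliance(525.0, 20.0, 5.0) == 35.0
        assert np.isnan(respiratory_compliance(500.0, 5.0, 5.0))
        assert respiratory_compliance(1050.0, 20.0, 5.0) == 70.0

    def test_ratios(self):
        sf, pf, rsbi = engineered_ratios(98.0, 0.5, 5.0, 14.0, 350.0)
        assert sf == 196.0
        assert rsbi == 40.0
        assert engineered_ratios(98.0, 0.4, 5.0, 14.0, 350.0)[1] == 12.5

    @pytest.mark.parametrize("ratio,fvc,grade", [
        (0.60, 90.0, "obstructive"),
        (0.80, 70.0, "restrictive"),
        (0.60, 70.0, "mixed"),
        (0.80, 90.0, "none"),
        (None, None, "none"),
        (float("nan"), 90.0, "none"),
    ])
    def test_pft_grades(self, ratio, fvc, grade):
        assert classify_pft(ratio, fvc) == grade


def _mini_cohort():
    """Three cases with constant channels for hand-checkable features."""
    cases = [
        CaseRecord("A", 50, "male", 177.8, 80.0, 2, "general", "open", 0.8, 95.0),
        CaseRecord("B", 65, "female", 152.4, 60.0, 3, "thoracic", "open", 0.6, 70.0),
        CaseRecord("C", 40, "male", 170.0, 70.0, 1, "urologic", "robotic"),
    ]
    t = np.arange(0.0, 1200.0, 2.0)
    level = {
        "A": {"BT": 36.5, "HR": 70, "SPO2": 98, "MV": 7.0, "PEEP": 5, "PIP": 22,
              "PPLAT": 20, "MAWP": 11, "RR": 14, "TV": 525, "FIO2": 0.5,
              "ETCO2": 35, "CO": 5},
        "B": {"BT": 36.0, "HR": 80, "SPO2": 97, "MV": 6.0, "PEEP": 4, "PIP": 20,
              "PPLAT": 18, "MAWP": 10, "RR": 12, "TV": 400, "FIO2": 0.4,
              "ETCO2": 33, "CO": 4},
        "C": {"BT": 37.0, "HR": 60, "SPO2": 99, "MV": 8.0, "PEEP": 6, "PIP": 24,
              "PPLAT": 6, "MAWP": 12, "RR": 16, "TV": 500, "FIO2": 0.6,
              "ETCO2": 38, "CO": 6},   # PPLAT == PEEP: invalid compliance
    }
    traces = [BiosignalTrace(cid, ch, t, np.full(t.size, float(v)))
              for cid, chans in level.items() for ch, v in chans.items()]
    return Cohort(cases=cases, traces=traces, abga=[])


def _aligned_event(case_id, target=42.0):
    return EventPoint(case_id=case_id, recorded_time_s=1000.0,
                      status=STATUS_ALIGNED, estimated_draw_time_s=960.0,
                      trigger_time_s=900.0, window_start_s=840.0,
                      window_end_s=900.0, target_paco2=target)


class TestAssembleFeatureTable:
    def test_hand_computed_row(self):
        cohort = _mini_cohort()
        events = [_aligned_event("A")]
        feats, excl = assemble_feature_table(events, cohort, FeatureConfig())
        assert len(feats) == 1 and excl.empty
        row = feats.iloc[0]
        assert row["crs"] == pytest.approx(525.0 / 15.0)
        assert row["tv_ibw"] == pytest.approx(525.0 / 73.0)
        assert row["sf_ratio"] == pytest.approx(98.0 / 0.5)
        assert row["peep_fio2"] == pytest.approx(10.0)
        assert row["rsbi"] == pytest.approx(14.0 / 0.525)
        assert row["pft_grade"] == "none"   # 0.8 ratio, 95% FVC
        assert row["paco2"] == 42.0

    def test_invalid_compliance_dropped(self):
        cohort = _mini_cohort()
        events = [_aligned_event("C")]
        feats, excl = assemble_feature_table(events, cohort, FeatureConfig())
        assert feats.empty
        assert excl.iloc[0]["reason"].startswith("missing:")
        assert "CRS" in excl.iloc[0]["reason"]
        assert events[0].status == STATUS_MISSING

    def test_unknown_case_raises(self):
        with pytest.raises(KeyError):
            assemble_feature_table([_aligned_event("ZZ")], _mini_cohort(),
                                   FeatureConfig())

    def test_missing_grade_classification(self):
        cohort = _mini_cohort()
        feats, _ = assemble_feature_table(
            [_aligned_event("A"), _aligned_event("B")], cohort, FeatureConfig())
        assert list(feats["pft_grade"]) == ["none", "mixed"]

    def test_event_conservation_with_missing_channels(self):
        """aligned = modeled + excluded_missing_features."""
        from paco2est.align import align_events
        from paco2est.config import AlignmentConfig
        cohort = generate_cohort(tiny_generator(
            n_cases=20, missing_channel_fraction=0.4))
        events = align_events(cohort, AlignmentConfig())
        feats, excl = assemble_feature_table(events, cohort, FeatureConfig())
        n_aligned = sum(1 for e in events
                        if e.status in (STATUS_ALIGNED, STATUS_MISSING))
        n_missing = (excl["reason"].str.startswith("missing")).sum()
        assert n_aligned == len(feats) + n_missing
        assert n_missing > 0

    def test_engineered_features_recomputable(self, small_cohort, aligned_small):
        feats, _ = assemble_feature_table(aligned_small, small_cohort,
                                          FeatureConfig())
        cases = {c.case_id: c for c in small_cohort.cases}
        for _, r in feats.iterrows():
            ibw = ideal_body_weight(cases[r["case_id"]].height,
                                    cases[r["case_id"]].sex)
            assert r["tv_ibw"] == r["tv"] / ibw
            assert r["crs"] == r["tv"] / (r["pplat"] - r["peep"])
            assert r["sf_ratio"] == r["spo2"] / r["fio2"]
            assert r["rsbi"] == r["rr"] / (r["tv"] / 1000.0)


class TestRobustScaler:
    FRAME = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [10.0, 10, 10, 10, 10]})

    def test_worked_example(self):
        state = robust_scale_fit(self.FRAME, ["a"])
        out = robust_scale_apply(state, self.FRAME)
        np.testing.assert_allclose(out["a"], [-1, -0.5, 0, 0.5, 1])

    def test_constant_feature_flagged(self):
        state = robust_scale_fit(self.FRAME, ["a", "b"])
        assert state.constant == ["b"]
        assert state.scale["b"] == 1.0

    def test_apply_uses_stored_state_only(self):
        state = robust_scale_fit(self.FRAME, ["a"])
        test = pd.DataFrame({"a": [100.0, 200.0]})
        out = robust_scale_apply(state, test)
        np.testing.assert_allclose(out["a"], [(100 - 3) / 2, (200 - 3) / 2])

    def test_round_trip(self, rng):
        frame = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("xyz"))
        state = robust_scale_fit(frame, ["x", "y", "z"])
        back = robust_scale_invert(state, robust_scale_apply(state, frame))
        np.testing.assert_allclose(back.to_numpy(), frame.to_numpy(),
                                   atol=1e-12)


def test_feature_list_with_and_without_co():
    with_co = continuous_features(True)
    without = continuous_features(False)
    assert "co" in with_co and "co" not in without
    assert set(without) < set(with_co)
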