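"""Metrics, per-class error summaries, paired tests, and the LOSO harness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from armscore.evaluation import (
    build_report,
    loso_cv,
    mean_predictor_loso,
    metrics,
    paired_class_test,
    per_class_errors,
)
from armscore.forest import fma_class
from armscore.models import ModelConfig


class TestMetrics:
    def test_perfect_estimates(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m == {"rmse": 0.0, "r2": 1.0, "bias": 0.0}

    def test_constant_offset(self):
        y = np.array([10.0, 20.0, 30.0])
        m = metrics(y + 2.0, y)
        assert m["bias"] == pytest.approx(2.0)
        assert m["rmse"] == pytest.approx(2.0)

    def test_hand_computed_case(self):
        m = metrics([1.0, 2.0, 3.0], [0.0, 2.0, 4.0])
        assert m["rmse"] == pytest.approx(np.sqrt(2 / 3), abs=1e-12)
        assert m["bias"] == pytest.approx(0.0, abs=1e-12)
        assert m["r2"] == pytest.approx(0.75, abs=1e-12)

    def test_constant_truth_r2_is_nan(self):
        assert np.isnan(metrics([1.0, 2.0], [3.0, 3.0])["r2"])

    def test_rmse_decomposition(self, rng):
        # rmse^2 = bias^2 + error variance (population variance)
        est = rng.normal(size=200)
        y = rng.normal(size=200)
        m = metrics(est, y)
        err = est - y
        assert m["rmse"] ** 2 == pytest.approx(
            m["bias"] ** 2 + err.var(), abs=1e-9
        )


class TestPerClassErrors:
    def test_boundary_class_assignment(self):
        truth = [20.0, 35.0, 40.0, 50.0, 60.0]
        assert list(fma_class(truth)) == [1, 2, 3, 4, 5]
        assert fma_class([30.0])[0] == 1  # "FMA <= 30" is class 1

    def test_quantile_convention(self):
        rows = per_class_errors([18.0, 20.0, 22.0], [20.0, 20.0, 20.0])
        c1 = rows[0]
        assert (c1["n"], c1["median"]) == (3, 0.0)
        assert c1["q1"] == pytest.approx(-1.0)
        assert c1["q3"] == pytest.approx(1.0)

    def test_empty_class_reported_with_nulls(self):
        rows = per_class_errors([35.0], [35.0])
        assert rows[0]["n"] == 0 and rows[0]["median"] is None
        assert rows[1]["n"] == 1

    def test_quartiles_ordered(self, rng):
        est = rng.uniform(0, 66, 100)
        truth = rng.uniform(0, 66, 100)
        for row in per_class_errors(est, truth):
            if row["n"]:
                assert row["q1"] <= row["median"] <= row["q3"]


class TestPairedClassTest:
    def test_closed_form_t(self):
        # |errors| differing by [2,1,3,2,2]: t = 6.3246, p ~= 0.0032
        b = np.zeros(5)
        a = np.array([2.0, 1.0, 3.0, 2.0, 2.0])
        p = paired_class_test(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(6.3246, abs=1e-4)
        assert p == pytest.approx(2 * sstats.t.sf(t, 4), abs=1e-12)
        assert p == pytest.approx(0.0032, abs=2e-4)

    def test_zero_variance_differences_flagged(self):
        assert np.isnan(paired_class_test([3.0, 3.0], [2.0, 2.0]))
        assert np.isnan(paired_class_test([2.0, 2.0], [2.0, 2.0]))

    def test_single_pair_flagged(self):
        assert np.isnan(paired_class_test([1.0], [0.5]))


class TestLosoHarness:
    def test_one_estimate_per_subject_per_method(self, tiny_cohort, tiny_table):
        cfg = ModelConfig(task_trees=10, aggregator_trees=5)
        frame = loso_cv(
            tiny_cohort, methods=("fas_rf", "m2_rf"), config=cfg, seed=0,
            table=tiny_table,
        )
        n = len(tiny_cohort)
        assert (frame["method"] == "fas_rf").sum() == n
        assert (frame["method"] == "m2_rf").sum() == n
        assert frame.groupby("method")["subject_id"].nunique().eq(n).all()

    def test_deterministic_given_seed(self, tiny_cohort, tiny_table):
        cfg = ModelConfig(task_trees=10, aggregator_trees=5)
        a = loso_cv(tiny_cohort, methods=("m2_rf",), config=cfg, seed=3,
                    table=tiny_table)
        b = loso_cv(tiny_cohort, methods=("m2_rf",), config=cfg, seed=3,
                    table=tiny_table)
        assert a.equals(b)

    def test_mean_predictor_baseline_r2_nonpositive(self, tiny_cohort):
        truth = {s.subject_id: float(s.fma_true) for s in tiny_cohort}
        preds = mean_predictor_loso(truth)
        ids = list(truth)
        m = metrics([preds[s] for s in ids], [truth[s] for s in ids])
        assert m["r2"] <= 0.0

    def test_too_few_subjects_raise(self, tiny_cohort):
        with pytest.raises(ValueError):
            loso_cv(tiny_cohort[:2])

    def test_report_invariants(self, tiny_cohort, tiny_table):
        cfg = ModelConfig(task_trees=10, aggregator_trees=5)
        frame = loso_cv(tiny_cohort, methods=("m3_balanced_rf",), config=cfg,
                        seed=1, table=tiny_table)
        rep = build_report(frame, "m3_balanced_rf", "FMA")
        assert rep.rmse >= abs(rep.bias)
        assert rep.rmse >= 0
        assert rep.n == len(tiny_cohort)


class TestMethodComparison:
    def test_per_class_paired_comparison_structure(self, tiny_cohort, tiny_table):
        from armscore.evaluation import compare_methods_per_class
        from armscore.models import ModelConfig

        cfg = ModelConfig(task_trees=10, aggregator_trees=5)
        frame = loso_cv(
            tiny_cohort, methods=("m2_rf", "m3_balanced_rf"), config=cfg,
            seed=2, table=tiny_table,
        )
        pvals = compare_methods_per_class(frame, "m2_rf", "m3_balanced_rf")
        assert set(pvals) == {1, 2, 3, 4, 5}
        for p in pvals.values():
            assert np.isnan(p) or 0.0 <= p <= 1.0

    def test_identical_methods_give_degenerate_comparison(
        self, tiny_cohort, tiny_table
    ):
        from armscore.evaluation import compare_methods_per_class
        from armscore.models import ModelConfig

        cfg = ModelConfig(task_trees=10, aggregator_trees=5)
        frame = loso_cv(
            tiny_cohort, methods=("m2_rf",), config=cfg, seed=2,
            table=tiny_table,
        )
        clone = frame.copy()
        clone["method"] = "m3_balanced_rf"
        both = pd.concat([frame, clone])
        pvals = compare_methods_per_class(both, "m2_rf", "m3_balanced_rf")
        assert all(np.isnan(p) for p in pvals.values())
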