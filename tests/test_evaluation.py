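import math

import pytest

from onconer.evaluation import (
    TASKS,
    EvalResult,
    EvaluationError,
    WeightConfig,
    robustness_curve,
    score_records,
    score_task,
    weighted_overall,
)


def _f1_identity(r: EvalResult) -> None:
    if r.precision + r.recall > 0:
        assert math.isclose(r.f1, 2 * r.precision * r.recall / (r.precision + r.recall))
    else:
        assert r.f1 == 0.0


class TestScoreTask:
    def test_toy_two_thirds(self):
        r = score_task({"d": ["A", "B", "C"]}, {"d": ["A", "B", "D"]})
        assert (r.tp, r.fp, r.fn) == (2, 1, 1)
        assert r.precision == pytest.approx(2 / 3)
        assert r.recall == pytest.approx(2 / 3)
        assert r.f1 == pytest.approx(2 / 3)

    def test_perfect_and_boundary_conventions(self):
        assert score_task({"d": ["A"]}, {"d": ["A"]}).f1 == 1.0
        r = score_task({"d": []}, {"d": ["A"]})
        assert (r.precision, r.recall, r.f1) == (0.0, 0.0, 0.0)
        r = score_task({"d": ["A"]}, {"d": []})
        assert (r.precision, r.recall) == (0.0, 0.0)

    def test_vacuous_perfection_when_all_empty(self):
        r = score_task({"a": [], "b": []}, {"a": [], "b": []})
        assert (r.precision, r.recall, r.f1) == (1.0, 1.0, 1.0)

    def test_id_mismatch_raises_with_ids(self):
        with pytest.raises(EvaluationError, match="doc2"):
            score_task({"doc1": []}, {"doc2": []})

    def test_duplicates_collapse(self):
        r = score_task({"d": ["A", "A"]}, {"d": ["A"]})
        assert (r.tp, r.fp, r.fn) == (1, 0, 0)

    def test_micro_pools_counts_and_is_order_invariant(self):
        pred = {"a": ["x"], "b": ["y", "z"]}
        gold = {"a": ["x", "w"], "b": ["y"]}
        r1 = score_task(pred, gold)
        r2 = score_task(dict(reversed(list(pred.items()))),
                        dict(reversed(list(gold.items()))))
        assert (r1.tp, r1.fp, r1.fn) == (r2.tp, r2.fp, r2.fn) == (2, 1, 1)
        _f1_identity(r1)

    def test_monotonicity(self):
        gold = {"d": ["A", "B"]}
        base = score_task({"d": ["A"]}, gold)
        with_correct = score_task({"d": ["A", "B"]}, gold)
        with_wrong = score_task({"d": ["A", "X"]}, gold)
        assert with_correct.recall >= base.recall
        assert with_wrong.precision <= base.precision

    def test_macro_averages_per_document(self):
        pred = {"a": ["x"], "b": []}
        gold = {"a": ["x"], "b": ["y"]}
        r = score_task(pred, gold, average="macro")
        assert r.f1 == pytest.approx(0.5)


class TestWeightedOverall:
    def test_single_task_weight_passthrough(self):
        results = [EvalResult(1, 1, 1), EvalResult(0, 0, 0), EvalResult(0, 0, 0)]
        overall = weighted_overall(results)
        assert overall.f1 == pytest.approx(0.2)

    def test_uniform_scores_pass_through(self):
        results = [EvalResult(0.5, 0.5, 0.5)] * 3
        assert weighted_overall(results).f1 == pytest.approx(0.5)

    def test_perfect_in_both_modes(self):
        results = [EvalResult.from_counts(5, 0, 0)] * 3
        assert weighted_overall(results, mode="metric").f1 == 1.0
        assert weighted_overall(results, mode="count").f1 == 1.0

    def test_count_mode_reapplies_formulas(self):
        results = [EvalResult.from_counts(1, 1, 0),
                   EvalResult.from_counts(1, 0, 1),
                   EvalResult.from_counts(1, 0, 0)]
        r = weighted_overall(results, mode="count")
        tp = 0.2 * 1 + 0.3 * 1 + 0.5 * 1
        fp, fn = 0.2 * 1, 0.3 * 1
        assert r.precision == pytest.approx(tp / (tp + fp))
        assert r.recall == pytest.approx(tp / (tp + fn))
        _f1_identity(r)

    def test_bad_weights_rejected(self):
        with pytest.raises(EvaluationError, match="sum to 1"):
            WeightConfig(0.5, 0.5, 0.5)

    def test_wrong_arity_rejected(self):
        with pytest.raises(EvaluationError):
            weighted_overall([EvalResult(1, 1, 1)])


class TestRobustnessCurve:
    @staticmethod
    def _records(n, perfect=True):
        gold = {f"d{i}": {"primary_sites": ["肺"], "primary_sizes": ["5CM"],
                          "metastatic_sites": ["肝"]} for i in range(n)}
        pred = {k: dict(v) for k, v in gold.items()}
        if not perfect:
            pred["d0"] = {"primary_sites": [], "primary_sizes": ["5CM"],
                          "metastatic_sites": ["肝", "脑"]}
        return pred, gold

    def test_full_corpus_size_has_zero_std(self):
        pred, gold = self._records(30, perfect=False)
        curve = robustness_curve(pred, gold, sizes=[30], repeats=10, seed=3)
        row = curve.iloc[0]
        assert row["precision_std"] == 0.0
        assert row["recall_std"] == 0.0
        assert row["f1_std"] == 0.0

    def test_full_size_mean_equals_full_corpus_score(self):
        pred, gold = self._records(25, perfect=False)
        curve = robustness_curve(pred, gold, sizes=[25], repeats=5, seed=1)
        tasks = score_records(pred, gold)
        overall = weighted_overall([tasks[t] for t in TASKS])
        assert curve.iloc[0]["f1_mean"] == pytest.approx(overall.f1)

    def test_single_repeat_reports_zero_std(self):
        pred, gold = self._records(10)
        curve = robustness_curve(pred, gold, sizes=[5], repeats=1, seed=0)
        assert curve.iloc[0]["f1_std"] == 0.0

    def test_reproducible_given_seed(self):
        pred, gold = self._records(20, perfect=False)
        c1 = robustness_curve(pred, gold, sizes=[5, 10], repeats=8, seed=11)
        c2 = robustness_curve(pred, gold, sizes=[5, 10], repeats=8, seed=11)
        assert c1.equals(c2)

    def test_oversized_subsample_rejected(self):
        pred, gold = self._records(5)
        with pytest.raises(EvaluationError, match="outside"):
            robustness_curve(pred, gold, sizes=[6], repeats=2, seed=0)


def test_f1_identity_holds_for_all_emitted_results():
    for tp, fp, fn in [(0, 0, 0), (3, 1, 2), (0, 4, 0), (0, 0, 4), (10, 0, 0)]:
        _f1_identity(EvalResult.from_counts(tp, fp, fn))
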