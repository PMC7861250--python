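"""Entity-level evaluation: micro P/R/F1, weighted aggregation, robustness.

Predictions and gold annotations are per-document sets of normalized
entity strings, matched exactly (set semantics, duplicates collapsed).
True positives, false positives and false negatives are pooled over
documents (micro averaging; macro available), then

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall).

True negatives are never computed: extraction has no closed universe of
negatives and the metrics above never use them.

The three task scores combine into an overall score with weights 0.2
(primary site), 0.3 (tumor size) and 0.5 (metastatic site).  Two
aggregation modes exist because weighting can act on the metrics or on the
counts; the default weights the metrics.

The robustness experiment rescored random document subsamples of
increasing size (20..200 step 20, 50 repeats each in the original design)
and reports mean and standard deviation of the weighted metrics per size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TASKS = ("primary_sites", "primary_sizes", "metastatic_sites")


class EvaluationError(ValueError):
    """Raised for mismatched inputs (e.g. pred/gold document id sets)."""


@dataclass(frozen=True)
class EvalResult:
    """TP/FP/FN counts and the derived precision/recall/F1.

    Counts are ``None`` for aggregated results that are not backed by a
    single confusion count (metric-mode weighted overall, macro average).
    """

    precision: float
    recall: float
    f1: float
    tp: float | None = None
    fp: float | None = None
    fn: float | None = None

    @classmethod
    def from_counts(cls, tp: float, fp: float, fn: float, vacuous_perfect: bool = False) -> "EvalResult":
        """Apply the metric formulas with the boundary conventions.

        ``tp+fp = 0`` yields precision 0 and ``tp+fn = 0`` recall 0, except
        when ``vacuous_perfect`` is set (both pred and gold empty for every
        document): then all three metrics are 1.
        """
        if vacuous_perfect and tp == fp == fn == 0:
            return cls(precision=1.0, recall=1.0, f1=1.0, tp=tp, fp=fp, fn=fn)
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        return cls(precision=precision, recall=recall, f1=f1, tp=tp, fp=fp, fn=fn)


@dataclass(frozen=True)
class WeightConfig:
    """Task weights for the overall score; must sum to 1."""

    w_primary: float = 0.2
    w_size: float = 0.3
    w_meta: float = 0.5

    def __post_init__(self) -> None:
        total = self.w_primary + self.w_size + self.w_meta
        if abs(total - 1.0) > 1e-9:
            raise EvaluationError(f"weights must sum to 1, got {total}")

    @property
    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w_primary, self.w_size, self.w_meta)


def _check_ids(pred: Mapping[str, Iterable[str]], gold: Mapping[str, Iterable[str]]) -> None:
    missing = sorted(set(gold) - set(pred))
    extra = sorted(set(pred) - set(gold))
    if missing or extra:
        raise EvaluationError(
            f"document id mismatch: missing from pred {missing[:10]}, not in gold {extra[:10]}")


def score_task(pred: Mapping[str, Iterable[str]], gold: Mapping[str, Iterable[str]],
               average: str = "micro") -> EvalResult:
    """Score one extraction task against gold annotations.

    Per document tp = |pred ∩ gold|, fp = |pred \\ gold|, fn = |gold \\ pred|
    under exact normalized-string matching.  ``micro`` pools counts over
    documents; ``macro`` averages per-document metrics (a document with
    both sides empty counts as perfect).
    """
    if average not in ("micro", "macro"):
        raise EvaluationError(f"unknown averaging mode: {average!r}")
    _check_ids(pred, gold)
    per_doc = []
    for doc_id in gold:
        p, g = set(pred[doc_id]), set(gold[doc_id])
        per_doc.append((len(p & g), len(p - g), len(g - p), not p and not g))
    if not per_doc:
        return EvalResult.from_counts(0, 0, 0, vacuous_perfect=True)
    if average == "micro":
        tp = sum(d[0] for d in per_doc)
        fp = sum(d[1] for d in per_doc)
        fn = sum(d[2] for d in per_doc)
        return EvalResult.from_counts(tp, fp, fn, vacuous_perfect=all(d[3] for d in per_doc))
    results = [EvalResult.from_counts(tp, fp, fn, vacuous_perfect=empty)
               for tp, fp, fn, empty in per_doc]
    return EvalResult(
        precision=float(np.mean([r.precision for r in results])),
        recall=float(np.mean([r.recall for r in results])),
        f1=float(np.mean([r.f1 for r in results])),
    )


def weighted_overall(results: Sequence[EvalResult], weights: WeightConfig | None = None,
                     mode: str = "metric") -> EvalResult:
    """Combine the three task results (primary, size, metastatic) into one.

    ``metric`` mode (default) takes the weight-dot-product of each metric;
    ``count`` mode weight-scales the TP/FP/FN counts and re-applies the
    formulas.
    """
    if len(results) != 3:
        raise EvaluationError("expected exactly three task results (primary, size, meta)")
    weights = weights or WeightConfig()
    if mode == "metric":
        w = weights.as_tuple
        return EvalResult(
            precision=sum(wi * r.precision for wi, r in zip(w, results)),
            recall=sum(wi * r.recall for wi, r in zip(w, results)),
            f1=sum(wi * r.f1 for wi, r in zip(w, results)),
        )
    if mode == "count":
        for r in results:
            if r.tp is None:
                raise EvaluationError("count mode needs results carrying TP/FP/FN counts")
        w = weights.as_tuple
        tp = sum(wi * r.tp for wi, r in zip(w, results))
        fp = sum(wi * r.fp for wi, r in zip(w, results))
        fn = sum(wi * r.fn for wi, r in zip(w, results))
        return EvalResult.from_counts(tp, fp, fn,
                                      vacuous_perfect=all(r.tp == r.fp == r.fn == 0 for r in results))
    raise EvaluationError(f"unknown aggregation mode: {mode!r}")


def score_records(pred: Mapping[str, Mapping[str, list[str]]],
                  gold: Mapping[str, Mapping[str, list[str]]],
                  average: str = "micro") -> dict[str, EvalResult]:
    """Score all three tasks from full prediction/gold records."""
    out = {}
    for task in TASKS:
        out[task] = score_task({i: r.get(task, []) for i, r in pred.items()},
                               {i: r.get(task, []) for i, r in gold.items()},
                               average=average)
    return out


def robustness_curve(pred: Mapping[str, Mapping[str, list[str]]],
                     gold: Mapping[str, Mapping[str, list[str]]],
                     sizes: Sequence[int], repeats: int = 50, seed: int = 0,
                     weights: WeightConfig | None = None, mode: str = "metric",
                     average: str = "micro") -> pd.DataFrame:
    """Weighted scores on random document subsamples of increasing size.

    For each size, ``repeats`` subsets are drawn uniformly without
    replacement (reproducible from ``seed``), the weighted overall score
    computed on each, and the mean and standard deviation (population,
    ddof=0) per metric reported.
    """
    _check_ids(pred, gold)
    if repeats < 1:
        raise EvaluationError("repeats must be >= 1")
    ids = sorted(gold)
    for size in sizes:
        if size < 1 or size > len(ids):
            raise EvaluationError(f"subsample size {size} outside 1..{len(ids)}")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        metrics = np.empty((repeats, 3))
        for rep in range(repeats):
            chosen = rng.choice(len(ids), size=size, replace=False)
            sub = [ids[i] for i in chosen]
            task_results = score_records({i: pred[i] for i in sub},
                                         {i: gold[i] for i in sub}, average=average)
            overall = weighted_overall([task_results[t] for t in TASKS],
                                       weights=weights, mode=mode)
            metrics[rep] = (overall.precision, overall.recall, overall.f1)
        mean, std = metrics.mean(axis=0), metrics.std(axis=0, ddof=0)
        std[np.ptp(metrics, axis=0) == 0] = 0.0  # identical repeats: exactly zero
        rows.append({
            "size": size,
            "precision_mean": mean[0], "precision_std": std[0],
            "recall_mean": mean[1], "recall_std": std[1],
            "f1_mean": mean[2], "f1_std": std[2],
        })
    return pd.DataFrame(rows)
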