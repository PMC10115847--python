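"""Metrics, percentile bootstrap, and coverage-aware predictor comparison.

Variant effect predictors rarely cover the same variants, so naive
benchmark tables mix incomparable numbers.  The protocol here evaluates each
pair of predictors on exactly the variants both cover, reports every
predictor's coverage against the full set, and — for tools that emit a
three-way pathogenic/benign/uncertain call — resolves the uncertain calls as
a random classifier in expectation, so abstention cannot masquerade as
accuracy.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Optional, Sequence

import numpy as np


@dataclasses.dataclass
class ConfusionMetrics:
    """Binary-classification counts and the derived rates.

    Counts may be fractional (see :func:`resolve_uncertain_as_random`).
    MCC is 0 whenever one of its marginals is zero.
    """

    tp: float
    fp: float
    tn: float
    fn: float

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def misclassification_rate(self) -> float:
        return (self.fp + self.fn) / self.n if self.n else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")

    @property
    def mcc(self) -> float:
        denom = math.sqrt(
            (self.tp + self.fp) * (self.tp + self.fn)
            * (self.tn + self.fp) * (self.tn + self.fn)
        )
        if denom == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / denom

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "mcc": self.mcc,
            "ppv": self.ppv, "npv": self.npv,
            "misclassification_rate": self.misclassification_rate,
        }


def confusion_metrics(truth: Sequence[int], predicted: Sequence[int]) -> ConfusionMetrics:
    """Standard confusion counts; 1 = pathogenic / positive."""
    y = np.asarray(list(truth), dtype=int)
    p = np.asarray(list(predicted), dtype=int)
    if len(y) != len(p):
        raise ValueError(f"length mismatch: {len(y)} truth vs {len(p)} predictions")
    return ConfusionMetrics(
        tp=float(np.sum((y == 1) & (p == 1))),
        fp=float(np.sum((y == 0) & (p == 1))),
        tn=float(np.sum((y == 0) & (p == 0))),
        fn=float(np.sum((y == 1) & (p == 0))),
    )


def rank_auc(truth: Sequence[int], scores: Sequence[float]) -> float:
    """ROC-AUC as the Mann-Whitney rank statistic, ties counted half."""
    y = np.asarray(list(truth), dtype=int)
    s = np.asarray(list(scores), dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute AUC")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = float(np.sum(ranks[: len(pos)]))
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return u / (len(pos) * len(neg))


def bootstrap_interval(
    values: Sequence,
    metric,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval by order statistics.

    ``metric`` maps a resampled list of values to a number; the interval is
    the 25th and 975th sorted resample metric when ``n_boot`` is 1000
    (scaling proportionally otherwise, i.e. the 2.5% / 97.5% order
    statistics).  Deterministic given the seed.
    """
    values = list(values)
    if not values:
        raise ValueError("empty sample")
    if n_boot < 40:
        raise ValueError("n_boot must be >= 40 for the 2.5%/97.5% order statistics")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    n = len(values)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        stats[b] = metric([values[i] for i in idx])
    stats.sort()
    lo = stats[int(0.025 * n_boot) - 1]  # 25th of 1000
    hi = stats[int(0.975 * n_boot) - 1]  # 975th of 1000
    return float(lo), float(hi)


@dataclasses.dataclass
class ComparisonReport:
    """Pairwise benchmark on the shared prediction set."""

    n_total: int
    n_shared: int
    coverage_a: float
    coverage_b: float
    metrics_a: ConfusionMetrics
    metrics_b: ConfusionMetrics

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_shared": self.n_shared,
            "coverage_a": self.coverage_a,
            "coverage_b": self.coverage_b,
            "metrics_a": self.metrics_a.as_dict(),
            "metrics_b": self.metrics_b.as_dict(),
        }


def compare_predictors(
    truth: Mapping,
    predictions_a: Mapping,
    predictions_b: Mapping,
) -> ComparisonReport:
    """Benchmark two (possibly partial) predictors on their shared variants.

    ``truth`` maps variant key -> {0, 1}; each predictions map covers a
    subset of those keys with class calls in {0, 1}.  Metrics for both
    predictors are computed on the intersection of their coverage, so the
    evaluation subset is identical whichever order the arguments come in;
    coverage fractions are reported against the full truth set.
    """
    keys = list(truth)
    shared = [k for k in keys if k in predictions_a and k in predictions_b]
    if not shared:
        raise ValueError("no shared predictions")
    y = [int(truth[k]) for k in shared]
    return ComparisonReport(
        n_total=len(keys),
        n_shared=len(shared),
        coverage_a=sum(k in predictions_a for k in keys) / len(keys),
        coverage_b=sum(k in predictions_b for k in keys) / len(keys),
        metrics_a=confusion_metrics(y, [int(predictions_a[k]) for k in shared]),
        metrics_b=confusion_metrics(y, [int(predictions_b[k]) for k in shared]),
    )


def resolve_uncertain_as_random(
    truth: Sequence[int],
    three_way: Sequence[str],
    mode: str = "expected",
    seed: int = 0,
) -> ConfusionMetrics:
    """Score a pathogenic/benign/uncertain predictor with uncertain calls
    resolved as a random classifier.

    In the default analytic mode each uncertain variant contributes half a
    count to its true class's correct cell and half to the error cell — the
    expectation of a fair coin, with no sampling noise.  ``mode="sampled"``
    instead flips a seeded coin per uncertain variant, for sensitivity
    checks.
    """
    y = np.asarray(list(truth), dtype=int)
    calls = list(three_way)
    if len(y) != len(calls):
        raise ValueError(f"length mismatch: {len(y)} truth vs {len(calls)} predictions")
    allowed = {"pathogenic", "benign", "uncertain"}
    bad = set(calls) - allowed
    if bad:
        raise ValueError(f"unknown prediction classes: {sorted(bad)}")

    tp = fp = tn = fn = 0.0
    rng = np.random.default_rng(seed)
    for yi, call in zip(y, calls):
        if call == "uncertain":
            if mode == "sampled":
                call = "pathogenic" if rng.random() < 0.5 else "benign"
            else:
                if yi == 1:
                    tp += 0.5
                    fn += 0.5
                else:
                    tn += 0.5
                    fp += 0.5
                continue
        pred = 1 if call == "pathogenic" else 0
        tp += float(yi == 1 and pred == 1)
        fp += float(yi == 0 and pred == 1)
        tn += float(yi == 0 and pred == 0)
        fn += float(yi == 1 and pred == 0)
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)
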