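"""Multi-label evaluation metrics, protocols and the significance test.

Subset accuracy is the headline measure: an instance counts as correct
only when the predicted label set is an *exact* match of the true set —
a protein truly labelled {1.-.-.-, 1.2.-.-, 1.2.3.-, 1.2.3.4} that is
predicted with only the first three labels is completely incorrect.
Matching empty sets (a correct non-enzyme call) count as a match.

Micro averages pool confusion counts over all labels and so favour
frequent EC classes; macro averages weight every class equally, making
them sensitive to rare-class mistakes; example-based metrics score the
per-protein overlap between true and predicted sets.  The significance
test compares two samples of fold-level metric values with a one-sample
style t statistic using the reference sample's standard deviation:
``t = (X - M) / (sd / sqrt(n))`` with ``n - 1`` degrees of freedom and a
two-tailed p-value from the t distribution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import (
    Dict,
    FrozenSet,
    Iterable,
    List,
    NamedTuple,
    Optional,
    Sequence,
    Tuple,
)

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import ModelFactory
from .dataset import AnnotatedDataset, FoldAssignment, partition_by_group
from .ec import ECLabel, LabelSpace, most_specific

__all__ = [
    "EvaluationReport",
    "LabelCounts",
    "SignificanceResult",
    "confusion_counts",
    "cross_evaluate",
    "digit_histogram",
    "leave_group_out",
    "micro_macro_example_metrics",
    "per_main_class_accuracy",
    "significance",
    "subset_accuracy",
]

LabelSets = Sequence[FrozenSet[ECLabel]]

METRIC_NAMES = (
    "subset_accuracy",
    "micro_precision",
    "micro_recall",
    "macro_precision",
    "macro_recall",
    "example_precision",
    "example_recall",
    "example_accuracy",
)


def _check_lengths(truth: LabelSets, predicted: LabelSets) -> None:
    if len(truth) != len(predicted):
        raise ValueError(
            f"truth has {len(truth)} instances, predictions {len(predicted)}"
        )


def subset_accuracy(truth: LabelSets, predicted: LabelSets) -> float:
    """Fraction of instances whose predicted set exactly equals the truth."""
    _check_lengths(truth, predicted)
    if not truth:
        return 0.0
    hits = sum(1 for t, p in zip(truth, predicted) if t == p)
    return hits / len(truth)


class LabelCounts(NamedTuple):
    tp: int
    fp: int
    fn: int
    tn: int


def confusion_counts(
    truth: LabelSets,
    predicted: LabelSets,
    labels: Iterable[ECLabel],
) -> Dict[ECLabel, LabelCounts]:
    """Per-label TP/FP/FN/TN over the evaluated instances."""
    _check_lengths(truth, predicted)
    n = len(truth)
    tp: Counter = Counter()
    fp: Counter = Counter()
    fn: Counter = Counter()
    for t, p in zip(truth, predicted):
        for lab in t & p:
            tp[lab] += 1
        for lab in p - t:
            fp[lab] += 1
        for lab in t - p:
            fn[lab] += 1
    out = {}
    for lab in labels:
        a, b, c = tp[lab], fp[lab], fn[lab]
        out[lab] = LabelCounts(a, b, c, n - a - b - c)
    return out


def micro_macro_example_metrics(
    truth: LabelSets,
    predicted: LabelSets,
    label_space: Optional[LabelSpace] = None,
    include_absent_labels: bool = False,
) -> Dict[str, float]:
    """Micro-, macro- and example-averaged precision/recall (+ accuracy).

    Macro averages run over labels with at least one true or predicted
    occurrence (never-occurring labels are undefined 0/0 and skipped
    unless *include_absent_labels* forces them in as zeros); a label with
    positives but no predictions contributes zero precision, and
    symmetrically for recall.  Example-based metrics treat the
    empty-truth/empty-prediction instance as fully correct (1.0), so
    correct non-enzyme calls are rewarded, consistent with subset
    accuracy counting them as matches.
    """
    _check_lengths(truth, predicted)
    if label_space is not None:
        labels: List[ECLabel] = list(label_space)
    else:
        seen = set()
        for s in truth:
            seen.update(s)
        for s in predicted:
            seen.update(s)
        labels = sorted(seen)
    counts = confusion_counts(truth, predicted, labels)

    sum_tp = sum(c.tp for c in counts.values())
    sum_fp = sum(c.fp for c in counts.values())
    sum_fn = sum(c.fn for c in counts.values())
    micro_p = sum_tp / (sum_tp + sum_fp) if (sum_tp + sum_fp) else 1.0
    micro_r = sum_tp / (sum_tp + sum_fn) if (sum_tp + sum_fn) else 1.0

    prec_vals: List[float] = []
    rec_vals: List[float] = []
    for lab in labels:
        c = counts[lab]
        occurs = (c.tp + c.fp + c.fn) > 0
        if not occurs and not include_absent_labels:
            continue
        if not occurs:
            prec_vals.append(0.0)
            rec_vals.append(0.0)
            continue
        prec_vals.append(c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0)
        rec_vals.append(c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0)
    macro_p = float(np.mean(prec_vals)) if prec_vals else 1.0
    macro_r = float(np.mean(rec_vals)) if rec_vals else 1.0

    ex_p: List[float] = []
    ex_r: List[float] = []
    ex_a: List[float] = []
    for t, p in zip(truth, predicted):
        if not t and not p:
            ex_p.append(1.0)
            ex_r.append(1.0)
            ex_a.append(1.0)
            continue
        inter = len(t & p)
        ex_p.append(inter / len(p) if p else 0.0)
        ex_r.append(inter / len(t) if t else 0.0)
        ex_a.append(inter / len(t | p))
    n = len(truth)
    return {
        "micro_precision": micro_p,
        "micro_recall": micro_r,
        "macro_precision": macro_p,
        "macro_recall": macro_r,
        "example_precision": float(np.mean(ex_p)) if n else 1.0,
        "example_recall": float(np.mean(ex_r)) if n else 1.0,
        "example_accuracy": float(np.mean(ex_a)) if n else 1.0,
    }


def digit_histogram(label_sets: LabelSets) -> Dict[int, int]:
    """Counts of most-specific label depths (1-4) across label sets.

    Each hierarchical chain contributes one count at the depth of its
    most specific label: a full 4-digit annotation counts once at depth
    4, not four times.
    """
    hist = {1: 0, 2: 0, 3: 0, 4: 0}
    for labels in label_sets:
        for leaf in most_specific(labels):
            hist[leaf.depth] += 1
    return hist


def per_main_class_accuracy(
    truth: LabelSets, predicted: LabelSets
) -> Dict[str, float]:
    """Subset accuracy bucketed by the true labels' main EC class.

    Keys are ``"EC1"`` .. ``"EC6"`` (and higher, should they occur) plus
    ``"no-EC"`` for empty-truth instances; an instance whose true labels
    span several main classes is scored in each such bucket.
    """
    _check_lengths(truth, predicted)
    buckets: Dict[str, List[int]] = {}
    for i, t in enumerate(truth):
        if not t:
            buckets.setdefault("no-EC", []).append(i)
        else:
            for mc in sorted({lab.main_class for lab in t}):
                buckets.setdefault(f"EC{mc}", []).append(i)
    return {
        key: subset_accuracy([truth[i] for i in idx], [predicted[i] for i in idx])
        for key, idx in buckets.items()
    }


@dataclass
class EvaluationReport:
    """Per-fold metric values with their means and standard deviations.

    ``folds`` has one row per (round, fold) with a column per metric;
    standard deviations (sample sd, ddof=1) are only defined for
    multi-fold runs.  Optional extras: per-main-EC-class accuracy and the
    EC-digit histogram of truth and predictions.
    """

    folds: pd.DataFrame
    per_main_class: Optional[Dict[str, float]] = None
    digit_histogram_truth: Optional[Dict[int, int]] = None
    digit_histogram_predicted: Optional[Dict[int, int]] = None

    @property
    def metric_names(self) -> Tuple[str, ...]:
        return tuple(c for c in self.folds.columns if c in METRIC_NAMES)

    @property
    def mean(self) -> pd.Series:
        return self.folds[list(self.metric_names)].mean()

    @property
    def sd(self) -> Optional[pd.Series]:
        if len(self.folds) < 2:
            return None
        return self.folds[list(self.metric_names)].std(ddof=1)

    def __getitem__(self, metric: str) -> float:
        return float(self.mean[metric])

    def fold_values(self, metric: str) -> np.ndarray:
        return self.folds[metric].to_numpy()

    def summary(self) -> pd.DataFrame:
        """One row per metric: mean and (when defined) standard deviation."""
        sd = self.sd
        return pd.DataFrame(
            {
                "mean": self.mean,
                "sd": sd if sd is not None else np.nan,
            }
        ).rename_axis("metric")

    def to_csv(self, path) -> None:
        """Long-format export: one row per fold per metric + summary rows."""
        rows = []
        for _, fold_row in self.folds.iterrows():
            for m in self.metric_names:
                rows.append(
                    {
                        "round": int(fold_row["round"]),
                        "fold": int(fold_row["fold"]),
                        "metric": m,
                        "value": fold_row[m],
                    }
                )
        sd = self.sd
        for m in self.metric_names:
            rows.append({"round": "all", "fold": "mean", "metric": m, "value": self.mean[m]})
            if sd is not None:
                rows.append({"round": "all", "fold": "sd", "metric": m, "value": sd[m]})
        pd.DataFrame(rows).to_csv(path, index=False)


def _score_fold(
    truth: LabelSets, predicted: LabelSets, label_space: LabelSpace
) -> Dict[str, float]:
    out = {"subset_accuracy": subset_accuracy(truth, predicted)}
    out.update(micro_macro_example_metrics(truth, predicted, label_space))
    return out


def cross_evaluate(
    dataset: AnnotatedDataset,
    model_factory: ModelFactory,
    folds: FoldAssignment,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Seeded cross-evaluation: fit on each fold's complement, score the fold.

    The label space stays fixed to the full dataset's, so labels present
    only in a test fold remain scoreable (as unpredictable misses).
    Bit-reproducible for a fixed dataset, factory and fold assignment.
    """
    rows = []
    for r, f, test_idx, train_idx in folds.iter_splits():
        train = dataset.subset(train_idx.tolist(), name=f"{dataset.name}:train")
        model = model_factory(train)
        test_instances = [dataset.instances[i] for i in test_idx.tolist()]
        preds = model.predict(
            [inst.signatures for inst in test_instances], threshold=threshold
        )
        truth = [inst.labels for inst in test_instances]
        row: Dict[str, object] = {"round": r, "fold": f, "n_test": len(test_instances)}
        row.update(_score_fold(truth, preds.label_sets(), dataset.label_space))
        rows.append(row)
    return EvaluationReport(folds=pd.DataFrame(rows))


def leave_group_out(
    dataset: AnnotatedDataset,
    group_key: str,
    group_value: str,
    model_factory: ModelFactory,
    inverse: bool = False,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Jackknife reannotation of one group (e.g. one species' proteome).

    Train on everything except the group and predict the group; with
    ``inverse=True`` train on the group alone and predict the rest.
    Returns a single-run report with per-main-class accuracies and the
    EC-digit histograms attached.
    """
    group, rest = partition_by_group(dataset, group_key, [group_value])
    if len(group) == 0:
        raise ValueError(f"group {group_value!r} is empty")
    train, test = (group, rest) if inverse else (rest, group)
    if len(train) == 0:
        raise ValueError("training side of the split is empty")
    model = model_factory(train)
    preds = model.predict(
        [inst.signatures for inst in test.instances], threshold=threshold
    )
    truth = [inst.labels for inst in test.instances]
    row: Dict[str, object] = {"round": 0, "fold": 0, "n_test": len(test)}
    row.update(_score_fold(truth, preds.label_sets(), dataset.label_space))
    return EvaluationReport(
        folds=pd.DataFrame([row]),
        per_main_class=per_main_class_accuracy(truth, preds.label_sets()),
        digit_histogram_truth=digit_histogram(truth),
        digit_histogram_predicted=digit_histogram(preds.label_sets()),
    )


class SignificanceResult(NamedTuple):
    t: float
    p_value: float
    significant: bool


def significance(
    samples_a: Sequence[float],
    samples_b: Sequence[float],
    alpha: float = 0.05,
) -> SignificanceResult:
    """Two-tailed t-test of two equal-sized metric samples.

    ``t = (X - M) / (sd / sqrt(n))`` where X and sd are the mean and
    sample standard deviation of the reference sample A and M the mean of
    B, with ``n - 1`` degrees of freedom; the p-value is the two-tailed
    tail probability ``2 * (1 - CDF(|t|))`` of the t distribution.  A
    zero reference sd is an error.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"sample sizes differ: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least two samples per set")
    n = a.size
    sd = float(a.std(ddof=1))
    if sd == 0.0:
        raise ValueError("reference sample has zero standard deviation")
    t = (float(a.mean()) - float(b.mean())) / (sd / np.sqrt(n))
    r = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df=r))
    p = min(p, 1.0)
    return SignificanceResult(t=float(t), p_value=p, significant=p < alpha)
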