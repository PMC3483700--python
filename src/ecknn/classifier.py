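"""Binary-relevance k-nearest-neighbour multi-label classification.

The classifier is a lazy learner: fitting stores the training instances
verbatim.  At query time the Euclidean distance to every training
instance is computed *once* and shared across all label problems — the
optimisation that makes binary relevance tractable over thousands of EC
labels.  Over binary signature vectors the squared Euclidean distance is
the size of the symmetric difference of the two signature sets, an
integer, so nearest-neighbour ties are exact.

With the default ``k=1`` and no ties, prediction reduces to copying the
nearest training instance's (hierarchically closed) label set; an empty
predicted set is the cumulative "no-EC" (non-enzyme) call.  Two baseline
predictors are provided: Zero Rule (the modal exact label set of the
training data, the non-enzyme set on realistic data) and the transitive
signature-to-EC mapping baseline.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import (
    Callable,
    Dict,
    FrozenSet,
    Iterable,
    List,
    Mapping,
    Optional,
    Sequence,
    Set,
    Tuple,
)

import numpy as np
from scipy import sparse

from .dataset import AnnotatedDataset
from .ec import ECLabel, LabelSpace, expand_label_set

logger = logging.getLogger(__name__)

__all__ = [
    "FittedModel",
    "PredictionSet",
    "ZeroRuleModel",
    "brknn",
    "distance",
    "fit",
    "majority_label_set",
    "predict",
    "predict_dataset",
    "transitive_predict",
    "zero_rule",
    "zero_rule_predict",
]

SignatureVector = FrozenSet[int]


def distance(a: Iterable[int], b: Iterable[int]) -> float:
    """Euclidean distance between two binary signature vectors.

    Equals ``sqrt(|A symmetric-difference B|)``; zero iff the sets are
    equal, symmetric, and satisfies the triangle inequality.
    """
    return math.sqrt(len(frozenset(a) ^ frozenset(b)))


@dataclass
class PredictionSet:
    """Per-instance predicted label sets with per-label confidences.

    ``no_ec_confidence`` scores the cumulative non-enzyme call as one
    minus the largest label confidence (1.0 when no label got any vote).
    """

    labels: Tuple[FrozenSet[ECLabel], ...]
    confidences: Tuple[Mapping[ECLabel, float], ...]
    no_ec_confidence: Tuple[float, ...]
    ids: Optional[Tuple[str, ...]] = None

    def __len__(self) -> int:
        return len(self.labels)

    def label_sets(self) -> List[FrozenSet[ECLabel]]:
        return list(self.labels)


def _vectors_to_csr(
    vectors: Sequence[Iterable[int]], n_cols: int, *, clip: bool = True
) -> sparse.csr_matrix:
    indptr = [0]
    indices: List[int] = []
    dropped = 0
    for vec in vectors:
        idx = sorted(set(vec))
        if clip:
            kept = [i for i in idx if 0 <= i < n_cols]
            dropped += len(idx) - len(kept)
            idx = kept
        indices.extend(idx)
        indptr.append(len(indices))
    if dropped:
        logger.debug("ignored %d query signature indices outside the vocabulary", dropped)
    data = np.ones(len(indices), dtype=np.int64)
    return sparse.csr_matrix(
        (data, np.asarray(indices, dtype=np.int64), np.asarray(indptr, dtype=np.int64)),
        shape=(len(vectors), n_cols),
    )


@dataclass
class FittedModel:
    """A stored training set ready for shared-distance k-NN queries."""

    ids: Tuple[str, ...]
    label_sets: Tuple[FrozenSet[ECLabel], ...]
    matrix: sparse.csr_matrix
    set_sizes: np.ndarray
    vocabulary: Tuple[str, ...]
    label_space: LabelSpace
    k: int = 1

    def __len__(self) -> int:
        return len(self.ids)

    def predict(
        self,
        queries: Sequence[Iterable[int]],
        threshold: float = 0.5,
        ids: Optional[Sequence[str]] = None,
    ) -> PredictionSet:
        return predict(self, queries, threshold=threshold, ids=ids)


def fit(dataset: AnnotatedDataset, k: int = 1) -> FittedModel:
    """Store the training data for k-NN prediction (lazy learner).

    Every label is kept, including labels with a single training example.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(dataset) == 0:
        raise ValueError("cannot fit on an empty dataset")
    if k > len(dataset):
        raise ValueError(f"k={k} exceeds the {len(dataset)} training instances")
    matrix = _vectors_to_csr(
        [inst.signatures for inst in dataset.instances],
        len(dataset.signature_vocabulary),
        clip=False,
    )
    sizes = np.asarray(matrix.sum(axis=1)).ravel().astype(np.int64)
    return FittedModel(
        ids=dataset.ids,
        label_sets=tuple(inst.labels for inst in dataset.instances),
        matrix=matrix,
        set_sizes=sizes,
        vocabulary=dataset.signature_vocabulary,
        label_space=dataset.label_space,
        k=k,
    )


def predict(
    model: FittedModel,
    queries: Sequence[Iterable[int]],
    threshold: float = 0.5,
    ids: Optional[Sequence[str]] = None,
    chunk_size: int = 512,
) -> PredictionSet:
    """Predict label sets for query signature vectors.

    Distances to all training instances are computed once per query and
    shared across labels.  The neighbour set is the k nearest training
    instances *including every instance tied with the k-th distance*;
    per-label confidence is the fraction of that set carrying the label
    and labels at or above *threshold* (default 0.5) are predicted.
    Query indices outside the training vocabulary are ignored: they shift
    every distance equally and cannot change the neighbour ranking.
    """
    n_cols = model.matrix.shape[1]
    qmat = _vectors_to_csr(list(queries), n_cols, clip=True)
    q_sizes = np.asarray(qmat.sum(axis=1)).ravel().astype(np.int64)
    t_sizes = model.set_sizes
    mt = model.matrix.T.tocsc()

    out_labels: List[FrozenSet[ECLabel]] = []
    out_conf: List[Dict[ECLabel, float]] = []
    out_noec: List[float] = []
    k = model.k
    for start in range(0, qmat.shape[0], chunk_size):
        stop = min(start + chunk_size, qmat.shape[0])
        overlap = (qmat[start:stop] @ mt).toarray().astype(np.int64)
        d2 = q_sizes[start:stop, None] + t_sizes[None, :] - 2 * overlap
        for row in d2:
            if k == 1:
                kth = row.min()
            else:
                kth = np.partition(row, k - 1)[k - 1]
            neighbours = np.flatnonzero(row <= kth)
            counts: Counter = Counter()
            for j in neighbours:
                counts.update(model.label_sets[j])
            m = len(neighbours)
            conf = {lab: c / m for lab, c in counts.items()}
            predicted = frozenset(l for l, c in conf.items() if c >= threshold)
            out_labels.append(predicted)
            out_conf.append(conf)
            out_noec.append(1.0 - max(conf.values(), default=0.0))
    return PredictionSet(
        labels=tuple(out_labels),
        confidences=tuple(out_conf),
        no_ec_confidence=tuple(out_noec),
        ids=tuple(ids) if ids is not None else None,
    )


def predict_dataset(
    model: FittedModel, dataset: AnnotatedDataset, threshold: float = 0.5
) -> PredictionSet:
    """Predict a dataset whose vocabulary may differ from the model's.

    Signatures are aligned by name; query signatures unknown to the
    training vocabulary are dropped with a logged warning.
    """
    index = {s: i for i, s in enumerate(model.vocabulary)}
    vectors: List[FrozenSet[int]] = []
    unknown = 0
    for inst in dataset.instances:
        mapped = []
        for si in inst.signatures:
            name = dataset.signature_vocabulary[si]
            if name in index:
                mapped.append(index[name])
            else:
                unknown += 1
        vectors.append(frozenset(mapped))
    if unknown:
        logger.warning(
            "%d query signature occurrences unknown to the training vocabulary were ignored",
            unknown,
        )
    return predict(model, vectors, threshold=threshold, ids=dataset.ids)


def _label_set_sort_key(s: FrozenSet[ECLabel]) -> Tuple:
    return tuple(sorted(lab.digits for lab in s))


def majority_label_set(dataset: AnnotatedDataset) -> Tuple[FrozenSet[ECLabel], float]:
    """The modal exact label set of a dataset and its support fraction.

    Ties break toward the empty (non-enzyme) set, then lexicographically.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset has no majority label set")
    counts = Counter(inst.labels for inst in dataset.instances)
    best = min(
        counts.items(),
        key=lambda kv: (-kv[1], len(kv[0]) > 0, _label_set_sort_key(kv[0])),
    )
    return best[0], best[1] / len(dataset)


@dataclass
class ZeroRuleModel:
    """Majority-class baseline: every query gets the modal label set."""

    modal_set: FrozenSet[ECLabel]
    support: float
    label_space: LabelSpace
    vocabulary: Tuple[str, ...]

    def predict(
        self,
        queries: Sequence[Iterable[int]],
        threshold: float = 0.5,
        ids: Optional[Sequence[str]] = None,
    ) -> PredictionSet:
        n = len(queries)
        conf = {lab: self.support for lab in self.modal_set}
        no_ec = 1.0 - (self.support if self.modal_set else 0.0)
        if not self.modal_set:
            no_ec = 1.0
        return PredictionSet(
            labels=tuple(self.modal_set for _ in range(n)),
            confidences=tuple(dict(conf) for _ in range(n)),
            no_ec_confidence=tuple(no_ec for _ in range(n)),
            ids=tuple(ids) if ids is not None else None,
        )


def zero_rule(dataset: AnnotatedDataset) -> ZeroRuleModel:
    modal, support = majority_label_set(dataset)
    return ZeroRuleModel(
        modal_set=modal,
        support=support,
        label_space=dataset.label_space,
        vocabulary=dataset.signature_vocabulary,
    )


def zero_rule_predict(dataset: AnnotatedDataset) -> PredictionSet:
    """Zero Rule self-prediction: the modal exact label set for every instance."""
    model = zero_rule(dataset)
    return model.predict([inst.signatures for inst in dataset.instances], ids=dataset.ids)


def transitive_predict(
    queries: Sequence[Iterable[str]],
    signature_to_ec: Mapping[str, Iterable[ECLabel]],
    ids: Optional[Sequence[str]] = None,
) -> PredictionSet:
    """Direct signature-to-EC transitive annotation baseline.

    Each query's prediction is the hierarchical expansion of the union of
    the ECs mapped from its signatures, all at confidence 1.0; queries
    with no mapping hit get the empty (non-enzyme) prediction.
    """
    out_labels: List[FrozenSet[ECLabel]] = []
    out_conf: List[Dict[ECLabel, float]] = []
    out_noec: List[float] = []
    for sigs in queries:
        raw: Set[ECLabel] = set()
        for s in sigs:
            raw.update(signature_to_ec.get(s, ()))
        expanded = expand_label_set(raw)
        out_labels.append(expanded)
        out_conf.append({lab: 1.0 for lab in expanded})
        out_noec.append(1.0 if not expanded else 0.0)
    return PredictionSet(
        labels=tuple(out_labels),
        confidences=tuple(out_conf),
        no_ec_confidence=tuple(out_noec),
        ids=tuple(ids) if ids is not None else None,
    )


ModelFactory = Callable[[AnnotatedDataset], object]


def brknn(k: int = 1) -> ModelFactory:
    """Model factory for cross-evaluation: ``brknn(k)(train) -> FittedModel``."""

    def factory(train: AnnotatedDataset) -> FittedModel:
        return fit(train, k=k)

    return factory


def zero_rule_factory() -> ModelFactory:
    """Model factory building the Zero Rule baseline from a training set."""
    return zero_rule
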