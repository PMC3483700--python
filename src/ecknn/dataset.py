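"""Annotated protein datasets: assembly, joins, partitions, folds, censuses.

An :class:`AnnotatedDataset` couples a signature vocabulary (binary
attributes, one per InterPro-style signature), a hierarchically closed
:class:`~ecknn.ec.LabelSpace`, and a list of protein instances, each with
a sparse binary signature vector, an expanded true label set and optional
group keys (species, taxon, cluster representative).  Empty signature
vectors and empty label sets (non-enzymes) are legal instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import (
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
import pandas as pd
from scipy import sparse

from .ec import (
    ECLabel,
    ECStatusTable,
    LabelSpace,
    build_label_space,
    expand_label_set,
    most_specific,
    parse_ec,
    remap_annotations,
)

__all__ = [
    "AnnotatedDataset",
    "FoldAssignment",
    "Instance",
    "SignatureSetStats",
    "assemble",
    "count_combinations",
    "duplicate_collapse_map",
    "ec_cumulative_distribution",
    "join_agreeing",
    "make_folds",
    "partition_by_group",
    "random_subset",
    "reduce_to_representatives",
    "signature_set_stats",
]


@dataclass(frozen=True)
class Instance:
    """One protein: id, sparse signature vector, expanded labels, groups."""

    id: str
    signatures: FrozenSet[int]
    labels: FrozenSet[ECLabel]
    groups: Mapping[str, str] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Instance):
            return NotImplemented
        return (
            self.id == other.id
            and self.signatures == other.signatures
            and self.labels == other.labels
            and dict(self.groups) == dict(other.groups)
        )


@dataclass
class AnnotatedDataset:
    """Instances x signature vocabulary x label space."""

    signature_vocabulary: Tuple[str, ...]
    label_space: LabelSpace
    instances: Tuple[Instance, ...]
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.signature_vocabulary = tuple(self.signature_vocabulary)
        self.instances = tuple(self.instances)

    def __len__(self) -> int:
        return len(self.instances)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedDataset):
            return NotImplemented
        return (
            self.signature_vocabulary == other.signature_vocabulary
            and self.label_space == other.label_space
            and self.instances == other.instances
        )

    @property
    def ids(self) -> Tuple[str, ...]:
        return tuple(inst.id for inst in self.instances)

    def label_sets(self) -> List[FrozenSet[ECLabel]]:
        return [inst.labels for inst in self.instances]

    def vectors(self) -> List[FrozenSet[int]]:
        return [inst.signatures for inst in self.instances]

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on breach."""
        n_sig = len(self.signature_vocabulary)
        if len(set(self.signature_vocabulary)) != n_sig:
            raise ValueError("duplicate signature in vocabulary")
        seen_ids: Set[str] = set()
        for inst in self.instances:
            if inst.id in seen_ids:
                raise ValueError(f"duplicate instance id {inst.id!r}")
            seen_ids.add(inst.id)
            for idx in inst.signatures:
                if not 0 <= idx < n_sig:
                    raise ValueError(
                        f"instance {inst.id!r}: signature index {idx} out of bounds"
                    )
            for lab in inst.labels:
                if lab not in self.label_space:
                    raise ValueError(f"instance {inst.id!r}: label {lab} not in label space")
            if expand_label_set(inst.labels) != inst.labels:
                raise ValueError(f"instance {inst.id!r}: label set not hierarchically closed")

    def to_attribute_matrix(self) -> sparse.csr_matrix:
        """Instances-by-signatures binary matrix (CSR, int8)."""
        indptr = [0]
        indices: List[int] = []
        for inst in self.instances:
            indices.extend(sorted(inst.signatures))
            indptr.append(len(indices))
        data = np.ones(len(indices), dtype=np.int8)
        return sparse.csr_matrix(
            (data, indices, indptr),
            shape=(len(self.instances), len(self.signature_vocabulary)),
        )

    def subset(self, indices: Sequence[int], name: Optional[str] = None) -> "AnnotatedDataset":
        """A new dataset over the same vocabulary/label space."""
        return AnnotatedDataset(
            signature_vocabulary=self.signature_vocabulary,
            label_space=self.label_space,
            instances=tuple(self.instances[i] for i in indices),
            name=name or self.name,
        )


def assemble(
    ec_map: Mapping[str, Set[str]],
    signature_map: Mapping[str, Set[str]],
    group_maps: Optional[Mapping[str, Mapping[str, str]]] = None,
    status_table: Optional[ECStatusTable] = None,
    name: str = "dataset",
) -> AnnotatedDataset:
    """Build a dataset from raw annotation maps.

    EC strings are parsed, modernised against *status_table* (when given)
    and hierarchically expanded; the signature vocabulary and label space
    are built deterministically (sorted).  Proteins appearing in any map
    are retained, including proteins with no signatures or no labels; a
    protein annotated only with a deleted EC becomes a non-enzyme.
    """
    group_maps = group_maps or {}
    proteins: Set[str] = set(ec_map) | set(signature_map)
    for gm in group_maps.values():
        proteins.update(gm)
    protein_order = sorted(proteins)

    vocabulary = tuple(sorted({s for sigs in signature_map.values() for s in sigs}))
    sig_index = {s: i for i, s in enumerate(vocabulary)}

    parsed: Dict[str, FrozenSet[ECLabel]] = {}
    for pid in protein_order:
        raw = {parse_ec(e) for e in ec_map.get(pid, set())}
        if status_table is not None:
            raw = set(remap_annotations(raw, status_table))
        parsed[pid] = expand_label_set(raw)

    label_space = build_label_space(parsed.values())
    instances = []
    for pid in protein_order:
        groups = {
            key: gm[pid] for key, gm in group_maps.items() if pid in gm
        }
        instances.append(
            Instance(
                id=pid,
                signatures=frozenset(
                    sig_index[s] for s in signature_map.get(pid, set())
                ),
                labels=parsed[pid],
                groups=groups,
            )
        )
    ds = AnnotatedDataset(vocabulary, label_space, tuple(instances), name=name)
    ds.validate()
    return ds


def join_agreeing(
    annotations_a: Mapping[str, Set[str]],
    annotations_b: Mapping[str, Set[str]],
) -> Dict[str, Set[str]]:
    """Keep only (protein, EC) couples present in both sources.

    A protein is retained with the intersection of its EC sets; a protein
    recorded as a non-enzyme (empty set) in *both* sources is retained as
    an agreeing non-enzyme; a protein whose non-empty annotations fully
    disagree, or which is absent from either source, is dropped.
    Symmetric in its arguments.
    """
    out: Dict[str, Set[str]] = {}
    for pid in set(annotations_a) & set(annotations_b):
        a, b = set(annotations_a[pid]), set(annotations_b[pid])
        common = a & b
        if common:
            out[pid] = common
        elif not a and not b:
            out[pid] = set()
    return out


def partition_by_group(
    dataset: AnnotatedDataset, group_key: str, values: Iterable[str]
) -> Tuple[AnnotatedDataset, AnnotatedDataset]:
    """Split into (members, complement) by group-key membership.

    Both halves share the parent's vocabulary and label space.  Instances
    lacking the key fall into the complement; an entirely unknown key is
    an error.
    """
    if not any(group_key in inst.groups for inst in dataset.instances):
        raise KeyError(f"group key {group_key!r} not present in dataset")
    values = set(values)
    inside = [
        i
        for i, inst in enumerate(dataset.instances)
        if inst.groups.get(group_key) in values
    ]
    outside = [
        i
        for i, inst in enumerate(dataset.instances)
        if inst.groups.get(group_key) not in values
    ]
    return (
        dataset.subset(inside, name=f"{dataset.name}:{group_key}"),
        dataset.subset(outside, name=f"{dataset.name}:not-{group_key}"),
    )


def random_subset(dataset: AnnotatedDataset, n: int, seed: int) -> AnnotatedDataset:
    """Uniform sample of *n* instances without replacement, seeded.

    Selected instances keep their original order, so sampling all
    instances returns the dataset unchanged.
    """
    if n > len(dataset):
        raise ValueError(f"cannot sample {n} of {len(dataset)} instances")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(len(dataset), size=n, replace=False))
    return dataset.subset(chosen.tolist(), name=f"{dataset.name}:random{n}")


def reduce_to_representatives(
    dataset: AnnotatedDataset, cluster_map: Mapping[str, str]
) -> AnnotatedDataset:
    """Keep one representative instance per cluster (UniRef-style).

    ``cluster_map`` maps member id to representative id; a member absent
    from the map is its own representative.  A representative id missing
    from the dataset raises ``ValueError``.
    """
    ids = set(inst.id for inst in dataset.instances)
    keep = []
    for i, inst in enumerate(dataset.instances):
        rep = cluster_map.get(inst.id, inst.id)
        if rep not in ids:
            raise ValueError(
                f"representative {rep!r} of member {inst.id!r} not in dataset"
            )
        if rep == inst.id:
            keep.append(i)
    return dataset.subset(keep, name=f"{dataset.name}:representatives")


@dataclass(frozen=True)
class FoldAssignment:
    """Seeded, reproducible cross-evaluation folds.

    ``folds[r][f]`` is the array of instance indices forming fold *f* of
    round *r*; each round is a partition with fold sizes differing by at
    most one.
    """

    seed: int
    n_folds: int
    rounds: int
    folds: Tuple[Tuple[np.ndarray, ...], ...]

    def iter_splits(self):
        """Yield (round, fold, test_indices, train_indices)."""
        for r, round_folds in enumerate(self.folds):
            all_idx = np.concatenate(round_folds)
            for f, test_idx in enumerate(round_folds):
                mask = np.ones(len(all_idx), dtype=bool)
                test_set = set(test_idx.tolist())
                train_idx = np.array(
                    [i for i in np.sort(all_idx) if i not in test_set], dtype=np.int64
                )
                yield r, f, test_idx, train_idx


# Per the curation-scale protocol: small datasets get a second round of
# cross-evaluation to stabilise the reported means.
TWO_ROUND_THRESHOLD = 40_000


def make_folds(
    dataset: AnnotatedDataset,
    n_folds: int = 10,
    rounds: Optional[int] = None,
    seed: int = 0,
) -> FoldAssignment:
    """Seeded shuffle + contiguous slicing into *n_folds* folds per round.

    ``rounds=None`` applies the default policy: two rounds below
    :data:`TWO_ROUND_THRESHOLD` instances, one round otherwise.
    """
    n = len(dataset)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n < n_folds:
        raise ValueError(f"{n} instances cannot fill {n_folds} folds")
    if rounds is None:
        rounds = 2 if n < TWO_ROUND_THRESHOLD else 1
    all_rounds = []
    for r in range(rounds):
        rng = np.random.default_rng([seed, r])
        perm = rng.permutation(n)
        all_rounds.append(tuple(np.array_split(perm, n_folds)))
    return FoldAssignment(seed=seed, n_folds=n_folds, rounds=rounds, folds=tuple(all_rounds))


def ec_cumulative_distribution(dataset: AnnotatedDataset) -> pd.DataFrame:
    """Cumulative share of enzyme annotations vs class rank.

    Leaf (most specific) labels only, ranked by descending frequency; the
    returned frame has columns ``rank_fraction`` and
    ``cumulative_fraction`` in percent, non-decreasing, ending at 100.
    Long-tail distributed data bows far above the diagonal.  Datasets
    without enzymes yield an empty frame.
    """
    counts: Dict[ECLabel, int] = {}
    for inst in dataset.instances:
        for leaf in most_specific(inst.labels):
            counts[leaf] = counts.get(leaf, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["rank_fraction", "cumulative_fraction"])
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    values = np.array([c for _, c in ordered], dtype=float)
    k = len(values)
    rank_fraction = 100.0 * np.arange(1, k + 1) / k
    cumulative = 100.0 * np.cumsum(values) / values.sum()
    return pd.DataFrame(
        {"rank_fraction": rank_fraction, "cumulative_fraction": cumulative}
    )


@dataclass(frozen=True)
class SignatureSetStats:
    """Census of the distinct unordered signature sets in a dataset."""

    n_distinct: int
    mean_size: float
    n_maximal: int


def signature_set_stats(dataset: AnnotatedDataset) -> SignatureSetStats:
    """Distinct signature sets, their mean size, and how many are maximal.

    A maximal set is not a proper subset of any other distinct set
    present; a handful of maximal sets can cover a large protein corpus.
    """
    distinct = sorted(
        {inst.signatures for inst in dataset.instances},
        key=lambda s: (-len(s), sorted(s)),
    )
    mean_size = float(np.mean([len(s) for s in distinct])) if distinct else 0.0
    n_maximal = 0
    for i, s in enumerate(distinct):
        # distinct is size-sorted: only strictly larger sets can contain s
        if not any(len(t) > len(s) and s < t for t in distinct[:i]):
            n_maximal += 1
    return SignatureSetStats(
        n_distinct=len(distinct), mean_size=mean_size, n_maximal=n_maximal
    )


def count_combinations(n: int, k: int) -> int:
    """Exact binomial coefficient C(n, k), arbitrary precision."""
    if k < 0 or n < 0:
        raise ValueError("n and k must be non-negative")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    return math.comb(n, k)


def duplicate_collapse_map(dataset: AnnotatedDataset) -> Dict[str, str]:
    """UniRef100-like duplicate collapse over identical signature sets.

    The first instance (in dataset order) carrying a given signature set
    is the representative for every later instance with the same set.
    """
    rep_of_set: Dict[FrozenSet[int], str] = {}
    mapping: Dict[str, str] = {}
    for inst in dataset.instances:
        rep = rep_of_set.setdefault(inst.signatures, inst.id)
        mapping[inst.id] = rep
    return mapping
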