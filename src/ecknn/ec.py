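"""Enzyme Commission (EC) numbers, their hierarchy and status remapping.

An EC number is a four-field dot-separated code (e.g. ``1.2.3.4``): the
first three fields give an increasingly specific reaction class, the last
the accepted substrates.  Annotations may be *incomplete* (``1.2.-.-``),
with trailing fields unspecified; such partial labels are legitimate class
labels in their own right and frequently occur in curated databases.

The ENZYME nomenclature also evolves: individual 4-digit entries can be
*deleted* or *transferred* to one or more replacement entries.  This module
models labels (:class:`ECLabel`), the status table used to modernise
annotations (:class:`ECStatusTable`), and the ordered, hierarchically
closed label universe a classifier predicts over (:class:`LabelSpace`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import total_ordering
from typing import Dict, FrozenSet, Iterable, Iterator, Mapping, Optional, Sequence, Set, Tuple

logger = logging.getLogger(__name__)

__all__ = [
    "ECLabel",
    "ECParseError",
    "ECStatusError",
    "ECStatusTable",
    "LabelSpace",
    "ancestors",
    "build_label_space",
    "expand_label_set",
    "most_specific",
    "parse_ec",
    "remap_annotations",
]


class ECParseError(ValueError):
    """Raised for malformed EC number strings."""


class ECStatusError(ValueError):
    """Raised for inconsistent or cyclic EC status tables."""


@total_ordering
@dataclass(frozen=True)
class ECLabel:
    """One EC number at 1-4 digit resolution.

    ``digits`` holds the specified components; unspecified trailing
    positions render as ``-``.  Two labels are equal iff their digit
    tuples are identical; ordering is numeric-lexicographic, which puts a
    prefix before any of its descendants (``1.-.-.-`` < ``1.2.-.-``).
    """

    digits: Tuple[int, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.digits, tuple):
            object.__setattr__(self, "digits", tuple(self.digits))
        if not 1 <= len(self.digits) <= 4:
            raise ECParseError(
                f"EC label needs 1-4 components, got {len(self.digits)}"
            )
        for i, d in enumerate(self.digits, start=1):
            if not isinstance(d, int) or isinstance(d, bool) or d <= 0:
                raise ECParseError(
                    f"EC component {i} must be a positive integer, got {d!r}"
                )

    @property
    def depth(self) -> int:
        """Number of specified components (1-4)."""
        return len(self.digits)

    @property
    def main_class(self) -> int:
        """The first digit: the top-level reaction class (1-6 in practice)."""
        return self.digits[0]

    @property
    def parent(self) -> Optional["ECLabel"]:
        """The depth-1 prefix, or ``None`` for a top-level label."""
        if len(self.digits) == 1:
            return None
        return ECLabel(self.digits[:-1])

    def is_prefix_of(self, other: "ECLabel") -> bool:
        """True when *self* is a proper prefix (ancestor) of *other*."""
        return (
            len(self.digits) < len(other.digits)
            and other.digits[: len(self.digits)] == self.digits
        )

    def __str__(self) -> str:
        fields = [str(d) for d in self.digits] + ["-"] * (4 - len(self.digits))
        return ".".join(fields)

    def __repr__(self) -> str:  # pragma: no cover - debugging sugar
        return f"ECLabel({self})"

    def __lt__(self, other: "ECLabel") -> bool:
        if not isinstance(other, ECLabel):
            return NotImplemented
        return self.digits < other.digits


def parse_ec(text: str) -> ECLabel:
    """Parse an EC number string into an :class:`ECLabel`.

    Accepts 1-4 dot-separated fields, optionally padded with ``-`` fields
    and optionally prefixed by ``EC`` (``"EC 1.2.-.-"``).  A specified
    field after an unspecified one (``"1.-.3.-"``) is rejected.
    """
    s = text.strip()
    if s.upper().startswith("EC"):
        s = s[2:].lstrip(" :")
    if not s:
        raise ECParseError(f"empty EC number in {text!r}")
    fields = s.split(".")
    if len(fields) > 4:
        raise ECParseError(f"too many components ({len(fields)}) in {text!r}")
    digits: list[int] = []
    seen_wildcard = False
    for i, f in enumerate(fields, start=1):
        f = f.strip()
        if f in ("-", ""):
            seen_wildcard = True
            continue
        if seen_wildcard:
            raise ECParseError(
                f"component {i} ({f!r}) specified after a wildcard in {text!r}"
            )
        try:
            value = int(f)
        except ValueError:
            raise ECParseError(f"component {i} ({f!r}) is not an integer in {text!r}") from None
        if value <= 0:
            raise ECParseError(f"component {i} ({value}) must be positive in {text!r}")
        digits.append(value)
    if not digits:
        raise ECParseError(f"no specified component in {text!r}")
    return ECLabel(tuple(digits))


def ancestors(label: ECLabel) -> Tuple[ECLabel, ...]:
    """All proper prefixes of *label*, in increasing depth.

    ``1.2.3.4`` -> ``(1.-.-.-, 1.2.-.-, 1.2.3.-)``; a depth-1 label has
    no ancestors.
    """
    return tuple(ECLabel(label.digits[:d]) for d in range(1, label.depth))


def expand_label_set(labels: Iterable[ECLabel]) -> FrozenSet[ECLabel]:
    """Hierarchical closure: the input plus every ancestor of each member.

    Idempotent and monotone; the empty set (a non-enzyme) stays empty.
    """
    out: Set[ECLabel] = set()
    for lab in labels:
        out.add(lab)
        out.update(ancestors(lab))
    return frozenset(out)


def most_specific(labels: Iterable[ECLabel]) -> FrozenSet[ECLabel]:
    """The maximal (leaf) labels of a hierarchically related set.

    A label is dropped when the set also contains one of its descendants;
    on an expanded set this recovers the original annotations.
    """
    labs = set(labels)
    return frozenset(
        a for a in labs if not any(a.is_prefix_of(b) for b in labs)
    )


@dataclass(frozen=True)
class _StatusEntry:
    status: str
    replacements: Tuple[ECLabel, ...] = ()


class ECStatusTable:
    """Active / deleted / transferred status of 4-digit EC numbers.

    Transferred entries carry one or more replacements which are resolved
    transitively; a cyclic transfer chain raises :class:`ECStatusError`.
    """

    _STATUSES = ("active", "deleted", "transferred")

    def __init__(
        self,
        entries: Mapping[ECLabel, Tuple[str, Sequence[ECLabel]]],
    ) -> None:
        table: Dict[ECLabel, _StatusEntry] = {}
        for label, (status, replacements) in entries.items():
            status = status.lower()
            if label.depth != 4:
                raise ECStatusError(f"status table entries must be 4-digit ECs, got {label}")
            if status not in self._STATUSES:
                raise ECStatusError(f"unknown status {status!r} for {label}")
            reps = tuple(replacements)
            if status == "transferred" and not reps:
                raise ECStatusError(f"transferred entry {label} has no replacement")
            if status != "transferred" and reps:
                raise ECStatusError(f"{status} entry {label} must not carry replacements")
            table[label] = _StatusEntry(status, reps)
        self._entries = table
        self._cache: Dict[ECLabel, FrozenSet[ECLabel]] = {}

    def __contains__(self, label: ECLabel) -> bool:
        return label in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def status(self, label: ECLabel) -> Optional[str]:
        entry = self._entries.get(label)
        return entry.status if entry is not None else None

    def resolve(self, label: ECLabel) -> FrozenSet[ECLabel]:
        """Fully resolve one label: itself if active/unknown, nothing if
        deleted, the transitive replacement set if transferred."""
        return self._resolve(label, ())

    def _resolve(self, label: ECLabel, stack: Tuple[ECLabel, ...]) -> FrozenSet[ECLabel]:
        if label in self._cache:
            return self._cache[label]
        if label in stack:
            chain = " -> ".join(str(l) for l in stack + (label,))
            raise ECStatusError(f"cyclic EC transfer chain: {chain}")
        entry = self._entries.get(label)
        if entry is None or entry.status == "active":
            result = frozenset({label})
        elif entry.status == "deleted":
            result = frozenset()
        else:  # transferred
            acc: Set[ECLabel] = set()
            for rep in entry.replacements:
                acc.update(self._resolve(rep, stack + (label,)))
            result = frozenset(acc)
        self._cache[label] = result
        return result


def remap_annotations(
    annotations: Iterable[ECLabel], table: ECStatusTable
) -> FrozenSet[ECLabel]:
    """Modernise raw annotations against an EC status table.

    Deleted labels are dropped, transferred labels replaced (transitively)
    by all their replacements; partial labels pass through untouched.  A
    4-digit label absent from the table is treated as active with a
    logged warning (the table is assumed to be a complete export, but an
    incomplete one should not destroy data).
    """
    out: Set[ECLabel] = set()
    for lab in annotations:
        if lab.depth < 4:
            out.add(lab)
            continue
        if lab not in table:
            logger.warning("EC %s absent from status table; treated as active", lab)
            out.add(lab)
            continue
        out.update(table.resolve(lab))
    return frozenset(out)


class LabelSpace(Sequence):
    """The ordered, hierarchically closed set of predictable EC labels.

    The implicit "no-EC" (non-enzyme) outcome is the empty label set and
    is not an element.  Order is numeric-lexicographic, which is stable,
    deterministic and places every label after its ancestors.
    """

    def __init__(self, labels: Iterable[ECLabel]) -> None:
        closed = expand_label_set(labels)
        self._labels: Tuple[ECLabel, ...] = tuple(sorted(closed))
        self._index: Dict[ECLabel, int] = {
            lab: i for i, lab in enumerate(self._labels)
        }

    @property
    def labels(self) -> Tuple[ECLabel, ...]:
        return self._labels

    def index(self, label: ECLabel) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"label {label} not in label space") from None

    def parent(self, label: ECLabel) -> Optional[ECLabel]:
        p = label.parent
        if p is not None and p not in self._index:  # pragma: no cover - closure guard
            raise KeyError(f"label space not closed: {p} missing")
        return p

    @property
    def roots(self) -> Tuple[ECLabel, ...]:
        return tuple(l for l in self._labels if l.depth == 1)

    def children(self, label: ECLabel) -> Tuple[ECLabel, ...]:
        return tuple(
            l for l in self._labels if l.parent == label
        )

    def __len__(self) -> int:
        return len(self._labels)

    def __getitem__(self, i):
        return self._labels[i]

    def __iter__(self) -> Iterator[ECLabel]:
        return iter(self._labels)

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelSpace):
            return NotImplemented
        return self._labels == other._labels

    def __hash__(self) -> int:
        return hash(self._labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"LabelSpace({len(self)} labels)"


def build_label_space(all_annotations: Iterable[Iterable[ECLabel]]) -> LabelSpace:
    """Union all per-instance label sets into one closed, ordered space."""
    seen: Set[ECLabel] = set()
    for labels in all_annotations:
        seen.update(labels)
    return LabelSpace(seen)
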