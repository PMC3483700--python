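"""File formats: sparse ARFF + XML label hierarchy, delimited tables.

The dataset interchange format is a sparse Weka-style ARFF file paired
with a Mulan-style XML document describing the label hierarchy:

* every signature is a binary attribute ``@attribute IPR000001 {0,1}``;
* label columns follow the signature columns, named by the canonical EC
  string with ``EC_`` prefixed and dots replaced by underscores
  (``EC_1_2_-_-``);
* data rows are sparse, ``{index 1, index 1, ...}``; an instance with no
  attributes and no labels is the row ``{}``; dense rows are accepted on
  input;
* each data row is preceded by a full-line comment carrying the instance
  id and any group keys, tab-separated: ``% id=P00001\tspecies=E. coli``.
  Comment lines are legal ARFF and invisible to other ARFF readers; they
  let a write -> read -> write cycle reproduce the file byte for byte.

Annotation tables are headerless two-column CSVs, one (protein, value)
pair per row, with an empty value marking a non-enzyme row.  The EC
status table is a headed CSV with columns ``ec,status,replacements``
(replacements semicolon-separated).  All text is UTF-8 with ``\n`` line
endings.
"""

from __future__ import annotations

import csv
import os
import re
import tempfile
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from lxml import etree

from .classifier import PredictionSet
from .dataset import AnnotatedDataset, Instance
from .ec import ECLabel, ECStatusTable, LabelSpace, parse_ec

__all__ = [
    "ARFFParseError",
    "TableParseError",
    "label_attribute_name",
    "parse_label_attribute_name",
    "read_annotation_tables",
    "read_cluster_map",
    "read_signature_ec_map",
    "read_sparse_arff",
    "read_status_table",
    "write_predictions_csv",
    "write_sparse_arff",
]


class ARFFParseError(ValueError):
    """Malformed ARFF/XML input; the message carries the line number."""


class TableParseError(ValueError):
    """Malformed delimited table; the message carries the row number."""


def label_attribute_name(label: ECLabel) -> str:
    """``1.2.-.-`` -> ``EC_1_2_-_-`` (safe as an ARFF attribute name)."""
    return "EC_" + str(label).replace(".", "_")


def parse_label_attribute_name(name: str) -> ECLabel:
    if not name.startswith("EC_"):
        raise ARFFParseError(f"label attribute {name!r} lacks the EC_ prefix")
    return parse_ec(name[3:].replace("_", "."))


def _atomic_write_text(path: Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _instance_comment(inst: Instance) -> str:
    parts = [f"id={inst.id}"]
    for key in sorted(inst.groups):
        parts.append(f"{key}={inst.groups[key]}")
    return "% " + "\t".join(parts)


def write_sparse_arff(
    dataset: AnnotatedDataset,
    arff_path: os.PathLike,
    xml_path: Optional[os.PathLike] = None,
    header_comment: Optional[str] = None,
) -> Tuple[Path, Path]:
    """Write the ARFF + XML hierarchy pair; byte-stable for a fixed dataset.

    Returns the two paths written.  ``xml_path`` defaults to the ARFF
    path with an ``.xml`` suffix.
    """
    arff_path = Path(arff_path)
    xml_path = Path(xml_path) if xml_path is not None else arff_path.with_suffix(".xml")
    n_sig = len(dataset.signature_vocabulary)

    lines: List[str] = []
    if header_comment:
        for cl in header_comment.splitlines():
            lines.append(f"% {cl}")
    lines.append(f"@relation {dataset.name}")
    lines.append("")
    for sig in dataset.signature_vocabulary:
        lines.append(f"@attribute {sig} {{0,1}}")
    for label in dataset.label_space:
        lines.append(f"@attribute {label_attribute_name(label)} {{0,1}}")
    lines.append("")
    lines.append("@data")
    for inst in dataset.instances:
        cols = sorted(inst.signatures) + sorted(
            n_sig + dataset.label_space.index(lab) for lab in inst.labels
        )
        lines.append(_instance_comment(inst))
        lines.append("{" + ", ".join(f"{c} 1" for c in cols) + "}")
    _atomic_write_text(arff_path, "\n".join(lines) + "\n")

    _write_hierarchy_xml(dataset.label_space, xml_path)
    return arff_path, xml_path


MULAN_NS = "http://mulan.sourceforge.net/labels"


def _write_hierarchy_xml(space: LabelSpace, xml_path: Path) -> None:
    root = etree.Element("labels", nsmap={None: MULAN_NS})

    def attach(parent_el, label: ECLabel) -> None:
        el = etree.SubElement(parent_el, "label", name=label_attribute_name(label))
        for child in space.children(label):
            attach(el, child)

    for top in space.roots:
        attach(root, top)
    blob = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="utf-8"
    )
    _atomic_write_text(xml_path, blob.decode("utf-8"))


def _read_hierarchy_xml(xml_path: Path) -> List[ECLabel]:
    tree = etree.parse(str(xml_path))
    labels: List[ECLabel] = []

    def walk(el, parent: Optional[ECLabel]) -> None:
        for child in el:
            tag = etree.QName(child).localname
            if tag != "label":
                continue
            lab = parse_label_attribute_name(child.get("name"))
            if parent is not None and not parent.is_prefix_of(lab):
                raise ARFFParseError(
                    f"hierarchy violation: {lab} nested under {parent}"
                )
            labels.append(lab)
            walk(child, lab)

    walk(tree.getroot(), None)
    return labels


_ATTR_RE = re.compile(r"@attribute\s+(\S+)\s+\{\s*0\s*,\s*1\s*\}\s*$", re.IGNORECASE)
_ID_COMMENT_RE = re.compile(r"%\s*id=(.*)$")


def read_sparse_arff(
    source: os.PathLike, hierarchy_source: os.PathLike
) -> AnnotatedDataset:
    """Read an ARFF + XML pair back into an :class:`AnnotatedDataset`.

    Sparse and dense data rows are both accepted; indices out of bounds,
    non-binary values and hierarchy/label-column mismatches raise
    :class:`ARFFParseError` with the offending line number.
    """
    source = Path(source)
    hier_labels = _read_hierarchy_xml(Path(hierarchy_source))
    label_names = {label_attribute_name(l) for l in hier_labels}

    relation = "dataset"
    attr_names: List[str] = []
    data_start: Optional[int] = None
    raw_lines = source.read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(raw_lines, start=1):
        s = line.strip()
        if not s or s.startswith("%"):
            continue
        low = s.lower()
        if low.startswith("@relation"):
            relation = s.split(None, 1)[1] if len(s.split(None, 1)) > 1 else relation
        elif low.startswith("@attribute"):
            m = _ATTR_RE.match(s)
            if not m:
                raise ARFFParseError(
                    f"line {lineno}: only binary {{0,1}} attributes are supported: {s!r}"
                )
            attr_names.append(m.group(1))
        elif low.startswith("@data"):
            data_start = lineno
            break
        else:
            raise ARFFParseError(f"line {lineno}: unexpected header line {s!r}")
    if data_start is None:
        raise ARFFParseError("missing @data section")

    # label columns are the trailing attributes named in the hierarchy
    n_labels = len(hier_labels)
    if n_labels > len(attr_names):
        raise ARFFParseError(
            f"hierarchy lists {n_labels} labels but file has {len(attr_names)} attributes"
        )
    sig_names = attr_names[: len(attr_names) - n_labels]
    file_label_names = attr_names[len(attr_names) - n_labels :]
    if set(file_label_names) != label_names:
        raise ARFFParseError(
            "label columns do not match the hierarchy file "
            f"({sorted(set(file_label_names) ^ label_names)[:4]} ...)"
        )
    if any(name in label_names for name in sig_names):
        raise ARFFParseError("hierarchy label found among signature columns")
    label_space = LabelSpace(hier_labels)
    file_labels = [parse_label_attribute_name(n) for n in file_label_names]
    if tuple(file_labels) != label_space.labels:
        raise ARFFParseError(
            "label columns are not in canonical (numeric-lexicographic) order"
        )
    n_sig = len(sig_names)
    n_cols = len(attr_names)

    instances: List[Instance] = []
    pending_id: Optional[str] = None
    pending_groups: Dict[str, str] = {}
    counter = 0
    for lineno, line in enumerate(raw_lines[data_start:], start=data_start + 1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("%"):
            m = _ID_COMMENT_RE.match(s)
            if m:
                fields = m.group(1).split("\t")
                pending_id = fields[0].strip()
                pending_groups = {}
                for f in fields[1:]:
                    if "=" in f:
                        k, v = f.split("=", 1)
                        pending_groups[k.strip()] = v
            continue
        cols = _parse_data_row(s, lineno, n_cols)
        sig_idx = frozenset(c for c in cols if c < n_sig)
        labels = frozenset(file_labels[c - n_sig] for c in cols if c >= n_sig)
        inst_id = pending_id if pending_id is not None else f"instance_{counter}"
        instances.append(
            Instance(id=inst_id, signatures=sig_idx, labels=labels, groups=pending_groups)
        )
        pending_id, pending_groups = None, {}
        counter += 1

    ds = AnnotatedDataset(
        signature_vocabulary=tuple(sig_names),
        label_space=label_space,
        instances=tuple(instances),
        name=relation,
    )
    ds.validate()
    return ds


def _parse_data_row(s: str, lineno: int, n_cols: int) -> List[int]:
    if s.startswith("{"):
        if not s.endswith("}"):
            raise ARFFParseError(f"line {lineno}: unterminated sparse row")
        body = s[1:-1].strip()
        cols: List[int] = []
        if body:
            prev = -1
            for item in body.split(","):
                parts = item.split()
                if len(parts) != 2:
                    raise ARFFParseError(
                        f"line {lineno}: malformed sparse entry {item.strip()!r}"
                    )
                try:
                    idx = int(parts[0])
                except ValueError:
                    raise ARFFParseError(
                        f"line {lineno}: non-integer index {parts[0]!r}"
                    ) from None
                if parts[1] not in ("0", "1"):
                    raise ARFFParseError(
                        f"line {lineno}: non-binary value {parts[1]!r}"
                    )
                if not 0 <= idx < n_cols:
                    raise ARFFParseError(
                        f"line {lineno}: index {idx} out of bounds (0..{n_cols - 1})"
                    )
                if idx <= prev:
                    raise ARFFParseError(
                        f"line {lineno}: indices not strictly increasing at {idx}"
                    )
                prev = idx
                if parts[1] == "1":
                    cols.append(idx)
        return cols
    # dense row
    values = [v.strip() for v in s.split(",")]
    if len(values) != n_cols:
        raise ARFFParseError(
            f"line {lineno}: dense row has {len(values)} values, expected {n_cols}"
        )
    cols = []
    for idx, v in enumerate(values):
        if v not in ("0", "1"):
            raise ARFFParseError(f"line {lineno}: non-binary value {v!r}")
        if v == "1":
            cols.append(idx)
    return cols


def _read_pairs(path: os.PathLike, what: str) -> List[Tuple[str, str]]:
    pairs: List[Tuple[str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for rowno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) == 1:
                pairs.append((row[0].strip(), ""))
            elif len(row) == 2:
                pairs.append((row[0].strip(), row[1].strip()))
            else:
                raise TableParseError(
                    f"{what} row {rowno}: expected 2 fields, got {len(row)}"
                )
            if not pairs[-1][0]:
                raise TableParseError(f"{what} row {rowno}: empty protein id")
    return pairs


def read_annotation_tables(
    protein_ec_source: os.PathLike,
    protein_signature_source: os.PathLike,
    protein_group_source: Optional[os.PathLike] = None,
) -> Tuple[Dict[str, Set[str]], Dict[str, Set[str]], Dict[str, str]]:
    """Read (protein, EC), (protein, signature) and optional group tables.

    Empty EC values mark non-enzyme rows; duplicate identical rows are
    deduplicated; proteins present in only one table get empty entries in
    the others.  Returns ``(ec_map, signature_map, group_map)``.
    """
    ec_map: Dict[str, Set[str]] = {}
    for pid, value in _read_pairs(protein_ec_source, "EC table"):
        ec_map.setdefault(pid, set())
        if value:
            ec_map[pid].add(value)
    sig_map: Dict[str, Set[str]] = {}
    for pid, value in _read_pairs(protein_signature_source, "signature table"):
        sig_map.setdefault(pid, set())
        if value:
            sig_map[pid].add(value)
    group_map: Dict[str, str] = {}
    if protein_group_source is not None:
        for rowno, (pid, value) in enumerate(
            _read_pairs(protein_group_source, "group table"), start=1
        ):
            if pid in group_map and group_map[pid] != value:
                raise TableParseError(
                    f"group table row {rowno}: conflicting group for {pid!r}"
                )
            group_map[pid] = value
    # harmonise key sets
    everyone = set(ec_map) | set(sig_map) | set(group_map)
    for pid in everyone:
        ec_map.setdefault(pid, set())
        sig_map.setdefault(pid, set())
    return ec_map, sig_map, group_map


def read_status_table(path: os.PathLike) -> ECStatusTable:
    """Read an ENZYME-style status CSV: columns ``ec,status,replacements``."""
    entries: Dict[ECLabel, Tuple[str, List[ECLabel]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"ec", "status"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise TableParseError(
                f"status table must have header columns ec,status[,replacements]; got {reader.fieldnames}"
            )
        for rowno, row in enumerate(reader, start=2):
            try:
                label = parse_ec(row["ec"])
                reps = [
                    parse_ec(r)
                    for r in (row.get("replacements") or "").split(";")
                    if r.strip()
                ]
            except ValueError as exc:
                raise TableParseError(f"status table row {rowno}: {exc}") from exc
            entries[label] = (row["status"].strip(), reps)
    return ECStatusTable(entries)


def read_cluster_map(path: os.PathLike) -> Dict[str, str]:
    """Headerless two-column CSV ``member,representative``."""
    mapping: Dict[str, str] = {}
    for rowno, (member, rep) in enumerate(_read_pairs(path, "cluster map"), start=1):
        if not rep:
            raise TableParseError(f"cluster map row {rowno}: empty representative")
        if member in mapping and mapping[member] != rep:
            raise TableParseError(
                f"cluster map row {rowno}: conflicting representative for {member!r}"
            )
        mapping[member] = rep
    return mapping


def read_signature_ec_map(path: os.PathLike) -> Dict[str, FrozenSet[ECLabel]]:
    """Headerless two-column CSV ``signature,EC`` for transitive annotation."""
    raw: Dict[str, Set[ECLabel]] = {}
    for rowno, (sig, ec) in enumerate(_read_pairs(path, "signature-EC map"), start=1):
        if not ec:
            raise TableParseError(f"signature-EC map row {rowno}: empty EC")
        try:
            label = parse_ec(ec)
        except ValueError as exc:
            raise TableParseError(f"signature-EC map row {rowno}: {exc}") from exc
        raw.setdefault(sig, set()).add(label)
    return {sig: frozenset(labels) for sig, labels in raw.items()}


def write_predictions_csv(
    predictions: PredictionSet,
    path: os.PathLike,
    header_comment: Optional[str] = None,
) -> Path:
    """Export predictions: protein, semicolon-joined ECs, confidences.

    Columns: ``protein``, ``predicted_ecs`` (canonical strings, sorted),
    ``confidences`` (aligned, semicolon-joined), ``no_ec_confidence``.
    """
    path = Path(path)
    lines: List[str] = []
    if header_comment:
        for cl in header_comment.splitlines():
            lines.append(f"# {cl}")
    lines.append("protein,predicted_ecs,confidences,no_ec_confidence")
    ids = predictions.ids or tuple(
        f"instance_{i}" for i in range(len(predictions))
    )
    for pid, labels, confs, no_ec in zip(
        ids, predictions.labels, predictions.confidences, predictions.no_ec_confidence
    ):
        ordered = sorted(labels)
        ecs = ";".join(str(l) for l in ordered)
        cvals = ";".join(f"{confs[l]:.4f}" for l in ordered)
        lines.append(f"{pid},{ecs},{cvals},{no_ec:.4f}")
    _atomic_write_text(path, "\n".join(lines) + "\n")
    return path
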