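"""Synthetic annotation databases with curated-corpus statistics.

Real EC annotation corpora have a handful of structural features that
drive classifier behaviour: enzymatic classes are long-tail (Zipf)
distributed; each class is represented by a small number of recurring
unordered signature combinations (a class with a thousand member
proteins may exhibit only three combinations); a large minority of
proteins are non-enzymes whose signatures come from families unrelated
to catalysis; a few proteins have no signatures at all; some carry
multiple EC numbers (bifunctional enzymes, whose class *pairs* recur
across species); and some are annotated only to partial depth
(``1.2.-.-``), behaving as leaf classes of their own.  The generator
reproduces exactly these features so every pipeline stage is testable
without downloading UniProt/KEGG/InterPro; what it does *not* model is
documented in the methods note.

All randomness flows from a single mandatory seed through named
substreams, so individual stages can be regenerated independently and a
fixed configuration is byte-reproducible down to the ARFF export.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .dataset import AnnotatedDataset, Instance
from .ec import ECLabel, LabelSpace, expand_label_set

__all__ = [
    "GeneratorConfig",
    "corrupt_labels",
    "export_annotation_tables",
    "generate_dataset",
    "generate_label_space",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic annotation database.

    Defaults mirror a curated-corpus profile scaled to desk size: 5,000
    proteins over 200 leaf EC classes with Zipf-1 class frequencies, 45%
    non-enzymes, a mean of ~3.55 signatures per protein, ~0.3% of the
    corpus with empty signature vectors, 5% multi-EC and 9% partial-label
    enzymes.  ``noise_rate`` is the per-signature corruption probability
    (0 = clean combinations).  The seed is mandatory.
    """

    seed: int
    n_proteins: int = 5000
    n_signatures: int = 1200
    n_leaf_classes: int = 200
    zipf_exponent: float = 1.0
    combos_per_class: Tuple[int, int] = (1, 3)
    combo_length_mean: float = 3.55
    combo_length_max: int = 12
    non_enzyme_fraction: float = 0.45
    empty_vector_fraction: float = 0.007
    multi_ec_fraction: float = 0.05
    partial_label_fraction: float = 0.09
    noise_rate: float = 0.0
    n_species: int = 8
    background_pool_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "non_enzyme_fraction",
            "empty_vector_fraction",
            "multi_ec_fraction",
            "partial_label_fraction",
            "noise_rate",
            "background_pool_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.multi_ec_fraction + self.partial_label_fraction > 1.0:
            raise ValueError("multi_ec_fraction + partial_label_fraction exceed 1")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.n_proteins < 1 or self.n_signatures < 2 or self.n_leaf_classes < 1:
            raise ValueError("n_proteins, n_signatures, n_leaf_classes must be positive")
        lo, hi = self.combos_per_class
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid combos_per_class range {self.combos_per_class}")
        if self.combo_length_mean < 1 or self.combo_length_max < 1:
            raise ValueError("combo lengths must be >= 1")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    """Named substream: independent, reproducible per (seed, stage)."""
    return np.random.default_rng([config.seed, zlib.crc32(stream.encode())])


def generate_label_space(
    config: GeneratorConfig,
) -> Tuple[LabelSpace, Dict[ECLabel, float]]:
    """Leaf 4-digit classes under shared prefixes, with Zipf weights.

    Classes are grouped into 3-digit families of one to four leaves so
    the hierarchy has realistically shared internal nodes; frequency
    weights are proportional to ``rank ** -zipf_exponent`` with ranks
    assigned to leaves in a seeded random permutation.
    """
    rng = _rng(config, "labels")
    leaves: List[ECLabel] = []
    seen_families: Set[Tuple[int, int, int]] = set()
    while len(leaves) < config.n_leaf_classes:
        family = (
            int(rng.integers(1, 7)),
            int(rng.integers(1, 25)),
            int(rng.integers(1, 25)),
        )
        if family in seen_families:
            continue
        seen_families.add(family)
        size = min(int(rng.integers(1, 5)), config.n_leaf_classes - len(leaves))
        for serial in range(1, size + 1):
            leaves.append(ECLabel(family + (serial,)))
    leaves = sorted(leaves)
    ranks = rng.permutation(len(leaves)) + 1
    raw = ranks.astype(float) ** (-config.zipf_exponent)
    weights = raw / raw.sum()
    return LabelSpace(leaves), {leaf: float(w) for leaf, w in zip(leaves, weights)}


def _draw_length(rng: np.random.Generator, config: GeneratorConfig) -> int:
    # shifted Poisson: 1 + Poisson(mean - 1), capped
    lam = max(config.combo_length_mean - 1.0, 0.0)
    return min(1 + int(rng.poisson(lam)), config.combo_length_max)


def _new_combo(
    rng: np.random.Generator,
    config: GeneratorConfig,
    core: Sequence[int],
    pool: np.ndarray,
    taken: Set[FrozenSet[int]],
) -> FrozenSet[int]:
    """Draw a signature combination distinct from all existing ones.

    The combination starts from the family core and is padded with
    class-specific signatures; on collision with an existing combination
    it is redrawn (deterministic bounded retry).
    """
    for _ in range(200):
        length = _draw_length(rng, config)
        members: Set[int] = set(core[: min(len(core), length)])
        while len(members) < length:
            members.add(int(pool[rng.integers(len(pool))]))
        combo = frozenset(members)
        if combo not in taken:
            taken.add(combo)
            return combo
    raise RuntimeError(
        "could not draw a distinct signature combination; "
        "increase n_signatures or combo length"
    )


def generate_dataset(
    config: GeneratorConfig,
) -> Tuple[AnnotatedDataset, pd.DataFrame]:
    """Generate the annotated dataset plus per-protein ground truth.

    Each leaf class owns a small set of distinct signature combinations
    (capped by the class's expected support: a rare class cannot exhibit
    more combinations than proteins); partial-label classes and
    recurring multi-EC class pairs own dedicated combinations of their
    own.  Enzyme proteins draw a class by weight and one of its
    combinations uniformly; non-enzymes draw from a disjoint background
    signature pool or carry an empty vector.  With ``noise_rate`` > 0,
    each present signature is dropped with that probability and a
    binomial number of spurious signatures is added.  Labels are stored
    hierarchically expanded.  Fully reproducible from the seed.
    """
    space, weights = generate_label_space(config)
    leaves = sorted(weights)
    weight_arr = np.array([weights[l] for l in leaves])

    n_background = max(1, int(config.n_signatures * config.background_pool_fraction))
    n_enzyme_pool = config.n_signatures - n_background
    if n_enzyme_pool < 2:
        raise ValueError("signature vocabulary too small for the background split")
    enzyme_pool = np.arange(n_enzyme_pool)
    background_pool = np.arange(n_enzyme_pool, config.n_signatures)

    combo_rng = _rng(config, "combos")
    taken: Set[FrozenSet[int]] = set()

    # shared family cores create realistic near-neighbour confusability
    cores: Dict[Tuple[int, int, int], List[int]] = {}
    for leaf in leaves:
        fam = leaf.digits[:3]
        if fam not in cores:
            n_core = int(combo_rng.integers(1, 3))
            cores[fam] = [
                int(enzyme_pool[combo_rng.integers(len(enzyme_pool))])
                for _ in range(n_core)
            ]

    n_enzymes = config.n_proteins - round(config.non_enzyme_fraction * config.n_proteins)
    lo, hi = config.combos_per_class
    class_combos: Dict[ECLabel, List[FrozenSet[int]]] = {}
    for leaf, w in zip(leaves, weight_arr):
        expected = max(1, int(n_enzymes * w))
        n_c = min(int(combo_rng.integers(lo, hi + 1)), expected)
        class_combos[leaf] = [
            _new_combo(combo_rng, config, cores[leaf.digits[:3]], enzyme_pool, taken)
            for _ in range(n_c)
        ]

    # dedicated combinations for partial-depth classes
    partial_labels = sorted(
        {ECLabel(leaf.digits[:d]) for leaf in leaves for d in (1, 2, 3)}
    )
    partial_combos: Dict[ECLabel, FrozenSet[int]] = {}
    for lab in partial_labels:
        fam = lab.digits[:3] if lab.depth == 3 else ()
        core = cores.get(fam, [])
        partial_combos[lab] = _new_combo(combo_rng, config, core, enzyme_pool, taken)

    # recurring multi-EC class pairs (bifunctional-enzyme families)
    pair_rng = _rng(config, "pairs")
    n_pairs = max(1, config.n_leaf_classes // 10)
    pairs: List[Tuple[ECLabel, ECLabel]] = []
    pair_combos: List[FrozenSet[int]] = []
    seen_pairs: Set[Tuple[ECLabel, ECLabel]] = set()
    attempts = 0
    while len(leaves) >= 2 and len(pairs) < n_pairs and attempts < 50 * n_pairs:
        attempts += 1
        i, j = pair_rng.choice(len(leaves), size=2, replace=False, p=weight_arr)
        key = tuple(sorted((leaves[int(i)], leaves[int(j)])))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        union = frozenset(class_combos[key[0]][0] | class_combos[key[1]][0])
        if union in taken:
            continue
        taken.add(union)
        pairs.append(key)
        pair_combos.append(union)
    if not pairs:  # degenerate configs (a single class)
        pairs = [(leaves[0], leaves[0])]
        pair_combos = [class_combos[leaves[0]][0]]

    species_names = tuple(f"species_{i + 1:02d}" for i in range(config.n_species))
    species_w = 1.0 / np.arange(1, config.n_species + 1)
    species_w /= species_w.sum()

    prot_rng = _rng(config, "proteins")
    n = config.n_proteins
    n_non = round(config.non_enzyme_fraction * n)
    roles = np.array([0] * n_non + [1] * (n - n_non))
    prot_rng.shuffle(roles)

    instances: List[Instance] = []
    records: List[Dict[str, object]] = []
    for i in range(n):
        pid = f"P{i + 1:06d}"
        species = species_names[int(prot_rng.choice(config.n_species, p=species_w))]
        if roles[i] == 0:
            kind = "non_enzyme"
            raw_labels: Tuple[ECLabel, ...] = ()
            if prot_rng.random() < config.empty_vector_fraction:
                vector: FrozenSet[int] = frozenset()
            else:
                length = _draw_length(prot_rng, config)
                members: Set[int] = set()
                while len(members) < length:
                    members.add(int(background_pool[prot_rng.integers(n_background)]))
                vector = frozenset(members)
        else:
            u = prot_rng.random()
            if u < config.multi_ec_fraction:
                kind = "multi"
                p_idx = int(prot_rng.integers(len(pairs)))
                raw_labels = pairs[p_idx]
                vector = pair_combos[p_idx]
            elif u < config.multi_ec_fraction + config.partial_label_fraction:
                kind = "partial"
                leaf = leaves[int(prot_rng.choice(len(leaves), p=weight_arr))]
                depth = int(prot_rng.integers(1, 4))
                lab = ECLabel(leaf.digits[:depth])
                raw_labels = (lab,)
                vector = partial_combos[lab]
            else:
                kind = "single"
                leaf = leaves[int(prot_rng.choice(len(leaves), p=weight_arr))]
                combos = class_combos[leaf]
                raw_labels = (leaf,)
                vector = combos[int(prot_rng.integers(len(combos)))]
        original_len = len(vector)
        if config.noise_rate > 0 and original_len:
            kept = {
                s for s in sorted(vector) if prot_rng.random() >= config.noise_rate
            }
            n_add = int(prot_rng.binomial(original_len, config.noise_rate))
            while n_add > 0:
                cand = int(prot_rng.integers(config.n_signatures))
                if cand not in kept:
                    kept.add(cand)
                    n_add -= 1
            vector = frozenset(kept)
        instances.append(
            Instance(
                id=pid,
                signatures=vector,
                labels=expand_label_set(raw_labels),
                groups={"species": species},
            )
        )
        records.append(
            {
                "protein": pid,
                "species": species,
                "kind": kind,
                "raw_labels": ";".join(str(l) for l in sorted(raw_labels)),
                "n_signatures": len(vector),
            }
        )

    vocabulary = tuple(f"IPR{i + 1:06d}" for i in range(config.n_signatures))
    dataset = AnnotatedDataset(
        signature_vocabulary=vocabulary,
        label_space=space,
        instances=tuple(instances),
        name=f"synthetic_seed{config.seed}",
    )
    dataset.validate()
    return dataset, pd.DataFrame(records)


def corrupt_labels(
    dataset: AnnotatedDataset, flip_fraction: float, seed: int
) -> AnnotatedDataset:
    """Reassign a random fraction of instances to a *different* label set.

    Replacement sets are drawn from the distinct exact label sets present
    in the dataset (the empty set included), so the label space is
    unchanged; reproducible from the seed.  Emulates disagreeing or
    erroneous curation.
    """
    if not 0.0 <= flip_fraction <= 1.0:
        raise ValueError("flip_fraction must be in [0, 1]")
    if flip_fraction == 0.0:
        return dataset
    pool = sorted(
        {inst.labels for inst in dataset.instances},
        key=lambda s: tuple(sorted(lab.digits for lab in s)),
    )
    if len(pool) < 2:
        raise ValueError("need at least two distinct label sets to corrupt")
    rng = np.random.default_rng(seed)
    n_flip = round(flip_fraction * len(dataset))
    flip_idx = set(
        rng.choice(len(dataset), size=n_flip, replace=False).tolist()
    )
    new_instances: List[Instance] = []
    for i, inst in enumerate(dataset.instances):
        if i not in flip_idx:
            new_instances.append(inst)
            continue
        alternatives = [s for s in pool if s != inst.labels]
        chosen = alternatives[int(rng.integers(len(alternatives)))]
        new_instances.append(replace(inst, labels=chosen))
    return AnnotatedDataset(
        signature_vocabulary=dataset.signature_vocabulary,
        label_space=dataset.label_space,
        instances=tuple(new_instances),
        name=f"{dataset.name}:flip{flip_fraction:g}",
    )


def export_annotation_tables(
    dataset: AnnotatedDataset,
    records: pd.DataFrame,
    directory,
) -> Dict[str, str]:
    """Write the delimited annotation tables plus the ground-truth CSV.

    Emits ``protein_ec.csv`` (raw, unexpanded labels; non-enzymes get one
    row with an empty EC), ``protein_signature.csv``,
    ``protein_species.csv`` and ``ground_truth.csv`` into *directory*;
    returns the path of each file by table name.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    raw_by_protein = dict(zip(records["protein"], records["raw_labels"]))

    ec_lines: List[str] = []
    sig_lines: List[str] = []
    species_lines: List[str] = []
    for inst in dataset.instances:
        raw = raw_by_protein.get(inst.id, "")
        if raw:
            for lab in raw.split(";"):
                ec_lines.append(f"{inst.id},{lab}")
        else:
            ec_lines.append(f"{inst.id},")
        for si in sorted(inst.signatures):
            sig_lines.append(f"{inst.id},{dataset.signature_vocabulary[si]}")
        if not inst.signatures:
            sig_lines.append(f"{inst.id},")
        if "species" in inst.groups:
            species_lines.append(f"{inst.id},{inst.groups['species']}")

    paths = {
        "protein_ec": directory / "protein_ec.csv",
        "protein_signature": directory / "protein_signature.csv",
        "protein_species": directory / "protein_species.csv",
        "ground_truth": directory / "ground_truth.csv",
    }
    paths["protein_ec"].write_text("\n".join(ec_lines) + "\n", encoding="utf-8")
    paths["protein_signature"].write_text("\n".join(sig_lines) + "\n", encoding="utf-8")
    paths["protein_species"].write_text(
        "\n".join(species_lines) + "\n", encoding="utf-8"
    )
    records.to_csv(paths["ground_truth"], index=False)
    return {k: str(v) for k, v in paths.items()}
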