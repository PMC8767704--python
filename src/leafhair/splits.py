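"""Leaf-group-exclusive dataset splitting.

The atomic splitting unit is the leaf group: all images of a physical leaf
land on the same side of any split. The grammar covers the whole-dataset
80/20 split; mixed, intra and inter splits over leaf number, year and
environment; the inter-year candidate-list reduction to genotypes and score
classes present in both years; and repeated validation/train resampling of a
parent split's training side.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass
from typing import Iterable, Sequence

from .manifest import ImageRecord, Manifest

__all__ = [
    "DatasetSplit",
    "FoldPair",
    "group_by_leaf",
    "make_split",
    "make_whole_split",
    "make_factor_splits",
    "kfold_pairs",
    "split_report",
    "save_split",
    "load_split",
]

FACTORS = ("leaf_number", "year", "environment")

_FACTOR_CATEGORIES = {
    "leaf_number": ((3, "L3"), (4, "L4")),
    "year": (("Y1", "Y1"), ("Y2", "Y2")),
    "environment": (("GH", "GH"), ("FD", "FD")),
}


@dataclass(frozen=True)
class DatasetSplit:
    """Named train/test partition of image ids, exclusive at the leaf level."""

    name: str
    train_ids: frozenset[str]
    test_ids: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.train_ids & self.test_ids:
            raise ValueError(f"split {self.name}: train and test ids overlap")


@dataclass(frozen=True)
class FoldPair:
    fold_index: int
    validation_ids: frozenset[str]
    fold_train_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.validation_ids & self.fold_train_ids:
            raise ValueError(f"fold {self.fold_index}: validation and train ids overlap")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def group_by_leaf(manifest: Manifest, candidate_ids: Iterable[str]) -> list[list[str]]:
    """Partition candidate image ids into leaf groups, ordered by leaf_id."""
    wanted = set(candidate_ids)
    unknown = wanted - set(manifest.image_ids)
    if unknown:
        raise ValueError(f"candidate ids not in manifest: {sorted(unknown)[:5]}...")
    groups: dict[str, list[str]] = {}
    for r in manifest.records:
        if r.image_id in wanted:
            groups.setdefault(r.leaf_id, []).append(r.image_id)
    return [groups[leaf_id] for leaf_id in sorted(groups)]


def _select_test_groups(
    groups: list[list[str]], test_fraction: float, seed: int
) -> tuple[set[str], set[str]]:
    """Seeded selection over leaf groups (sorted, then shuffled) -> (train, test) ids."""
    order = list(range(len(groups)))
    random.Random(seed).shuffle(order)
    n_test = _round_half_up(test_fraction * len(groups))
    test_idx = set(order[:n_test])
    train_ids: set[str] = set()
    test_ids: set[str] = set()
    for i, g in enumerate(groups):
        (test_ids if i in test_idx else train_ids).update(g)
    return train_ids, test_ids


def make_split(
    manifest: Manifest,
    candidate_ids: Iterable[str],
    test_fraction: float,
    seed: int,
    extra_train_ids: Iterable[str] = (),
    name: str = "whole",
) -> DatasetSplit:
    """80/20-style split: round(test_fraction x L) leaf groups go to test.

    ``extra_train_ids`` (e.g. all images of the non-test category in a mixed
    split) are added to the training side and must not share a leaf with any
    candidate.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    candidate_ids = set(candidate_ids)
    extra_train_ids = set(extra_train_ids)
    by_id = manifest.by_image_id()
    cand_leaves = {by_id[i].leaf_id for i in candidate_ids}
    extra_leaves = {by_id[i].leaf_id for i in extra_train_ids}
    if cand_leaves & extra_leaves:
        raise ValueError("extra_train_ids share leaf groups with candidate ids")
    groups = group_by_leaf(manifest, candidate_ids)
    if len(groups) < 2:
        raise ValueError(f"need at least 2 leaf groups to split, got {len(groups)}")
    train_ids, test_ids = _select_test_groups(groups, test_fraction, seed)
    return DatasetSplit(
        name=name,
        train_ids=frozenset(train_ids | extra_train_ids),
        test_ids=frozenset(test_ids),
        seed=seed,
    )


def make_whole_split(manifest: Manifest, test_fraction: float = 0.2, seed: int = 0) -> DatasetSplit:
    return make_split(manifest, manifest.image_ids, test_fraction, seed, name="whole")


def _reduce_inter_year(manifest: Manifest) -> set[str]:
    """Candidate ids for inter-year splits: genotypes present in both years,
    then score classes present in both reduced year subsets."""
    years: dict[str, set[str]] = {"Y1": set(), "Y2": set()}
    for r in manifest.records:
        years[r.year].add(r.genotype)
    common_genotypes = years["Y1"] & years["Y2"]
    reduced = [r for r in manifest.records if r.genotype in common_genotypes]
    classes: dict[str, set[str]] = {"Y1": set(), "Y2": set()}
    for r in reduced:
        classes[r.year].add(r.score.label)
    common_classes = classes["Y1"] & classes["Y2"]
    return {r.image_id for r in reduced if r.score.label in common_classes}


def make_factor_splits(
    manifest: Manifest, factor: str, seed: int = 0, test_fraction: float = 0.2
) -> list[DatasetSplit]:
    """The six splits for one factor: mixed (AB/A, AB/B), intra (A/A, B/B),
    inter (A/B, B/A).

    Inter splits put all of one category in train and all of the other in
    test; for factor="year" the inter candidate list is first reduced to
    genotypes and score classes present in both years.
    """
    if factor not in _FACTOR_CATEGORIES:
        raise ValueError(f"factor must be one of {FACTORS}, got {factor!r}")
    cats = _FACTOR_CATEGORIES[factor]
    ids_by_cat: dict[str, set[str]] = {label: set() for _, label in cats}
    for r in manifest.records:
        value = getattr(r, factor)
        for v, label in cats:
            if value == v:
                ids_by_cat[label].add(r.image_id)
    for _, label in cats:
        if not ids_by_cat[label]:
            raise ValueError(f"factor category {label} absent from manifest")
    (la, ids_a), (lb, ids_b) = [(label, ids_by_cat[label]) for _, label in cats]
    mixed_name = f"{la}{lb}"

    splits = [
        # mixed: test drawn from one category, everything else trains
        make_split(manifest, ids_a, test_fraction, seed, extra_train_ids=ids_b,
                   name=f"{mixed_name}/{la}"),
        make_split(manifest, ids_b, test_fraction, seed, extra_train_ids=ids_a,
                   name=f"{mixed_name}/{lb}"),
        # intra: candidates restricted to one category
        make_split(manifest, ids_a, test_fraction, seed, name=f"{la}/{la}"),
        make_split(manifest, ids_b, test_fraction, seed, name=f"{lb}/{lb}"),
    ]

    if factor == "year":
        reduced = _reduce_inter_year(manifest)
        inter_a, inter_b = ids_a & reduced, ids_b & reduced
    else:
        inter_a, inter_b = ids_a, ids_b
    splits.append(DatasetSplit(f"{la}/{lb}", frozenset(inter_a), frozenset(inter_b), seed))
    splits.append(DatasetSplit(f"{lb}/{la}", frozenset(inter_b), frozenset(inter_a), seed))
    return splits


def kfold_pairs(
    manifest: Manifest,
    parent_split: DatasetSplit,
    k: int,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> list[FoldPair]:
    """k independent seeded resamplings (not a partition) of the parent train
    leaf groups into validation/train pairs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie strictly between 0 and 1")
    groups = group_by_leaf(manifest, parent_split.train_ids)
    if len(groups) < 2:
        raise ValueError("parent training set must contain at least 2 leaf groups")
    pairs = []
    for fold in range(1, k + 1):
        train_ids, val_ids = _select_test_groups(groups, val_fraction, seed + fold)
        pairs.append(FoldPair(fold, frozenset(val_ids), frozenset(train_ids)))
    return pairs


def split_report(split: DatasetSplit, manifest: Manifest) -> dict:
    """Bookkeeping summary of a split: sizes, leaf counts, per-class/year/env
    coverage, exclusivity check and error flags."""
    by_id = manifest.by_image_id()

    def _summarize(ids: frozenset[str]) -> dict:
        recs = [by_id[i] for i in ids]
        classes: dict[str, int] = {}
        years: dict[str, int] = {}
        envs: dict[str, int] = {}
        leaves = set()
        for r in recs:
            classes[r.score.label] = classes.get(r.score.label, 0) + 1
            years[r.year] = years.get(r.year, 0) + 1
            envs[r.environment] = envs.get(r.environment, 0) + 1
            leaves.add(r.leaf_id)
        return {
            "n_images": len(recs),
            "n_leaves": len(leaves),
            "per_class": dict(sorted(classes.items())),
            "per_year": dict(sorted(years.items())),
            "per_environment": dict(sorted(envs.items())),
            "leaves": leaves,
        }

    train = _summarize(split.train_ids)
    test = _summarize(split.test_ids)
    leaf_overlap = train.pop("leaves") & test.pop("leaves")
    total = len(split.train_ids) + len(split.test_ids)
    return {
        "name": split.name,
        "seed": split.seed,
        "train": train,
        "test": test,
        "total_images": total,
        "train_fraction": len(split.train_ids) / total if total else 0.0,
        "leaf_exclusive": not leaf_overlap,
        "class_sets_equal": set(train["per_class"]) == set(test["per_class"]),
        "n_common_classes": len(set(train["per_class"]) & set(test["per_class"])),
        "errors": ([] if split.test_ids else ["empty test set"])
        + ([] if not leaf_overlap else [f"leaf overlap: {sorted(leaf_overlap)[:3]}"]),
    }


def save_split(split: DatasetSplit, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "name": split.name,
                "seed": split.seed,
                "train_ids": sorted(split.train_ids),
                "test_ids": sorted(split.test_ids),
            },
            fh,
            indent=1,
        )


def load_split(path: str) -> DatasetSplit:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return DatasetSplit(d["name"], frozenset(d["train_ids"]), frozenset(d["test_ids"]), d["seed"])
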