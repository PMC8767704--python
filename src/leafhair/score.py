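"""Accuracy metrics: per-image, per-first-image and per-leaf scoring.

Image Accuracy (IA) is plain agreement between predicted and true classes.
First Image Accuracy (FIA) restricts IA to the most proximal image of each
leaf. Leaf Accuracy (LA) assigns each leaf the modal predicted class over its
test-side images, breaking ties toward the smallest score on the scale, and
compares it to the leaf's true class. Normalized (per-true-class) confusion
matrices and adjacent-class error fractions complete the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .manifest import Manifest, SCORE_LABELS, ScoreClass

__all__ = [
    "PredictionSet",
    "AccuracyReport",
    "image_accuracy",
    "first_image_accuracy",
    "leaf_accuracy",
    "normalized_confusion",
    "adjacent_error_analysis",
    "build_report",
    "noise_robustness_sweep",
]


@dataclass(frozen=True)
class PredictionSet:
    """Aligned (image_id, true, predicted) triples from one evaluation."""

    entries: tuple[tuple[str, ScoreClass, ScoreClass], ...]
    split_name: str = ""

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate image_ids in PredictionSet")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class AccuracyReport:
    IA: float
    FIA: float
    LA: float
    confusion_IA: dict
    confusion_FIA: dict
    confusion_LA: dict
    misprediction_fraction: float
    adjacent_error_fraction: float
    off_by_more_fraction: float
    leaf_scores: dict[str, str]
    warnings: tuple[str, ...] = ()

    def to_json(self, path: str) -> None:
        payload = {k: v for k, v in self.__dict__.items()}
        payload["warnings"] = list(self.warnings)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def image_accuracy(preds: PredictionSet) -> float:
    """Fraction of entries whose predicted class equals the true class."""
    if not preds.entries:
        raise ValueError("empty prediction set")
    correct = sum(1 for _, t, p in preds.entries if t == p)
    return correct / len(preds.entries)


def _first_entries(preds: PredictionSet, manifest: Manifest) -> list[tuple[str, ScoreClass, ScoreClass]]:
    by_id = manifest.by_image_id()
    leaves_seen: dict[str, int] = {}
    firsts = []
    for entry in preds.entries:
        rec = by_id[entry[0]]
        leaves_seen.setdefault(rec.leaf_id, 0)
        if rec.is_first:
            leaves_seen[rec.leaf_id] += 1
            firsts.append(entry)
    bad = [leaf for leaf, n in leaves_seen.items() if n != 1]
    if bad:
        raise ValueError(
            f"leaves without exactly one is_first entry in the prediction set: {sorted(bad)[:5]}"
        )
    return firsts


def first_image_accuracy(preds: PredictionSet, manifest: Manifest) -> float:
    """IA restricted to is_first images; denominator = number of test leaves."""
    firsts = _first_entries(preds, manifest)
    if not firsts:
        raise ValueError("no first-image entries in prediction set")
    return sum(1 for _, t, p in firsts if t == p) / len(firsts)


def assign_leaf_score(predictions: Sequence[ScoreClass]) -> ScoreClass:
    """Modal predicted class; ties broken toward the smallest rank among the
    tied classes."""
    if not predictions:
        raise ValueError("empty leaf group")
    counts: dict[int, int] = {}
    for p in predictions:
        counts[p.rank] = counts.get(p.rank, 0) + 1
    best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ScoreClass.from_rank(best[0])


def leaf_accuracy(preds: PredictionSet, manifest: Manifest) -> tuple[float, dict[str, ScoreClass]]:
    """LA plus the per-leaf assigned scores, over test-side images only."""
    if not preds.entries:
        raise ValueError("empty prediction set")
    by_id = manifest.by_image_id()
    per_leaf_preds: dict[str, list[ScoreClass]] = {}
    per_leaf_truth: dict[str, ScoreClass] = {}
    for image_id, true, predicted in preds.entries:
        leaf_id = by_id[image_id].leaf_id
        per_leaf_preds.setdefault(leaf_id, []).append(predicted)
        per_leaf_truth[leaf_id] = true
    assigned = {leaf: assign_leaf_score(ps) for leaf, ps in per_leaf_preds.items()}
    correct = sum(1 for leaf, score in assigned.items() if score == per_leaf_truth[leaf])
    return correct / len(assigned), assigned


def normalized_confusion(
    pairs: Sequence[tuple[ScoreClass, ScoreClass]],
) -> dict:
    """Row-normalized confusion matrix over the full scale.

    Rows index true classes, columns predicted; present-class rows sum to 1,
    absent-class rows are all-zero and listed under ``absent_classes``.
    """
    n = len(SCORE_LABELS)
    counts = np.zeros((n, n), dtype=float)
    for true, pred in pairs:
        counts[true.rank, pred.rank] += 1
    row_sums = counts.sum(axis=1)
    matrix = np.divide(
        counts, row_sums[:, None], out=np.zeros_like(counts), where=row_sums[:, None] > 0
    )
    return {
        "labels": list(SCORE_LABELS),
        "matrix": matrix.tolist(),
        "row_counts": row_sums.astype(int).tolist(),
        "absent_classes": [SCORE_LABELS[i] for i in range(n) if row_sums[i] == 0],
    }


def adjacent_error_analysis(preds: PredictionSet) -> tuple[float, float, float]:
    """(misprediction, within-one-class, beyond-one-class) fractions over all
    entries; the first equals the sum of the other two."""
    if not preds.entries:
        raise ValueError("empty prediction set")
    n = len(preds.entries)
    wrong = within = beyond = 0
    for _, t, p in preds.entries:
        d = abs(t.rank - p.rank)
        if d == 0:
            continue
        wrong += 1
        if d == 1:
            within += 1
        else:
            beyond += 1
    return wrong / n, within / n, beyond / n


def build_report(preds: PredictionSet, manifest: Manifest, warnings: Sequence[str] = ()) -> AccuracyReport:
    """Full accuracy report: IA/FIA/LA, confusion matrices, adjacency analysis."""
    ia = image_accuracy(preds)
    fia = first_image_accuracy(preds, manifest)
    la, assigned = leaf_accuracy(preds, manifest)
    by_id = manifest.by_image_id()
    leaf_truth = {by_id[i].leaf_id: t for i, t, _ in preds.entries}
    mispred, within, beyond = adjacent_error_analysis(preds)
    return AccuracyReport(
        IA=ia,
        FIA=fia,
        LA=la,
        confusion_IA=normalized_confusion([(t, p) for _, t, p in preds.entries]),
        confusion_FIA=normalized_confusion(
            [(t, p) for _, t, p in _first_entries(preds, manifest)]
        ),
        confusion_LA=normalized_confusion(
            [(leaf_truth[leaf], score) for leaf, score in assigned.items()]
        ),
        misprediction_fraction=mispred,
        adjacent_error_fraction=within,
        off_by_more_fraction=beyond,
        leaf_scores={leaf: s.label for leaf, s in sorted(assigned.items())},
        warnings=tuple(warnings),
    )


def noise_robustness_sweep(
    extractor,
    head,
    manifest: Manifest,
    test_ids: Sequence[str],
    images: dict[str, np.ndarray],
    sigmas: Sequence[float],
    probabilities: Sequence[float],
    aug_config=None,
    classes: Sequence[ScoreClass] | None = None,
    seed: int = 0,
    batch_size: int = 32,
) -> list[dict]:
    """Evaluate IA/FIA/LA under test-time Gaussian noise for each (sigma, p).

    Noise is injected before resize/normalize; rows with sigma=0 or p=0 are
    exactly the clean evaluation (the noise op is then the identity).
    """
    from .augment import AugmentationConfig, evaluation_transform, gaussian_noise
    from .net import forward as net_forward

    aug_config = aug_config or AugmentationConfig()
    transform = evaluation_transform(aug_config)
    by_id = manifest.by_image_id()
    ordered_ids = [i for i in sorted(test_ids)]
    if classes is None:
        classes = [ScoreClass.from_rank(r) for r in range(len(SCORE_LABELS))]
    rows = []
    for sigma in sigmas:
        for p in probabilities:
            rng = np.random.default_rng((seed, int(sigma * 1000), int(p * 1000)))
            entries = []
            for start in range(0, len(ordered_ids), batch_size):
                chunk = ordered_ids[start : start + batch_size]
                batch = np.stack(
                    [
                        transform(gaussian_noise(images[i], sigma, p, rng))
                        for i in chunk
                    ]
                )
                scores = net_forward(extractor, head, batch, training=False)
                for i, image_id in enumerate(chunk):
                    pred = classes[int(np.argmax(scores[i]))]
                    entries.append((image_id, by_id[image_id].score, pred))
            preds = PredictionSet(tuple(entries), split_name=f"noise s={sigma} p={p}")
            la, _ = leaf_accuracy(preds, manifest)
            rows.append(
                {
                    "sigma": sigma,
                    "p": p,
                    "IA": image_accuracy(preds),
                    "FIA": first_image_accuracy(preds, manifest),
                    "LA": la,
                }
            )
    return rows
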