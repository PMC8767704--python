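"""Training: cross-entropy minimization of the backbone + scoring head on the
train side of a leaf-exclusive split, and multi-run experiments.

The class vocabulary is inferred from the classes present in the training
images; test-only classes are recorded as warnings (predictions remain
restricted to the train vocabulary). Per-run seeds derive from the base seed
(base + run index) so the min/mean/max bands of an experiment are
reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from PIL import Image

from .augment import AugmentationConfig, Transform, compose, evaluation_transform
from .manifest import Manifest, ScoreClass
from .net import NetworkConfig, build_classifier, build_feature_extractor, forward
from .nn import make_optimizer, OPTIMIZERS
from .score import AccuracyReport, PredictionSet, build_report
from .splits import DatasetSplit

__all__ = [
    "TrainConfig",
    "RunResult",
    "load_images",
    "train_model",
    "evaluate_model",
    "run_experiment",
]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "Adam"
    learning_rate: float = 1e-4
    epochs: int = 30
    batch_size: int = 32
    n_runs: int = 5
    seed: int = 0
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {self.optimizer!r}; choose from {sorted(OPTIMIZERS)}"
            )
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.n_runs < 1 or self.batch_size < 1:
            raise ValueError("epochs, batch_size and n_runs must be >= 1")


@dataclass
class RunResult:
    run_index: int
    seed: int
    loss_trace: list[float]
    report: AccuracyReport
    extractor: object
    head: object
    classes: tuple[ScoreClass, ...]


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(probs[np.arange(n), targets] + 1e-12).mean())
    grad = probs
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n


def load_images(manifest: Manifest, root: str, ids: Sequence[str] | None = None) -> dict[str, np.ndarray]:
    """Decode images into an id -> (H, W, 3) uint8 cache."""
    wanted = set(ids) if ids is not None else None
    out: dict[str, np.ndarray] = {}
    for r in manifest.records:
        if wanted is not None and r.image_id not in wanted:
            continue
        path = os.path.join(root, r.image_path)
        out[r.image_id] = np.asarray(Image.open(path).convert("RGB"))
    return out


def _predict(
    extractor, head, ids: Sequence[str], images: dict, transform: Transform,
    classes: Sequence[ScoreClass], batch_size: int,
) -> dict[str, ScoreClass]:
    preds: dict[str, ScoreClass] = {}
    for start in range(0, len(ids), batch_size):
        chunk = list(ids[start : start + batch_size])
        batch = np.stack([transform(images[i]) for i in chunk])
        scores = forward(extractor, head, batch, training=False)
        for j, image_id in enumerate(chunk):
            preds[image_id] = classes[int(np.argmax(scores[j]))]
    return preds


def evaluate_model(
    extractor, head, manifest: Manifest, test_ids: Sequence[str],
    images: dict, aug_config: AugmentationConfig, classes: Sequence[ScoreClass],
    batch_size: int = 32, warnings: Sequence[str] = (),
) -> AccuracyReport:
    """Deterministic evaluation (resize + normalize only) on the test side."""
    transform = evaluation_transform(aug_config)
    by_id = manifest.by_image_id()
    ordered = sorted(test_ids)
    preds = _predict(extractor, head, ordered, images, transform, classes, batch_size)
    entries = tuple((i, by_id[i].score, preds[i]) for i in ordered)
    return build_report(PredictionSet(entries), manifest, warnings=warnings)


def train_model(
    config: TrainConfig,
    manifest: Manifest,
    split: DatasetSplit,
    images: dict[str, np.ndarray],
    run_index: int = 0,
) -> RunResult:
    """Train one run on the split's train side and evaluate on its test side.

    After every epoch the set of ids that contributed gradients is audited
    against the split's training ids, so no test image can influence weights.
    """
    seed = config.seed + run_index
    by_id = manifest.by_image_id()
    train_ids = sorted(split.train_ids)
    test_ids = sorted(split.test_ids)
    if not train_ids:
        raise ValueError("split has an empty training set")

    train_ranks = sorted({by_id[i].score.rank for i in train_ids})
    classes = tuple(ScoreClass.from_rank(r) for r in train_ranks)
    rank_to_idx = {r: j for j, r in enumerate(train_ranks)}
    warnings = []
    test_only = sorted({by_id[i].score.label for i in test_ids}
                       - {c.label for c in classes})
    if test_only:
        warnings.append(
            f"classes present in test but absent in train: {', '.join(test_only)}"
        )

    extractor = build_feature_extractor(config.network, seed=seed)
    head = build_classifier(
        extractor.feature_dim, len(classes), init=config.network.head_init,
        rng=np.random.default_rng(seed + 10_000),
    )
    params = extractor.parameters() + head.parameters()
    optimizer = make_optimizer(config.optimizer, params, config.learning_rate)
    train_transform = compose(config.augmentation)

    shuffle_rng = np.random.default_rng(seed)
    labels = {i: rank_to_idx[by_id[i].score.rank] for i in train_ids}
    allowed = set(train_ids)
    loss_trace: list[float] = []
    for epoch in range(config.epochs):
        order = list(train_ids)
        shuffle_rng.shuffle(order)
        epoch_loss = 0.0
        n_batches = 0
        seen: set[str] = set()
        for start in range(0, len(order), config.batch_size):
            chunk = order[start : start + config.batch_size]
            batch = np.stack(
                [
                    train_transform(
                        images[i], np.random.default_rng((seed, epoch, start + j))
                    )
                    for j, i in enumerate(chunk)
                ]
            )
            targets = np.array([labels[i] for i in chunk])
            logits = forward(extractor, head, batch, training=True)
            loss, grad = softmax_cross_entropy(logits, targets)
            optimizer.zero_grad()
            extractor.backward(head.backward(grad))
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
            seen.update(chunk)
        if not seen <= allowed:
            raise RuntimeError("leakage audit failed: non-train ids used in an epoch")
        loss_trace.append(epoch_loss / max(n_batches, 1))

    report = evaluate_model(
        extractor, head, manifest, test_ids, images, config.augmentation, classes,
        batch_size=config.batch_size, warnings=warnings,
    )
    return RunResult(run_index, seed, loss_trace, report, extractor, head, classes)


def run_experiment(
    config: TrainConfig,
    manifest: Manifest,
    split: DatasetSplit,
    images: dict[str, np.ndarray],
) -> dict:
    """Train ``config.n_runs`` runs (seeds base+0 .. base+n-1) and aggregate
    mean/min/max of IA, FIA and LA, plus the training-set size."""
    results = [
        train_model(config, manifest, split, images, run_index=i)
        for i in range(config.n_runs)
    ]
    summary: dict = {
        "split": split.name,
        "n_runs": config.n_runs,
        "train_size": len(split.train_ids),
        "runs": [],
    }
    for metric in ("IA", "FIA", "LA"):
        values = [getattr(r.report, metric) for r in results]
        summary[metric] = {
            "mean": float(np.mean(values)),
            "min": float(np.min(values)),
            "max": float(np.max(values)),
        }
    for r in results:
        summary["runs"].append(
            {"run_index": r.run_index, "seed": r.seed,
             "IA": r.report.IA, "FIA": r.report.FIA, "LA": r.report.LA,
             "final_loss": r.loss_trace[-1]}
        )
    summary["results"] = results
    return summary
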