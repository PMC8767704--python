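"""Feature extraction network and classification head.

The backbone is a headless residual network of configurable depth (18, 34,
50, 101 or 152, plus the CPU-scale "tiny" option); its pooled output feeds a
single fully connected layer initialized with Kaiming-Uniform whose output
length equals the number of score classes.

Feature dimension contract: 512 for depths 18/34, 2048 for 50/101/152,
64 for tiny. The headless depth-34 backbone has exactly 21,284,672 trainable
parameters (21.28M).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Union

import numpy as np

from .nn import Layer, Linear, ResNetFeatures, TinyFeatures, RESNET_DEPTHS

__all__ = [
    "NetworkConfig",
    "build_feature_extractor",
    "build_classifier",
    "count_trainable_parameters",
    "forward",
    "save_weights",
    "load_weights",
]

FEATURE_DIMS = {18: 512, 34: 512, 50: 2048, 101: 2048, 152: 2048, "tiny": 64}


@dataclass(frozen=True)
class NetworkConfig:
    depth: Union[int, str] = 34
    pretrained: bool = False
    n_classes: int = 9
    head_init: str = "kaiming_uniform"
    weights_path: str | None = None  # external asset when pretrained=True

    def __post_init__(self) -> None:
        if self.depth != "tiny" and self.depth not in RESNET_DEPTHS:
            raise ValueError(
                f"depth must be 'tiny' or one of {sorted(RESNET_DEPTHS)}, got {self.depth!r}"
            )
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def build_feature_extractor(config: NetworkConfig, seed: int = 0) -> Layer:
    """Build the headless backbone; deterministic initial weights for a seed.

    With ``pretrained=True`` the weights are loaded from the external asset at
    ``config.weights_path`` (no layer is frozen); the asset is optional and
    absent in offline runs, which raises.
    """
    rng = np.random.default_rng(seed)
    if config.depth == "tiny":
        extractor: Layer = TinyFeatures(rng)
    else:
        extractor = ResNetFeatures(int(config.depth), rng)
    if config.pretrained:
        if not config.weights_path or not os.path.exists(config.weights_path):
            raise FileNotFoundError(
                "pretrained=True requires a weights asset; set NetworkConfig.weights_path"
            )
        load_weights(extractor, config.weights_path)
    return extractor


def build_classifier(
    feature_dim: int,
    n_classes: int,
    init: str = "kaiming_uniform",
    rng: np.random.Generator | None = None,
) -> Linear:
    """Single fully connected scoring layer feature_dim -> n_classes."""
    if feature_dim < 1 or n_classes < 1:
        raise ValueError("feature_dim and n_classes must be >= 1")
    return Linear(feature_dim, n_classes, rng=rng or np.random.default_rng(0), init=init)


def count_trainable_parameters(model: Layer) -> int:
    """Exact count of trainable scalar weights."""
    return sum(p.size for p in model.parameters())


def forward(extractor: Layer, head: Linear, batch: np.ndarray, training: bool = False) -> np.ndarray:
    """Map a batch of images to prediction vectors (pre-softmax scores).

    Accepts (N, H, W, 3) channel-last float input (the augmentation output
    layout) or (N, 3, H, W) channel-first.
    """
    x = np.asarray(batch, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError(f"expected a 4-d batch, got shape {x.shape}")
    if x.shape[-1] == 3 and x.shape[1] != 3:
        x = x.transpose(0, 3, 1, 2)
    x = np.ascontiguousarray(x)
    features = extractor.forward(x, training)
    return head.forward(features, training)


def _iter_batchnorms(layer) -> list:
    """Recursively collect BatchNorm layers (they carry non-trainable buffers)."""
    from .nn import BatchNorm2d

    found = []
    if isinstance(layer, BatchNorm2d):
        found.append(layer)
    for attr in ("net", "main", "downsample", "relu"):
        child = getattr(layer, attr, None)
        if child is not None:
            found.extend(_iter_batchnorms(child))
    for child in getattr(layer, "layers", []):
        found.extend(_iter_batchnorms(child))
    return found


def save_weights(model: Layer, path: str) -> None:
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    for i, bn in enumerate(_iter_batchnorms(model)):
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    np.savez(path, **arrays)


def load_weights(model: Layer, path: str) -> None:
    with np.load(path) as data:
        params = model.parameters()
        for i, p in enumerate(params):
            key = f"p{i}"
            if key not in data:
                raise ValueError(f"checkpoint missing parameter {key}")
            arr = data[key]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr
        for i, bn in enumerate(_iter_batchnorms(model)):
            if f"bn{i}_mean" in data:
                bn.running_mean = data[f"bn{i}_mean"].copy()
                bn.running_var = data[f"bn{i}_var"].copy()
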