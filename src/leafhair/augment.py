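"""Image augmentation: mandatory resize/normalize plus stochastic ops.

All ops take and return (H, W, 3) float32 arrays on the 0-255 intensity
scale, except :func:`normalize` which converts to standardized float
(x/255 - mean)/std and is always the last step of a composed transform.
Geometric resampling (resize, rotation) is bilinear via Pillow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "AugmentationConfig",
    "resize",
    "normalize",
    "rv_flip",
    "rh_flip",
    "random_crop",
    "random_rotation",
    "gaussian_noise",
    "compose",
    "Transform",
]

# Channel statistics of the pretraining corpus (fractions of full scale).
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

KNOWN_OPS = (
    "resize",
    "normalize",
    "rv_flip",
    "rh_flip",
    "random_crop",
    "random_rotation",
    "gaussian_noise",
)


@dataclass(frozen=True)
class AugmentationConfig:
    ops: tuple[str, ...] = ("resize", "normalize")
    target_size: int = 448
    intermediate_size: int = 512
    flip_p: float = 0.5
    rotation_range: float = 30.0
    noise_sigma: float = 0.0
    noise_p: float = 1.0
    mean: tuple[float, float, float] = IMAGENET_MEAN
    std: tuple[float, float, float] = IMAGENET_STD
    seed: int = 0

    def __post_init__(self) -> None:
        for name in self.ops:
            if name not in KNOWN_OPS:
                raise ValueError(f"unknown augmentation op {name!r}; known: {KNOWN_OPS}")
        if not (0.0 <= self.flip_p <= 1.0 and 0.0 <= self.noise_p <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.intermediate_size < self.target_size:
            raise ValueError("intermediate_size must be >= target_size")
        if self.rotation_range < 0:
            raise ValueError("rotation_range must be >= 0")
        if any(s == 0 for s in self.std):
            raise ValueError("normalization std must be non-zero")


def _to_pil(image: np.ndarray) -> Image.Image:
    return Image.fromarray(np.clip(np.round(image), 0, 255).astype(np.uint8))


def _as_float(image: np.ndarray) -> np.ndarray:
    return np.asarray(image, dtype=np.float32)


def resize(image: np.ndarray, target: int) -> np.ndarray:
    """Down/up-sample to a square of side ``target`` (aspect ratio not kept)."""
    if target <= 0:
        raise ValueError(f"target size must be positive, got {target}")
    image = _as_float(image)
    if image.shape[0] == target and image.shape[1] == target:
        return image.copy()
    out = _to_pil(image).resize((target, target), Image.BILINEAR)
    return _as_float(np.asarray(out))


def normalize(
    image: np.ndarray,
    mean: Sequence[float] = IMAGENET_MEAN,
    std: Sequence[float] = IMAGENET_STD,
) -> np.ndarray:
    """Scale 0-255 input to [0, 1] then standardize per channel."""
    if any(s == 0 for s in std):
        raise ValueError("std must be non-zero")
    image = _as_float(image) / 255.0
    m = np.asarray(mean, dtype=np.float32).reshape(1, 1, 3)
    s = np.asarray(std, dtype=np.float32).reshape(1, 1, 3)
    return (image - m) / s


def rv_flip(image: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Reverse the rows (top-bottom flip) with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if rng.random() < p:
        return _as_float(image)[::-1].copy()
    return _as_float(image)


def rh_flip(image: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Reverse the columns (left-right flip) with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if rng.random() < p:
        return _as_float(image)[:, ::-1].copy()
    return _as_float(image)


def random_crop(
    image: np.ndarray, intermediate: int, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Resize to intermediate x intermediate then cut a target window at a
    uniformly drawn offset in [0, intermediate - target]^2."""
    if intermediate < target:
        raise ValueError("intermediate size must be >= target size")
    big = resize(image, intermediate)
    span = intermediate - target
    oy = int(rng.integers(0, span + 1))
    ox = int(rng.integers(0, span + 1))
    return big[oy : oy + target, ox : ox + target].copy()


def random_rotation(
    image: np.ndarray,
    max_deg: float,
    rng: np.random.Generator,
    fill: Sequence[float] | None = None,
    angle: float | None = None,
) -> np.ndarray:
    """Rotate about the image centre by an angle ~ Uniform(-max_deg, +max_deg).

    Exposed corners are filled with ``fill`` (default: the image's per-channel
    mean, to avoid injecting a constant-corner cue). ``angle`` forces a fixed
    angle, used for inverse-pair testing.
    """
    if max_deg < 0:
        raise ValueError("max_deg must be >= 0")
    image = _as_float(image)
    if angle is None:
        angle = float(rng.uniform(-max_deg, max_deg))
    if angle == 0.0:
        return image.copy()
    if fill is None:
        fill = image.reshape(-1, 3).mean(axis=0)
    fillcolor = tuple(int(round(c)) for c in fill)
    out = _to_pil(image).rotate(
        angle, resample=Image.BILINEAR, expand=False, fillcolor=fillcolor
    )
    return _as_float(np.asarray(out))


def gaussian_noise(
    image: np.ndarray, sigma: float, p: float, rng: np.random.Generator
) -> np.ndarray:
    """With probability ``p`` add iid zero-mean Gaussian noise (std ``sigma``,
    0-255 intensity units) to every channel, clipped to [0, 255]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    image = _as_float(image)
    if sigma == 0.0 or p == 0.0 or rng.random() >= p:
        return image.copy()
    noisy = image + rng.normal(0.0, sigma, size=image.shape).astype(np.float32)
    return np.clip(noisy, 0.0, 255.0)


class Transform:
    """A composed augmentation pipeline.

    Ops run in the configured order on the 0-255 scale; normalization is the
    terminal step. Call with an explicit ``rng`` for per-(seed, epoch, index)
    reproducibility, or without one to use the internal seeded stream.
    """

    def __init__(self, config: AugmentationConfig):
        # normalize is terminal regardless of its listed position: every other
        # op is defined on the 0-255 intensity scale
        ops = [op for op in config.ops if op != "normalize"]
        if "resize" not in ops and "random_crop" not in ops:
            ops.insert(0, "resize")
        ops.append("normalize")
        self.config = config
        self.ops = tuple(ops)
        self._rng = np.random.default_rng(config.seed)

    @property
    def is_stochastic(self) -> bool:
        return any(op not in ("resize", "normalize") for op in self.ops)

    def __call__(self, image: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None:
            rng = self._rng
        c = self.config
        out = _as_float(image)
        for op in self.ops:
            if op == "resize":
                out = resize(out, c.target_size)
            elif op == "random_crop":
                out = random_crop(out, c.intermediate_size, c.target_size, rng)
            elif op == "rv_flip":
                out = rv_flip(out, c.flip_p, rng)
            elif op == "rh_flip":
                out = rh_flip(out, c.flip_p, rng)
            elif op == "random_rotation":
                out = random_rotation(out, c.rotation_range, rng)
            elif op == "gaussian_noise":
                out = gaussian_noise(out, c.noise_sigma, c.noise_p, rng)
            elif op == "normalize":
                out = normalize(out, c.mean, c.std)
        return out


def compose(config: AugmentationConfig) -> Transform:
    """Build the composed transform for a config (resize/normalize always present)."""
    return Transform(config)


def evaluation_transform(config: AugmentationConfig) -> Transform:
    """The deterministic evaluation pipeline: resize + normalize only."""
    from dataclasses import replace

    return Transform(replace(config, ops=("resize", "normalize")))
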