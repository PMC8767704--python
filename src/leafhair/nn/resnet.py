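"""Residual feature-extraction backbones (headless) plus a tiny CPU-scale net.

The five canonical depths follow the standard residual architecture: a 7x7
stem, four stages of basic blocks (depths 18/34) or bottleneck blocks
(50/101/152), and a global average pool. The final fully connected classifier
of the original architecture is absent: the output is the pooled feature
vector (512 for basic-block depths, 2048 for bottleneck depths).
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Layer,
    MaxPool2d,
    Parameter,
    ReLU,
    Sequential,
)

__all__ = ["RESNET_DEPTHS", "ResNetFeatures", "TinyFeatures", "BasicBlock", "Bottleneck"]

#: stage block counts per canonical depth; bool flags bottleneck blocks
RESNET_DEPTHS: dict[int, tuple[list[int], bool]] = {
    18: ([2, 2, 2, 2], False),
    34: ([3, 4, 6, 3], False),
    50: ([3, 4, 6, 3], True),
    101: ([3, 4, 23, 3], True),
    152: ([3, 8, 36, 3], True),
}


class _Block(Layer):
    """Residual block with optional projection shortcut."""

    def __init__(self, main: Sequential, downsample: Sequential | None):
        self.main = main
        self.downsample = downsample
        self.relu = ReLU()

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        identity = x if self.downsample is None else self.downsample.forward(x, training)
        return self.relu.forward(self.main.forward(x, training) + identity, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu.backward(grad)
        gx = self.main.backward(g)
        gid = g if self.downsample is None else self.downsample.backward(g)
        return gx + gid

    def parameters(self) -> list[Parameter]:
        params = self.main.parameters()
        if self.downsample is not None:
            params += self.downsample.parameters()
        return params


def BasicBlock(in_ch: int, ch: int, stride: int, rng: np.random.Generator) -> _Block:
    main = Sequential(
        Conv2d(in_ch, ch, 3, stride=stride, pad=1, rng=rng),
        BatchNorm2d(ch),
        ReLU(),
        Conv2d(ch, ch, 3, stride=1, pad=1, rng=rng),
        BatchNorm2d(ch),
    )
    downsample = None
    if stride != 1 or in_ch != ch:
        downsample = Sequential(Conv2d(in_ch, ch, 1, stride=stride, rng=rng), BatchNorm2d(ch))
    return _Block(main, downsample)


def Bottleneck(in_ch: int, ch: int, stride: int, rng: np.random.Generator) -> _Block:
    out_ch = ch * 4
    main = Sequential(
        Conv2d(in_ch, ch, 1, rng=rng),
        BatchNorm2d(ch),
        ReLU(),
        Conv2d(ch, ch, 3, stride=stride, pad=1, rng=rng),
        BatchNorm2d(ch),
        ReLU(),
        Conv2d(ch, out_ch, 1, rng=rng),
        BatchNorm2d(out_ch),
    )
    downsample = None
    if stride != 1 or in_ch != out_ch:
        downsample = Sequential(
            Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng), BatchNorm2d(out_ch)
        )
    return _Block(main, downsample)


class ResNetFeatures(Layer):
    """Headless residual network: image batch (N, 3, H, W) -> features (N, D)."""

    def __init__(self, depth: int, rng: np.random.Generator | None = None):
        if depth not in RESNET_DEPTHS:
            raise ValueError(f"unsupported depth {depth}; choose from {sorted(RESNET_DEPTHS)}")
        rng = rng or np.random.default_rng(0)
        blocks_per_stage, bottleneck = RESNET_DEPTHS[depth]
        make = Bottleneck if bottleneck else BasicBlock
        expansion = 4 if bottleneck else 1
        layers: list[Layer] = [
            Conv2d(3, 64, 7, stride=2, pad=3, rng=rng),
            BatchNorm2d(64),
            ReLU(),
            MaxPool2d(3, 2, 1),
        ]
        in_ch = 64
        for stage, n_blocks in enumerate(blocks_per_stage):
            ch = 64 * 2**stage
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                layers.append(make(in_ch, ch, stride, rng))
                in_ch = ch * expansion
        layers.append(GlobalAvgPool())
        self.depth = depth
        self.feature_dim = in_ch
        self.net = Sequential(*layers)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return self.net.forward(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def parameters(self) -> list[Parameter]:
        return self.net.parameters()


class TinyFeatures(Layer):
    """Four stride-2 conv/ReLU stages + global pool, with a global-context
    shortcut (the input's per-channel spatial means concatenated onto the
    pooled conv features). ~100k parameters, feature dimension 131.

    CPU-scale stand-in for the residual backbones when training on synthetic
    data. No batch normalization: on small synthetic batches it destabilizes
    generalization without buying optimization speed.
    """

    def __init__(self, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        chans = [3, 16, 32, 64, 128]
        layers: list[Layer] = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            layers += [Conv2d(cin, cout, 3, stride=2, pad=1, bias=True, rng=rng), ReLU()]
        layers.append(GlobalAvgPool())
        self.depth = "tiny"
        self.feature_dim = chans[-1] + 3
        self.net = Sequential(*layers)

    #: gain on the context branch: raw channel means have tiny dynamic range
    #: after input normalization, so amplify them to the conv features' scale
    CONTEXT_GAIN = 8.0

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        conv = self.net.forward(x, training)
        context = self.CONTEXT_GAIN * x.mean(axis=(2, 3))
        return np.concatenate([conv, context], axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # the context branch is parameter-free; only conv features backprop
        return self.net.backward(grad[:, : self.feature_dim - 3])

    def parameters(self) -> list[Parameter]:
        return self.net.parameters()
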