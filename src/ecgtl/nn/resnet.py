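"""1D pre-activation residual networks (v2 ordering: norm - ReLU - conv).

Depths 18/34 use basic two-conv blocks, depth 50 uses bottleneck blocks
with a 4x channel expansion. Stage kernel sizes default to (7, 5, 5, 3),
which work better than 3-sample kernels on raw ECG. A width multiplier
shrinks every stage uniformly for desk-scale experiments.
"""

from __future__ import annotations

import numpy as np

from .core import Layer, Param
from .layers import BatchNorm1d, Conv1d, GlobalAvgPool, MaxPool1d, ReLU

STAGE_BLOCKS = {18: (2, 2, 2, 2), 34: (3, 4, 6, 3), 50: (3, 4, 6, 3)}
BASE_WIDTHS = (64, 128, 256, 512)


class PreActBasicBlock(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator) -> None:
        self.bn1 = BatchNorm1d(in_ch)
        self.relu1 = ReLU()
        self.conv1 = Conv1d(in_ch, out_ch, kernel, stride=stride, rng=rng)
        self.bn2 = BatchNorm1d(out_ch)
        self.relu2 = ReLU()
        self.conv2 = Conv1d(out_ch, out_ch, kernel, stride=1, rng=rng)
        self.project = stride != 1 or in_ch != out_ch
        self.shortcut = (Conv1d(in_ch, out_ch, 1, stride=stride, rng=rng)
                         if self.project else None)
        self._sub = [self.bn1, self.relu1, self.conv1, self.bn2, self.relu2,
                     self.conv2] + ([self.shortcut] if self.shortcut else [])

    def params(self) -> list[Param]:
        return [p for layer in self._sub for p in layer.params()]

    def buffers(self) -> dict[str, np.ndarray]:
        return {f"{i}.{k}": v for i, layer in enumerate(self._sub)
                for k, v in layer.buffers().items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        pre = self.relu1.forward(self.bn1.forward(x, train), train)
        h = self.conv1.forward(pre, train)
        h = self.conv2.forward(self.relu2.forward(self.bn2.forward(h, train), train), train)
        sc = self.shortcut.forward(pre, train) if self.project else x
        return h + sc

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.bn2.backward(self.relu2.backward(self.conv2.backward(dy)))
        dpre = self.conv1.backward(dh)
        if self.project:
            dpre = dpre + self.shortcut.backward(dy)
        dx = self.bn1.backward(self.relu1.backward(dpre))
        if not self.project:
            dx = dx + dy
        return dx


class PreActBottleneckBlock(Layer):
    expansion = 4

    def __init__(self, in_ch: int, mid_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator) -> None:
        out_ch = mid_ch * self.expansion
        self.bn1 = BatchNorm1d(in_ch)
        self.relu1 = ReLU()
        self.conv1 = Conv1d(in_ch, mid_ch, 1, stride=1, rng=rng)
        self.bn2 = BatchNorm1d(mid_ch)
        self.relu2 = ReLU()
        self.conv2 = Conv1d(mid_ch, mid_ch, kernel, stride=stride, rng=rng)
        self.bn3 = BatchNorm1d(mid_ch)
        self.relu3 = ReLU()
        self.conv3 = Conv1d(mid_ch, out_ch, 1, stride=1, rng=rng)
        self.project = stride != 1 or in_ch != out_ch
        self.shortcut = (Conv1d(in_ch, out_ch, 1, stride=stride, rng=rng)
                         if self.project else None)
        self._sub = [self.bn1, self.relu1, self.conv1, self.bn2, self.relu2,
                     self.conv2, self.bn3, self.relu3, self.conv3] + (
                     [self.shortcut] if self.shortcut else [])

    def params(self) -> list[Param]:
        return [p for layer in self._sub for p in layer.params()]

    def buffers(self) -> dict[str, np.ndarray]:
        return {f"{i}.{k}": v for i, layer in enumerate(self._sub)
                for k, v in layer.buffers().items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        pre = self.relu1.forward(self.bn1.forward(x, train), train)
        h = self.conv1.forward(pre, train)
        h = self.conv2.forward(self.relu2.forward(self.bn2.forward(h, train), train), train)
        h = self.conv3.forward(self.relu3.forward(self.bn3.forward(h, train), train), train)
        sc = self.shortcut.forward(pre, train) if self.project else x
        return h + sc

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.bn3.backward(self.relu3.backward(self.conv3.backward(dy)))
        dh = self.bn2.backward(self.relu2.backward(self.conv2.backward(dh)))
        dpre = self.conv1.backward(dh)
        if self.project:
            dpre = dpre + self.shortcut.backward(dy)
        dx = self.bn1.backward(self.relu1.backward(dpre))
        if not self.project:
            dx = dx + dy
        return dx


class ResNet1D(Layer):
    """Encoder: stem conv + pool, residual stages, final norm + global pool.

    ``stages_used`` < 4 truncates the network after that stage (used to
    pretrain only the early stages of the depth-50 network in the
    contrastive task, where the 4x expansion would blow up the pooling
    module).
    """

    def __init__(self, depth: int = 18, in_channels: int = 1,
                 width_multiplier: float = 1.0,
                 stage_kernels: tuple[int, int, int, int] = (7, 5, 5, 3),
                 stages_used: int = 4,
                 rng: np.random.Generator | None = None) -> None:
        if depth not in STAGE_BLOCKS:
            raise ValueError(f"unsupported depth {depth}; choose from {sorted(STAGE_BLOCKS)}")
        if not 1 <= stages_used <= 4:
            raise ValueError("stages_used must be in 1..4")
        if len(stage_kernels) != 4:
            raise ValueError("stage_kernels must have length 4")
        rng = rng or np.random.default_rng()
        self.depth = depth
        self.in_channels = in_channels
        self.width_multiplier = width_multiplier
        self.stage_kernels = tuple(stage_kernels)
        self.stages_used = stages_used
        widths = [max(int(round(w * width_multiplier)), 1) for w in BASE_WIDTHS]
        bottleneck = depth == 50

        self.stem_conv = Conv1d(in_channels, widths[0], 7, stride=2, rng=rng)
        self.stem_pool = MaxPool1d(3, 2)
        self.stages: list[list[Layer]] = []
        ch = widths[0]
        for i in range(stages_used):
            blocks: list[Layer] = []
            for j in range(STAGE_BLOCKS[depth][i]):
                stride = 2 if (i > 0 and j == 0) else 1
                if bottleneck:
                    block = PreActBottleneckBlock(ch, widths[i], self.stage_kernels[i],
                                                  stride, rng)
                    ch = widths[i] * PreActBottleneckBlock.expansion
                else:
                    block = PreActBasicBlock(ch, widths[i], self.stage_kernels[i],
                                             stride, rng)
                    ch = widths[i]
                blocks.append(block)
            self.stages.append(blocks)
        self.final_bn = BatchNorm1d(ch)
        self.final_relu = ReLU()
        self.gap = GlobalAvgPool()
        self.out_features = ch

    def _layers(self) -> list[Layer]:
        out: list[Layer] = [self.stem_conv, self.stem_pool]
        for blocks in self.stages:
            out.extend(blocks)
        out.extend([self.final_bn, self.final_relu, self.gap])
        return out

    def params(self) -> list[Param]:
        return [p for layer in self._layers() for p in layer.params()]

    def buffers(self) -> dict[str, np.ndarray]:
        return {f"{i}.{k}": v for i, layer in enumerate(self._layers())
                for k, v in layer.buffers().items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 3:
            raise ValueError("expected (batch, channels, length) input")
        for layer in self._layers():
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self._layers()):
            dy = layer.backward(dy)
        return dy
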