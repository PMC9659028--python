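"""Modified DenseNet classifier with valid padding.

The architecture: three dense blocks, each alternating four 1×1
convolutions (64 channels) with three 3×3 convolutions (32 channels),
starting and ending on a 1×1.  Inside a block, every 1×1 layer receives
the concatenation of the block input and all preceding 3×3 outputs,
center-cropped to the current spatial size (valid padding shrinks the
3×3 outputs by 2 px each, so crops are always symmetric).  Blocks 1–2
are followed by a transition block (1×1 convolution + 2×2 average
pooling); the last block by a single 3×3 convolution onto the class
logits.  Batch normalization and ReLU follow every convolution except
the last, which gets a soft-max.  Weights are He-initialized.

Because padding is valid, the network is translation-consistent: applied
fully convolutionally to a large raster it produces at every output
position exactly what it would produce on the corresponding patch, with
output stride 2^(blocks−1).  ``NetworkConfig`` is scalable so that tiny
instances can be trained and verified quickly; the defaults are the
full-scale architecture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from lymphmet.network.layers import (
    AvgPool2,
    BatchNorm2D,
    Conv2D,
    Param,
    ReLU,
    center_crop,
    softmax,
    uncrop_grad,
)


@dataclass
class NetworkConfig:
    n_dense_blocks: int = 3
    convs_1x1_per_block: int = 4
    convs_3x3_per_block: int = 3
    channels_1x1: int = 64
    channels_3x3: int = 32
    padding: str = "valid"
    patch_px: int = 279
    n_classes: int = 2
    in_channels: int = 3

    def __post_init__(self) -> None:
        if self.padding != "valid":
            raise ValueError("only valid padding is supported")
        if self.convs_1x1_per_block != self.convs_3x3_per_block + 1:
            raise ValueError(
                "alternating block must start and end with a 1x1 layer "
                "(convs_1x1_per_block == convs_3x3_per_block + 1)")
        for name in ("n_dense_blocks", "convs_3x3_per_block", "channels_1x1",
                     "channels_3x3", "patch_px", "n_classes", "in_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def output_shape(input_h: int, input_w: int, config: NetworkConfig
                 ) -> tuple[int, int, int]:
    """Spatial output size and effective stride of the composed stack.

    Raises if the input is below the minimum field of view.
    """

    def reduce(s: int) -> int:
        for b in range(config.n_dense_blocks):
            s -= 2 * config.convs_3x3_per_block
            if s < 1:
                raise ValueError("input smaller than the minimum field of view")
            if b < config.n_dense_blocks - 1:
                if s < 2:
                    raise ValueError("input smaller than the minimum field of view")
                s //= 2
        s -= 2  # final 3x3 convolution
        if s < 1:
            raise ValueError("input smaller than the minimum field of view")
        return s

    stride = 2 ** (config.n_dense_blocks - 1)
    return reduce(input_h), reduce(input_w), stride


def min_input_size(config: NetworkConfig) -> int:
    """Smallest input side producing a 1×1 output (the field of view)."""
    s = 1 + 2  # final 3x3 convolution
    for b in reversed(range(config.n_dense_blocks)):
        if b < config.n_dense_blocks - 1:
            s *= 2  # smallest pooling input yielding s
        s += 2 * config.convs_3x3_per_block
    return s


class _ConvUnit:
    """Conv → BN → ReLU."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.conv = Conv2D(in_ch, out_ch, k, rng)
        self.bn = BatchNorm2D(out_ch)
        self.relu = ReLU()

    def forward(self, x, train=False):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train),
                                                 train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))

    def params(self):
        return self.conv.params() + self.bn.params()

    def bn_stats(self):
        return [self.bn.running_mean, self.bn.running_var]


class DenseBlock:
    def __init__(self, in_ch: int, config: NetworkConfig,
                 rng: np.random.Generator):
        n1, n3 = config.convs_1x1_per_block, config.convs_3x3_per_block
        ch1, ch3 = config.channels_1x1, config.channels_3x3
        self.n1, self.n3 = n1, n3
        self.units_1x1 = [
            _ConvUnit(in_ch + i * ch3, ch1, 1, rng) for i in range(n1)]
        self.units_3x3 = [_ConvUnit(ch1, ch3, 3, rng) for i in range(n3)]
        self.out_channels = ch1
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        feats = [x]
        a = None
        iter_cache = []
        for i in range(self.n1):
            th, tw = feats[-1].shape[1], feats[-1].shape[2]
            cropped = [center_crop(f, th, tw) for f in feats]
            cat = np.concatenate(cropped, axis=-1) if len(cropped) > 1 else cropped[0]
            if train:
                iter_cache.append(
                    ((th, tw),
                     [(f.shape[1], f.shape[2], f.shape[3]) for f in feats]))
            a = self.units_1x1[i].forward(cat, train)
            if i < self.n3:
                feats.append(self.units_3x3[i].forward(a, train))
        if train:
            self._cache = iter_cache
        return a

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        iter_cache = self._cache
        feat_grads: list[np.ndarray | None] = [None] * (self.n3 + 1)
        d_a = d_out
        for i in range(self.n1 - 1, -1, -1):
            (th, tw), feat_shapes = iter_cache[i]
            dcat = self.units_1x1[i].backward(d_a)
            ofs = 0
            for j, (fh, fw, fc) in enumerate(feat_shapes):
                g = uncrop_grad(dcat[..., ofs:ofs + fc], fh, fw)
                feat_grads[j] = g if feat_grads[j] is None else feat_grads[j] + g
                ofs += fc
            if i > 0:
                d_a = self.units_3x3[i - 1].backward(feat_grads[i])
        return feat_grads[0]

    def params(self):
        out = []
        for u in self.units_1x1 + self.units_3x3:
            out.extend(u.params())
        return out

    def units(self):
        return self.units_1x1 + self.units_3x3


class Transition:
    """1×1 convolution + 2×2 average pooling."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.unit = _ConvUnit(in_ch, out_ch, 1, rng)
        self.pool = AvgPool2()
        self.out_channels = out_ch

    def forward(self, x, train=False):
        return self.pool.forward(self.unit.forward(x, train), train)

    def backward(self, dy):
        return self.unit.backward(self.pool.backward(dy))

    def params(self):
        return self.unit.params()

    def units(self):
        return [self.unit]


class DenseNet:
    """The composed network; all state lives in numpy arrays."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.blocks: list[DenseBlock] = []
        self.transitions: list[Transition] = []
        ch = config.in_channels
        for b in range(config.n_dense_blocks):
            block = DenseBlock(ch, config, rng)
            self.blocks.append(block)
            ch = block.out_channels
            if b < config.n_dense_blocks - 1:
                tr = Transition(ch, config.channels_1x1, rng)
                self.transitions.append(tr)
                ch = tr.out_channels
        self.final_conv = Conv2D(ch, config.n_classes, 3, rng, bias=True)

    # ----- geometry -------------------------------------------------------

    @property
    def stride(self) -> int:
        return 2 ** (self.config.n_dense_blocks - 1)

    @property
    def min_input(self) -> int:
        return min_input_size(self.config)

    def output_shape(self, input_h: int, input_w: int) -> tuple[int, int, int]:
        return output_shape(input_h, input_w, self.config)

    # ----- forward / backward --------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[-1] != self.config.in_channels:
            raise ValueError(
                f"expected NHWC input with {self.config.in_channels} channels")
        self.output_shape(x.shape[1], x.shape[2])  # validates size
        for b, block in enumerate(self.blocks):
            x = block.forward(x, train)
            if b < len(self.transitions):
                x = self.transitions[b].forward(x, train)
        return self.final_conv.forward(x, train)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-position class probabilities (soft-max over last axis)."""
        return softmax(self.forward_logits(x, train=False))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dx = self.final_conv.backward(dlogits)
        for b in range(len(self.blocks) - 1, -1, -1):
            if b < len(self.transitions):
                dx = self.transitions[b].backward(dx)
            dx = self.blocks[b].backward(dx)
        return dx

    # ----- parameters -----------------------------------------------------

    def params(self) -> list[Param]:
        out = []
        for b, block in enumerate(self.blocks):
            out.extend(block.params())
            if b < len(self.transitions):
                out.extend(self.transitions[b].params())
        out.extend(self.final_conv.params())
        return out

    def zero_grads(self) -> None:
        for p in self.params():
            p.grad.fill(0.0)

    def _bn_stats(self) -> list[np.ndarray]:
        stats = []
        for b, block in enumerate(self.blocks):
            units = block.units()
            if b < len(self.transitions):
                units = units + self.transitions[b].units()
            for u in units:
                stats.extend(u.bn_stats())
        return stats

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()] + \
               [s.copy() for s in self._bn_stats()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.params()
        stats = self._bn_stats()
        if len(state) != len(params) + len(stats):
            raise ValueError("state does not match the architecture")
        for p, v in zip(params, state[: len(params)]):
            p.value[...] = v
        for s, v in zip(stats, state[len(params):]):
            s[...] = v

    def save(self, path) -> None:
        arrays = {f"arr_{i}": a for i, a in enumerate(self.get_state())}
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "DenseNet":
        with np.load(path, allow_pickle=False) as data:
            config = NetworkConfig(**json.loads(str(data["config"])))
            net = cls(config)
            n = len(net.get_state())
            net.set_state([data[f"arr_{i}"] for i in range(n)])
        return net


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> DenseNet:
    """He-initialized network; identical weights for identical seeds."""
    return DenseNet(config or NetworkConfig(), seed=seed)
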