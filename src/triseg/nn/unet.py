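"""The modified U-Net used by each orientation-specialized network.

Relative to the classic U-Net: the input is the 3-channel extended-2D stack
(previous/center/next slice); every level is a double convolutional block
[3x3 padded unbiased conv -> batch norm -> ReLU] x2 with a parallel 1x1
convolution from the block input added to the block output (a residual
shortcut that also adapts channel counts); and the head is a 1x1 convolution
followed by a sigmoid (one foreground channel) or a two-channel softmax
(background/foreground), selected by ``output_mode``.

An encoder-initialization hook exists for externally supplied pretrained
weights; the default is seeded random (He) initialization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from ..exceptions import ConfigError, ShapeError
from .layers import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Layer,
    MaxPool2d,
    Param,
    ReLU,
    Sigmoid,
    SoftmaxChannels,
)

OUTPUT_MODES = ("sigmoid_1ch", "softmax_2ch")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of 2x downsamplings; input spatial sides must be
    divisible by ``2**depth``.  ``base_width`` is the filter count of the
    first block, doubling per level.
    """

    in_channels: int = 3
    base_width: int = 16
    depth: int = 4
    output_mode: str = "sigmoid_1ch"
    encoder_init: str = "random"
    seed: int = 0

    def validate(self) -> None:
        if self.in_channels != 3:
            raise ConfigError("the extended-2D input contract requires in_channels=3")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.base_width < 1:
            raise ConfigError("base_width must be >= 1")
        if self.output_mode not in OUTPUT_MODES:
            raise ConfigError(f"output_mode must be one of {OUTPUT_MODES}")
        if self.encoder_init not in ("random", "pretrained_hook"):
            raise ConfigError("encoder_init must be 'random' or 'pretrained_hook'")

    @property
    def out_channels(self) -> int:
        return 1 if self.output_mode == "sigmoid_1ch" else 2


class ResidualBlock(Layer):
    """[conv3 -> BN -> ReLU] x2 with a 1x1-conv shortcut added to the output."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu2 = ReLU()
        self.shortcut = Conv2d(in_ch, out_ch, 1, rng)

    def parameters(self) -> list[Param]:
        return (
            self.conv1.parameters()
            + self.bn1.parameters()
            + self.conv2.parameters()
            + self.bn2.parameters()
            + self.shortcut.parameters()
        )

    def sublayers(self) -> list[tuple[str, Layer]]:
        return [
            ("conv1", self.conv1),
            ("bn1", self.bn1),
            ("conv2", self.conv2),
            ("bn2", self.bn2),
            ("shortcut", self.shortcut),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.relu2.forward(self.bn2.forward(self.conv2.forward(h, train), train), train)
        return h + self.shortcut.forward(x, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = self.shortcut.backward(gy)
        g = self.conv2.backward(self.bn2.backward(self.relu2.backward(gy)))
        gx += self.conv1.backward(self.bn1.backward(self.relu1.backward(g)))
        return gx


class UNet:
    """Encoder-decoder with skip concatenations built from residual blocks."""

    def __init__(self, cfg: NetworkConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.base_width
        self.enc_blocks: list[ResidualBlock] = []
        self.pools: list[MaxPool2d] = []
        ch = cfg.in_channels
        for level in range(cfg.depth):
            self.enc_blocks.append(ResidualBlock(ch, w * 2**level, rng))
            self.pools.append(MaxPool2d())
            ch = w * 2**level
        self.bottleneck = ResidualBlock(ch, w * 2**cfg.depth, rng)
        self.upsamples: list[ConvTranspose2d] = []
        self.dec_blocks: list[ResidualBlock] = []
        ch = w * 2**cfg.depth
        for level in reversed(range(cfg.depth)):
            skip_ch = w * 2**level
            self.upsamples.append(ConvTranspose2d(ch, skip_ch, rng))
            self.dec_blocks.append(ResidualBlock(2 * skip_ch, skip_ch, rng))
            ch = skip_ch
        self.head = Conv2d(w, cfg.out_channels, 1, rng)
        self.activation = Sigmoid() if cfg.output_mode == "sigmoid_1ch" else SoftmaxChannels()

    # -- structure ---------------------------------------------------------
    def named_layers(self) -> list[tuple[str, Layer]]:
        out: list[tuple[str, Layer]] = []
        for i, blk in enumerate(self.enc_blocks):
            out += [(f"enc{i}.{n}", l) for n, l in blk.sublayers()]
        out += [(f"bottleneck.{n}", l) for n, l in self.bottleneck.sublayers()]
        for i, up in enumerate(self.upsamples):
            out.append((f"up{i}", up))
        for i, blk in enumerate(self.dec_blocks):
            out += [(f"dec{i}.{n}", l) for n, l in blk.sublayers()]
        out.append(("head", self.head))
        return out

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for _, layer in self.named_layers():
            params += layer.parameters()
        return params

    def num_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map an (N, 3, H, W) batch to (N, out_ch, H, W) probabilities."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ShapeError(f"expected (N,{self.cfg.in_channels},H,W), got {x.shape}")
        div = 2**self.cfg.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise ShapeError(
                f"spatial size {x.shape[2]}x{x.shape[3]} not divisible by 2**depth={div}"
            )
        skips = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._skip_channels = []
        for up, blk, skip in zip(self.upsamples, self.dec_blocks, reversed(skips)):
            h = up.forward(h, train)
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h, train)
        h = self.head.forward(h, train)
        return self.activation.forward(h, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(output probabilities); returns d/d(input)."""
        g = self.activation.backward(gy)
        g = self.head.backward(g)
        gskips = []
        for up, blk, skip_ch in zip(
            reversed(self.upsamples), reversed(self.dec_blocks), reversed(self._skip_channels)
        ):
            g = blk.backward(g)
            gskips.append(g[:, :skip_ch])
            g = up.backward(np.ascontiguousarray(g[:, skip_ch:]))
        g = self.bottleneck.backward(g)
        # gskips was collected walking the decoder in reverse, i.e. shallowest
        # skip first; the encoder is unwound deepest-first, so reverse again.
        for blk, pool, gskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(gskips)
        ):
            g = pool.backward(g)
            g = blk.backward(g + gskip)
        return g

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, layer in self.named_layers():
            for i, p in enumerate(layer.parameters()):
                state[f"{name}.p{i}"] = p.value
            for key, arr in layer.state_arrays().items():
                state[f"{name}.{key}"] = arr
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.named_layers():
            for i, p in enumerate(layer.parameters()):
                p.value[...] = state[f"{name}.p{i}"]
            for key, arr in layer.state_arrays().items():
                arr[...] = state[f"{name}.{key}"]

    def apply_encoder_init(self, hook: Callable[[str, Param], None]) -> None:
        """Call ``hook(layer_name, param)`` on every encoder conv weight.

        This is the entry point for loading externally pretrained encoder
        weights; nothing in the package downloads or ships any.
        """
        for i, blk in enumerate(self.enc_blocks):
            for n, layer in blk.sublayers():
                for p in layer.parameters():
                    hook(f"enc{i}.{n}", p)


def build_network(cfg: NetworkConfig) -> UNet:
    """Construct the modified U-Net described by ``cfg`` (seeded, deterministic)."""
    return UNet(cfg)


def save_checkpoint(model: UNet, path: str | Path) -> None:
    """Persist config + weights (.npz with an embedded JSON config)."""
    path = Path(path)
    cfg_json = json.dumps(asdict(model.cfg))
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path: str | Path) -> UNet:
    path = Path(path)
    with np.load(path) as npz:
        cfg = NetworkConfig(**json.loads(bytes(npz["__config__"]).decode()))
        model = UNet(cfg)
        model.load_state_dict({k: npz[k] for k in npz.files if k != "__config__"})
    return model
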