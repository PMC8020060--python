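"""Configurable 2D and 3D U-Net builders.

Both networks share the classic encoder/decoder layout: two 3^d "same"
convolutions per resolution level, each followed by instance normalization
and ReLU, 2x max pooling down, 2x
transposed-convolution up with skip concatenation, and a 1x1 head emitting
raw per-class scores (softmax is applied explicitly by the caller).

The paired configuration used throughout the study links the two
dimensionalities: at every shared level the 2D network carries four times
the feature maps of the 3D one, and the 3D network has one extra
pooling/up-convolution stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Adam, Conv, InstanceNorm, MaxPool2, Param, ReLU, ShapeError,
                 UpConv2, softmax)

__all__ = ["UNetConfig", "UNet", "build_unet", "linked_pair", "softmax_probabilities"]


@dataclass(frozen=True)
class UNetConfig:
    dims: int  # 2 or 3
    depth: int  # number of pooling stages
    base_features: int  # feature maps at the first level
    in_channels: int = 1
    out_classes: int = 3

    def __post_init__(self):
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.depth < 1 or self.base_features < 1:
            raise ValueError("depth and base_features must be >= 1")

    @property
    def encoder_widths(self) -> tuple[int, ...]:
        """Feature maps at levels 0..depth (last one is the bottleneck)."""
        return tuple(self.base_features * 2**k for k in range(self.depth + 1))


def linked_pair(base_features_3d: int, depth_3d: int) -> tuple[UNetConfig, UNetConfig]:
    """The linked (2D, 3D) configuration pair: 2D has 4x the feature maps
    per level and one pooling stage fewer than the 3D network."""
    if depth_3d < 2:
        raise ValueError("depth_3d must be >= 2 so the 2D depth stays >= 1")
    cfg3 = UNetConfig(dims=3, depth=depth_3d, base_features=base_features_3d)
    cfg2 = UNetConfig(dims=2, depth=depth_3d - 1, base_features=4 * base_features_3d)
    return cfg2, cfg3


def softmax_probabilities(scores: np.ndarray, axis: int = 0) -> np.ndarray:
    """Per-voxel class probabilities from raw scores.

    Default axis 0 matches the (classes, *spatial) layout returned by
    UNet.predict; pass axis=1 for batched (N, classes, *spatial) arrays.
    """
    return softmax(np.asarray(scores, dtype=np.float64), axis=axis)


class _ConvBlock:
    def __init__(self, in_ch, out_ch, rank, rng):
        self.layers = [Conv(in_ch, out_ch, 3, rank, rng), InstanceNorm(out_ch), ReLU(),
                       Conv(out_ch, out_ch, 3, rank, rng), InstanceNorm(out_ch), ReLU()]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet:
    """Segmentation network: (N, in_channels, *spatial) -> per-class scores
    of identical spatial shape. Build with `build_unet`."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        rank, widths = cfg.dims, cfg.encoder_widths
        self.enc = []
        in_ch = cfg.in_channels
        for w in widths:
            self.enc.append(_ConvBlock(in_ch, w, rank, rng))
            in_ch = w
        self.pools = [MaxPool2() for _ in range(cfg.depth)]
        self.ups = []
        self.dec = []
        for lvl in reversed(range(cfg.depth)):
            self.ups.append(UpConv2(widths[lvl + 1], widths[lvl], rank, rng))
            self.dec.append(_ConvBlock(2 * widths[lvl], widths[lvl], rank, rng))
        self.head = Conv(widths[0], cfg.out_classes, 1, rank, rng)

    def params(self) -> list[Param]:
        mods = self.enc + self.ups + self.dec + [self.head]
        return [p for m in mods for p in m.params()]

    def check_input(self, spatial: tuple[int, ...]):
        if len(spatial) != self.cfg.dims:
            raise ShapeError(f"expected {self.cfg.dims}D input, got shape {spatial}")
        div = 2**self.cfg.depth
        for ax, s in enumerate(spatial):
            if s % div:
                raise ShapeError(
                    f"spatial axis {ax} (extent {s}) is not divisible by 2^depth={div}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        self.check_input(x.shape[2:])
        skips = []
        for lvl in range(self.cfg.depth):
            x = self.enc[lvl].forward(x)
            skips.append(x)
            x = self.pools[lvl].forward(x)
        x = self.enc[self.cfg.depth].forward(x)
        self._split = []
        for i, lvl in enumerate(reversed(range(self.cfg.depth))):
            x = self.ups[i].forward(x)
            x = np.concatenate([skips[lvl], x], axis=1)
            self._split.append(skips[lvl].shape[1])
            x = self.dec[i].forward(x)
        return self.head.forward(x)

    def backward(self, dscores: np.ndarray) -> None:
        dy = self.head.backward(dscores.astype(np.float32))
        dskips = {}
        for i, lvl in zip(reversed(range(len(self.dec))), range(self.cfg.depth)):
            dy = self.dec[i].backward(dy)
            c = self._split[i]
            dskips[lvl], dy = dy[:, :c], dy[:, c:]
            dy = self.ups[i].backward(dy)
        dy = self.enc[self.cfg.depth].backward(dy)
        for lvl in reversed(range(self.cfg.depth)):
            dy = self.pools[lvl].backward(dy)
            dy = dy + dskips[lvl]
            dy = self.enc[lvl].backward(dy)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Scores for a single unbatched image/volume: (*spatial) ->
        (out_classes, *spatial)."""
        x = np.asarray(image, dtype=np.float32)[None, None]
        return self.forward(x)[0]

    # --- weights (de)serialization -------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(own, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value = w.astype(np.float32).copy()

    def summary(self) -> str:
        """Textual architecture audit: per-level widths and relations."""
        w = self.cfg.encoder_widths
        lines = [f"{self.cfg.dims}D U-Net  depth={self.cfg.depth}  "
                 f"base_features={self.cfg.base_features}  classes={self.cfg.out_classes}"]
        for lvl, width in enumerate(w):
            tag = "bottleneck" if lvl == self.cfg.depth else f"level {lvl}"
            lines.append(f"  {tag}: {width} feature maps (x2 conv {3}^{self.cfg.dims})")
        lines.append(f"  head: 1x1 conv -> {self.cfg.out_classes} class scores")
        return "\n".join(lines)


def build_unet(cfg: UNetConfig, seed: int = 0) -> UNet:
    return UNet(cfg, seed=seed)
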