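"""Phase-I feature extractor: a small U-Net-style encoder--decoder.

Produces an H x W x C grid of per-pixel deep features from the input
image.  The filter count doubles at each resolution level and the decoder
mirrors the encoder with skip connections; instance normalisation and
ReLU follow every convolution.  Any callable satisfying the same
(image -> feature map) contract can stand in for this default -- the CRF
head only sees the feature map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, ConvBlock, Module


@dataclass
class BackboneConfig:
    """Architecture knobs for the default encoder--decoder.

    ``base_filters`` is the channel count at full resolution (64 at full
    scale; 8 suffices for desk-scale experiments); ``out_features`` is the
    per-pixel feature width C handed to the CRF head and defaults to
    ``base_filters``.  C must be divisible by 4 so the 4-channel groups of
    the sinusoidal positional encoding tile it exactly.
    """

    base_filters: int = 64
    depth: int = 3
    in_channels: int = 1
    out_features: int | None = None

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be at least 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be positive")
        if self.out_features is None:
            self.out_features = self.base_filters
        if self.out_features % 4:
            raise ValueError("out_features must be divisible by 4 for "
                             "positional encoding")


class UNetBackbone(Module):
    def __init__(self, config: BackboneConfig, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.config = config
        self.dtype = dtype
        filters = [config.base_filters * 2 ** level for level in range(config.depth)]
        self.encoders = []
        in_ch = config.in_channels
        for level, f in enumerate(filters):
            block = ConvBlock(in_ch, f, rng, dtype=dtype)
            self.add_module(f"encoder{level}", block)
            self.encoders.append(block)
            in_ch = f
        self.decoders = []
        for level in range(config.depth - 2, -1, -1):
            block = ConvBlock(filters[level + 1] + filters[level], filters[level],
                              rng, dtype=dtype)
            self.add_module(f"decoder{level}", block)
            self.decoders.append(block)
        self.project = self.add_module(
            "project", Conv2d(filters[0], config.out_features, 1, rng,
                              padding=0, dtype=dtype))

    @property
    def out_features(self) -> int:
        return self.config.out_features

    def __call__(self, x: Tensor) -> Tensor:
        """(B, H, W, in_channels) -> per-pixel features (B, H, W, C)."""
        _, h, w, _ = x.shape
        factor = 2 ** (self.config.depth - 1)
        if h % factor or w % factor:
            pad_h = (-h) % factor
            pad_w = (-w) % factor
            raise ValueError(
                f"spatial size ({h}, {w}) must be divisible by {factor}; "
                f"pad by ({pad_h}, {pad_w})")
        skips = []
        for level, block in enumerate(self.encoders):
            x = block(x)
            if level < len(self.encoders) - 1:
                skips.append(x)
                x = ad.avg_pool2d(x)
        for block, skip in zip(self.decoders, reversed(skips)):
            x = ad.upsample_nearest2(x)
            x = block(ad.concat([x, skip], axis=3))
        return self.project(x)


def extract_features(image: np.ndarray, backbone: UNetBackbone) -> np.ndarray:
    """Run the backbone on one image: (H, W) or (H, W, Cin) -> (H, W, C)."""
    image = np.asarray(image, dtype=backbone.dtype)
    if image.ndim == 2:
        image = image[None, :, :, None]
    elif image.ndim == 3:
        image = image[None]
    else:
        raise ValueError("expected a single 2D image, optionally multi-channel")
    return backbone(Tensor(image)).data[0]
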