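"""Recurrent decoder blocks with optional spatial alignment of the hidden state.

The segmentation decoder walks axially through a half-sequence of slices.
At each decoder level a convolutional recurrent (CRNN) cell carries a
hidden feature map from slice to slice; the spatially adjusted variant
(SARC) first warps that hidden state by a learned 6-parameter affine so
that anatomy that drifted between neighbouring slices is re-aligned before
the recurrent update.  The affine is regressed by a localization network
from the pre-upsampling feature map of the current slice together with a
2x-downsampled view of the hidden state.

All blocks are pure functions of their inputs and parameters; hidden
states start as zeros, so at the first step (and whenever the localization
head still emits the identity) SARC and RC behave identically.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, concat
from .nn import functional as F
from .nn.modules import ChannelNorm2d, Conv2d, Linear, Module

IDENTITY_THETA = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]], dtype=np.float32)

__all__ = [
    "IDENTITY_THETA",
    "identity_theta",
    "apply_affine",
    "CrnnCell",
    "LocalizationNet",
    "RcBlock",
    "SarcBlock",
]


def identity_theta(batch: int) -> Tensor:
    return Tensor(np.broadcast_to(IDENTITY_THETA, (batch, 2, 3)).copy())


def apply_affine(features: Tensor, theta: Tensor) -> Tensor:
    """Warp (N,C,H,W) features by per-sample 2x3 affines.

    Coordinates are normalized to [-1, 1] (corner-aligned); samples mapped
    outside the feature map read as zero.
    """
    if not np.all(np.isfinite(theta.data)):
        raise ValueError("apply_affine: non-finite affine parameters")
    return F.affine_warp(features, theta)


class CrnnCell(Module):
    """Recurrent update: new hidden = ReLU(Conv3x3(concat(hidden, x)))."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.conv = Conv2d(2 * channels, channels, 3, rng)

    def init_hidden(self, batch: int, h: int, w: int) -> Tensor:
        return Tensor(np.zeros((batch, self.channels, h, w), dtype=np.float32))

    def forward(self, hidden: Tensor, x: Tensor) -> Tensor:
        if hidden.shape != x.shape:
            raise ValueError(f"crnn_step: hidden {hidden.shape} and input {x.shape} differ")
        return self.conv(concat([hidden, x], axis=1)).relu()


class LocalizationNet(Module):
    """Regress one 6-parameter affine from dense features and the hidden state.

    ``x_pre_up`` (the feature map before the level's upsampling, at half
    resolution) is concatenated with the average-pooled hidden state and
    convolved to ``channels`` maps.  After a per-channel affine
    normalization, every pixel's feature vector passes independently
    through a two-layer perceptron emitting a 6-vector, and the per-pixel
    predictions are reduced by an element-wise max over all pixels.

    The final layer starts at zero weights with an identity bias, so an
    untrained network always emits the identity transform.
    """

    def __init__(self, channels: int, pre_up_channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.conv = Conv2d(pre_up_channels + channels, channels, 3, rng)
        self.norm = ChannelNorm2d(channels)
        self.fc1 = Linear(channels, channels, rng)
        self.fc2 = Linear(channels, 6, rng)
        self.fc2.w.data[:] = 0.0
        self.fc2.b.data[:] = IDENTITY_THETA.ravel()

    def forward(self, x_pre_up: Tensor, hidden: Tensor) -> Tensor:
        pooled = F.avgpool2d(hidden, 2)
        if pooled.shape[2:] != x_pre_up.shape[2:]:
            raise ValueError(
                f"localization_net: pooled hidden {pooled.shape[2:]} does not match "
                f"pre-upsampling features {x_pre_up.shape[2:]}"
            )
        feat = self.norm(self.conv(concat([x_pre_up, pooled], axis=1))).relu()
        n, c, h, w = feat.shape
        pixels = feat.reshape(n, c, h * w).transpose(0, 2, 1)  # (N, HW, C)
        per_pixel = self.fc2(self.fc1(pixels).relu())  # (N, HW, 6)
        theta = per_pixel.max(axis=1)  # element-wise max over pixels
        return theta.reshape(n, 2, 3)


class RcBlock(Module):
    """Recurrent-convolution decoder block (no spatial alignment).

    Applies the CRNN update to the upsampled slice features, then merges
    the encoder skip connection with one further 3x3 convolution.
    """

    def __init__(self, channels: int, skip_channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.cell = CrnnCell(channels, rng)
        self.out_conv = Conv2d(channels + skip_channels, channels, 3, rng)

    def forward(self, x_t: Tensor, hidden: Tensor, skip: Tensor) -> tuple[Tensor, Tensor]:
        new_hidden = self.cell(hidden, x_t)
        out = self.out_conv(concat([new_hidden, skip], axis=1)).relu()
        return out, new_hidden


class SarcBlock(Module):
    """Spatially adjusted recurrent-convolution block.

    The hidden state is warped by the affine predicted from the current
    slice's pre-upsampling features before the recurrent update; the rest
    matches :class:`RcBlock`.
    """

    def __init__(self, channels: int, skip_channels: int, pre_up_channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.cell = CrnnCell(channels, rng)
        self.localization = LocalizationNet(channels, pre_up_channels, rng)
        self.out_conv = Conv2d(channels + skip_channels, channels, 3, rng)

    def forward(
        self, x_t: Tensor, x_pre_up: Tensor, hidden: Tensor, skip: Tensor
    ) -> tuple[Tensor, Tensor, Tensor]:
        theta = self.localization(x_pre_up, hidden)
        warped = apply_affine(hidden, theta)
        new_hidden = self.cell(warped, x_t)
        out = self.out_conv(concat([new_hidden, skip], axis=1)).relu()
        return out, new_hidden, theta
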