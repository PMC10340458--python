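"""Assembly of the four segmentation architectures from shared components.

``unet2d`` and ``unet3d`` are plain encoder-decoder U-Nets (one 3x3
convolution per level, max-pool downsampling, learned transposed-conv
upsampling, 1x1 sigmoid head).  ``rc_unet`` and ``sarc_unet`` share the 2D
encoder but run the decoder as a recurrence over a half-sequence of axial
slices, with an :class:`~sarc_unet.blocks.RcBlock` or
:class:`~sarc_unet.blocks.SarcBlock` at every decoder level, placed after
the transposed convolution and before the skip concatenation.

The volumetric net keeps the axial extent intact (its pooling and
upsampling act in-plane only), so every input slice yields an output
slice in all four models and the slice-wise Dice loss applies uniformly.

The canonical filter plan — per-level widths (32, 64, 128, 256) with a
512-wide bottleneck — fixes the trainable-parameter budget of each
architecture; :func:`count_parameters` exposes the exact accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import RcBlock, SarcBlock
from .nn import Tensor, concat, stack
from .nn import functional as F
from .nn.modules import Conv2d, Conv3d, ConvTranspose2d, ConvTranspose3d, Module, ModuleList

MODEL_NAMES = ("unet2d", "unet3d", "rc_unet", "sarc_unet")

CANONICAL_FILTERS = (32, 64, 128, 256, 512)

# The sigmoid head starts biased toward background: tumor voxels are a tiny
# minority, and beginning near "predict empty" avoids the long flat region
# of the Dice loss that an all-0.5 start produces.
HEAD_BIAS_INIT = -2.0

#: Trainable-parameter budgets of the canonical configurations.
CANONICAL_PARAMETER_COUNTS = {
    "unet2d": 3_832_321,
    "unet3d": 10_100_353,
    "rc_unet": 5_399_521,
    "sarc_unet": 7_841_465,
}

__all__ = [
    "ModelSpec",
    "build_model",
    "count_parameters",
    "MODEL_NAMES",
    "CANONICAL_FILTERS",
    "CANONICAL_PARAMETER_COUNTS",
    "UNet2d",
    "UNet3d",
    "RecurrentUNet",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description: name plus per-level filter widths.

    ``level_filters`` runs from the first encoder level to the bottleneck
    and must be strictly increasing; the decoder mirrors it.
    """

    name: str
    level_filters: tuple[int, ...] = CANONICAL_FILTERS
    in_channels: int = 2

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {self.name!r}; expected one of {MODEL_NAMES}")
        lf = tuple(self.level_filters)
        if len(lf) < 2:
            raise ValueError("level_filters needs at least one level plus a bottleneck")
        if any(b <= a for a, b in zip(lf, lf[1:])):
            raise ValueError("level_filters must increase strictly toward the bottleneck")
        object.__setattr__(self, "level_filters", lf)

    @property
    def encoder_filters(self) -> tuple[int, ...]:
        return self.level_filters[:-1]

    @property
    def bottleneck_filters(self) -> int:
        return self.level_filters[-1]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "level_filters": list(self.level_filters),
            "in_channels": self.in_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(name=d["name"], level_filters=tuple(d["level_filters"]), in_channels=d["in_channels"])


class _Encoder2d(Module):
    def __init__(self, spec: ModelSpec, rng):
        super().__init__()
        convs = []
        cin = spec.in_channels
        for f in spec.encoder_filters:
            convs.append(Conv2d(cin, f, 3, rng))
            cin = f
        self.convs = ModuleList(convs)
        self.bottleneck = Conv2d(cin, spec.bottleneck_filters, 3, rng)

    def forward(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        skips = []
        h = x
        for conv in self.convs:
            h = conv(h).relu()
            skips.append(h)
            h = F.maxpool2d(h, 2)
        return skips, self.bottleneck(h).relu()


class UNet2d(Module):
    """Slice-independent baseline; no pathway between adjacent slices."""

    def __init__(self, spec: ModelSpec, rng):
        super().__init__()
        self.spec = spec
        self.encoder = _Encoder2d(spec, rng)
        ups, convs = [], []
        prev = spec.bottleneck_filters
        for f in reversed(spec.encoder_filters):
            ups.append(ConvTranspose2d(prev, f, rng))
            convs.append(Conv2d(2 * f, f, 3, rng))
            prev = f
        self.ups = ModuleList(ups)
        self.dec_convs = ModuleList(convs)
        self.head = Conv2d(prev, 1, 1, rng, padding=0)
        self.head.b.data[:] = HEAD_BIAS_INIT

    def forward(self, x: Tensor) -> Tensor:
        skips, h = self.encoder(x)
        for up, conv, skip in zip(self.ups, self.dec_convs, reversed(skips)):
            h = up(h)
            h = conv(concat([h, skip], axis=1)).relu()
        return self.head(h).sigmoid()


class UNet3d(Module):
    """Volumetric baseline: 3x3x3 convolutions, in-plane down/upsampling."""

    def __init__(self, spec: ModelSpec, rng):
        super().__init__()
        self.spec = spec
        convs = []
        cin = spec.in_channels
        for f in spec.encoder_filters:
            convs.append(Conv3d(cin, f, 3, rng))
            cin = f
        self.enc_convs = ModuleList(convs)
        self.bottleneck = Conv3d(cin, spec.bottleneck_filters, 3, rng)
        ups, dconvs = [], []
        prev = spec.bottleneck_filters
        for f in reversed(spec.encoder_filters):
            ups.append(ConvTranspose3d(prev, f, rng, kernel=(1, 2, 2)))
            dconvs.append(Conv3d(2 * f, f, 3, rng))
            prev = f
        self.ups = ModuleList(ups)
        self.dec_convs = ModuleList(dconvs)
        self.head = Conv3d(prev, 1, 1, rng, padding=0)
        self.head.b.data[:] = HEAD_BIAS_INIT

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for conv in self.enc_convs:
            h = conv(h).relu()
            skips.append(h)
            h = F.maxpool2d(h, 2)  # acts on the trailing (H, W) axes only
        h = self.bottleneck(h).relu()
        for up, conv, skip in zip(self.ups, self.dec_convs, reversed(skips)):
            h = up(h)
            h = conv(concat([h, skip], axis=1)).relu()
        return self.head(h).sigmoid()


class RecurrentUNet(Module):
    """Shared implementation of the RC and SARC U-Nets.

    Consumes a half-sequence ordered from the tumor-center slice outward;
    each decoder level carries its own hidden state across steps.
    """

    def __init__(self, spec: ModelSpec, rng):
        super().__init__()
        if spec.name not in ("rc_unet", "sarc_unet"):
            raise ValueError(f"RecurrentUNet expects rc_unet or sarc_unet, got {spec.name}")
        self.spec = spec
        self.spatial = spec.name == "sarc_unet"
        self.encoder = _Encoder2d(spec, rng)
        ups, blocks = [], []
        prev = spec.bottleneck_filters
        for f in reversed(spec.encoder_filters):
            ups.append(ConvTranspose2d(prev, f, rng))
            if self.spatial:
                blocks.append(SarcBlock(f, f, prev, rng))
            else:
                blocks.append(RcBlock(f, f, rng))
            prev = f
        self.ups = ModuleList(ups)
        self.blocks = ModuleList(blocks)
        self.head = Conv2d(prev, 1, 1, rng, padding=0)
        self.head.b.data[:] = HEAD_BIAS_INIT

    def init_hidden(self) -> list[None]:
        return [None] * len(self.blocks)

    def step(self, x_t: Tensor, hidden: list) -> tuple[Tensor, list]:
        """One axial step: slice (N,C,H,W) plus per-level hidden states."""
        skips, h = self.encoder(x_t)
        new_hidden = []
        for lvl, (up, block, skip) in enumerate(zip(self.ups, self.blocks, reversed(skips))):
            x_pre = h
            h = up(h)
            state = hidden[lvl]
            if state is None:
                state = block.cell.init_hidden(h.shape[0], h.shape[2], h.shape[3])
            if self.spatial:
                h, state, _ = block(h, x_pre, state, skip)
            else:
                h, state = block(h, state, skip)
            new_hidden.append(state)
        return self.head(h).sigmoid(), new_hidden

    def forward(self, seq: Tensor) -> Tensor:
        """Run a batch of half-sequences (B,L,C,H,W) -> probs (B,L,1,H,W)."""
        b, length = seq.shape[0], seq.shape[1]
        hidden = self.init_hidden()
        outs = []
        for t in range(length):
            x_t = seq.data[:, t]
            out, hidden = self.step(Tensor(x_t) if not seq.requires_grad else _slice_step(seq, t), hidden)
            outs.append(out)
        return stack(outs, axis=1)


def _slice_step(seq: Tensor, t: int) -> Tensor:
    data = seq.data[:, t]

    def backward(g):
        if seq.requires_grad:
            full = np.zeros_like(seq.data)
            full[:, t] = g
            seq._accumulate(full)

    return Tensor._make(data, (seq,), backward)


def build_model(spec: ModelSpec | str, seed: int = 0, rng: np.random.Generator | None = None) -> Module:
    """Instantiate an architecture from its spec (or canonical name)."""
    if isinstance(spec, str):
        spec = ModelSpec(name=spec)
    if rng is None:
        rng = np.random.default_rng(seed)
    if spec.name == "unet2d":
        return UNet2d(spec, rng)
    if spec.name == "unet3d":
        return UNet3d(spec, rng)
    return RecurrentUNet(spec, rng)


def count_parameters(model: Module) -> int:
    """Total element count of all trainable tensors."""
    return model.count_parameters()
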