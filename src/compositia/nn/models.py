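"""Encoder–decoder architectures for localization and segmentation.

`MultiResUNet` regresses a single-channel landmark heatmap from a
3-channel sagittal projection: four MultiRes blocks per side, skip
connections carried through residual paths of 4/3/2/1 conv blocks, a
stride-2 transposed convolution per decoder stage and a final sigmoid.
MultiRes blocks emulate 5×5 and 7×7 receptive fields by chaining 3×3
convolutions and concatenating the three intermediate feature maps,
plus a 1×1 residual shortcut.

`UNet` is a plain 4-level U-Net with double-conv blocks and a channel
softmax head for mutually exclusive tissue classes.

Both require spatial dimensions divisible by 2**4 = 16.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, maxpool2x2, softmax_channels
from .layers import BatchNorm2d, Conv2d, ConvBNReLU, ConvTranspose2x, Module

ALPHA = 1.67  # scale factor between the nominal and actual block width


def _multires_filters(u: int) -> tuple[int, int, int]:
    w = ALPHA * u
    f1 = max(1, int(w * 0.167))
    f2 = max(1, int(w * 0.333))
    f3 = max(1, int(w * 0.5))
    return f1, f2, f3


class MultiResBlock(Module):
    def __init__(self, in_ch: int, u: int, rng: np.random.Generator):
        f1, f2, f3 = _multires_filters(u)
        self.out_ch = f1 + f2 + f3
        self.c1 = ConvBNReLU(in_ch, f1, 3, rng)
        self.c2 = ConvBNReLU(f1, f2, 3, rng)
        self.c3 = ConvBNReLU(f2, f3, 3, rng)
        self.shortcut = Conv2d(in_ch, self.out_ch, 1, rng)
        self.bn_cat = BatchNorm2d(self.out_ch)
        self.bn_out = BatchNorm2d(self.out_ch)

    def forward(self, x):
        a = self.c1(x)
        b = self.c2(a)
        c = self.c3(b)
        cat = self.bn_cat(concat([a, b, c], axis=1))
        y = (cat + self.shortcut(x)).relu()
        return self.bn_out(y)


class ResPathBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv = Conv2d(in_ch, out_ch, 3, rng)
        self.shortcut = Conv2d(in_ch, out_ch, 1, rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        return self.bn((self.conv(x) + self.shortcut(x)).relu())


class ResPath(Module):
    """Skip-connection refinement: `length` residual conv blocks."""

    def __init__(self, in_ch: int, length: int, rng: np.random.Generator):
        blocks = [ResPathBlock(in_ch, in_ch, rng)]
        for _ in range(length - 1):
            blocks.append(ResPathBlock(in_ch, in_ch, rng))
        self.blocks = blocks

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        return x


class MultiResUNet(Module):
    def __init__(self, in_ch: int = 3, base_filters: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        u = base_filters
        self.enc = []
        self.paths = []
        ch = in_ch
        enc_out = []
        for depth in range(4):
            block = MultiResBlock(ch, u * (2 ** depth), rng)
            self.enc.append(block)
            self.paths.append(ResPath(block.out_ch, 4 - depth, rng))
            enc_out.append(block.out_ch)
            ch = block.out_ch
        self.bottleneck = MultiResBlock(ch, u * 16, rng)
        ch = self.bottleneck.out_ch
        self.ups = []
        self.dec = []
        for depth in range(3, -1, -1):
            up = ConvTranspose2x(ch, enc_out[depth], rng)
            self.ups.append(up)
            block = MultiResBlock(2 * enc_out[depth], u * (2 ** depth), rng)
            self.dec.append(block)
            ch = block.out_ch
        self.head = Conv2d(ch, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for block, path in zip(self.enc, self.paths):
            x = block(x)
            skips.append(path(x))
            x = maxpool2x2(x)
        x = self.bottleneck(x)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = concat([up(x), skip], axis=1)
            x = block(x)
        return self.head(x).sigmoid()


class DoubleConv(Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.a = ConvBNReLU(in_ch, out_ch, 3, rng)
        self.b = ConvBNReLU(out_ch, out_ch, 3, rng)

    def forward(self, x):
        return self.b(self.a(x))


class UNet(Module):
    def __init__(self, in_ch: int, n_classes: int, base_filters: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        f = base_filters
        widths = [f, 2 * f, 4 * f, 8 * f]
        self.enc = []
        ch = in_ch
        for w in widths:
            self.enc.append(DoubleConv(ch, w, rng))
            ch = w
        self.bottleneck = DoubleConv(ch, 16 * f, rng)
        ch = 16 * f
        self.ups = []
        self.dec = []
        for w in reversed(widths):
            self.ups.append(ConvTranspose2x(ch, w, rng))
            self.dec.append(DoubleConv(2 * w, w, rng))
            ch = w
        self.head = Conv2d(ch, n_classes, 1, rng)
        self.n_classes = n_classes

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = maxpool2x2(x)
        x = self.bottleneck(x)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = concat([up(x), skip], axis=1)
            x = block(x)
        return softmax_channels(self.head(x))
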