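"""Building blocks of the nested-U segmentation networks.

Three pieces live here:

* :class:`ConvBNReLU` (re-exported from the backend) — the elementary
  3x3 convolution + batch-norm + rectifier unit;
* :class:`SEBlock` — squeeze-and-excitation channel recalibration with a
  residual term: gates ``sigma(W2 . relu(W1 . avgpool(x)))`` scale the
  input channel-wise and the input is added back;
* :class:`RSU` — the residual U-block: an input convolution forming a
  residual branch, a small encoder/decoder with 2x pooling and bilinear
  upsampling (or, for the dilated "F" variant, dilation rates 1/2/4/8 at
  constant resolution), and a final addition onto the residual branch.
  With ``spec.se`` set, the residual branch is passed through an SE block
  before the addition (the SE-RSU).

The SE unit supports two weight layouts.  ``per_channel`` is the
conventional squeeze-and-excitation bottleneck (C -> C/r -> C).  In
``shared_group`` mode one small (group_size -> bottleneck -> group_size)
affine pair is applied to every consecutive channel group with shared
weights, so the parameter overhead is a constant independent of the
block width — 148 parameters for the default (16, 4, bias) layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Module, ModuleList, Parameter, Tensor
from .nn.modules import Conv2d, ConvBNReLU
from .nn.tensor import concat, matmul, maxpool2x2, relu, reshape, sigmoid, tmean, upsample_bilinear

__all__ = ["SEConfig", "StageSpec", "SEBlock", "RSU", "ConvBNReLU"]


@dataclass(frozen=True)
class SEConfig:
    """Shape of the squeeze-and-excitation bottleneck.

    mode: "shared_group" (one shared affine pair per channel group) or
        "per_channel" (conventional C -> C//reduction -> C bottleneck).
    group_size: channels per group in shared_group mode.
    bottleneck: squeezed width (shared_group) / reduction ratio divisor
        is not used here — per_channel derives its width as
        ``max(1, C // reduction)``.
    """

    mode: str = "shared_group"
    group_size: int = 16
    bottleneck: int = 4
    bias: bool = True
    reduction: int = 16  # per_channel mode only

    def __post_init__(self):
        if self.mode not in ("shared_group", "per_channel"):
            raise ValueError(f"unknown SE mode {self.mode!r}")
        if self.bottleneck < 1:
            raise ValueError("SE bottleneck must be >= 1")


@dataclass(frozen=True)
class StageSpec:
    """Declarative description of one residual U-block stage."""

    name: str
    height: int
    in_ch: int
    mid_ch: int
    out_ch: int
    dilated: bool = False
    se: bool = False
    se_config: SEConfig | None = None

    def __post_init__(self):
        if not 4 <= self.height <= 7:
            raise ValueError(f"stage height must be in 4..7, got {self.height}")
        if self.dilated and self.height != 4:
            raise ValueError("the dilated variant is only defined at height 4")
        if self.se and self.se_config is None:
            object.__setattr__(self, "se_config", SEConfig())


class SEBlock(Module):
    """Channel attention: global average pool, bottlenecked affine pair
    (ReLU then logistic), channel-wise rescale plus residual addition."""

    def __init__(self, channels: int, cfg: SEConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        cfg = cfg or SEConfig()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.channels = channels
        if cfg.mode == "shared_group":
            if channels % cfg.group_size:
                raise ValueError(
                    f"shared_group SE needs channels divisible by group_size "
                    f"({channels} % {cfg.group_size} != 0)")
            fin, fout = cfg.group_size, cfg.bottleneck
        else:
            fin, fout = channels, max(1, channels // cfg.reduction)
        self._fin, self._fout = fin, fout

        def init(a, b):
            bound = float(np.sqrt(6.0 / a))
            return Parameter(rng.uniform(-bound, bound, (a, b)).astype(dtype))

        self.w1 = init(fin, fout)
        self.w2 = init(fout, fin)
        if cfg.bias:
            self.b1 = Parameter(np.zeros(fout, dtype=dtype))
            self.b2 = Parameter(np.zeros(fin, dtype=dtype))
        else:
            self.b1 = self.b2 = None

    def gates(self, x: Tensor) -> Tensor:
        """Per-channel gate values in (0, 1), shape (N, C)."""
        n, c = x.shape[:2]
        desc = tmean(x, axis=(2, 3))                      # (N, C) squeeze
        if self.cfg.mode == "shared_group":
            desc = reshape(desc, (n * (c // self._fin), self._fin))
        z = matmul(desc, self.w1)
        if self.b1 is not None:
            z = z + self.b1
        z = matmul(relu(z), self.w2)
        if self.b2 is not None:
            z = z + self.b2
        g = sigmoid(z)
        return reshape(g, (n, c))

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        g = reshape(self.gates(x), (n, c, 1, 1))
        return g * x + x


class RSU(Module):
    """Residual U-block (plain, dilated "F", or SE-augmented).

    Height L gives an encoder of L-1 conv units plus a dilated bottom
    conv; the plain variant pools 2x between encoder levels (so L-2
    poolings) and mirrors them with bilinear upsampling in the decoder,
    while the dilated variant keeps resolution and uses dilation rates
    1, 2, 4, 8 mirrored in the decoder.  The decoder consumes the
    concatenation of the skip and the deeper feature.  The output is
    decoder + residual branch (input conv output, optionally passed
    through an SE block).
    """

    def __init__(self, spec: StageSpec, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        L, cin, mid, cout = spec.height, spec.in_ch, spec.mid_ch, spec.out_ch
        self.conv_in = ConvBNReLU(cin, cout, rng=rng, dtype=dtype)
        if spec.dilated:
            dil = [1, 2, 4]
            bottom_dil = 8
        else:
            dil = [1] * (L - 1)
            bottom_dil = 2
        enc = [ConvBNReLU(cout, mid, dilation=dil[0], rng=rng, dtype=dtype)]
        enc += [ConvBNReLU(mid, mid, dilation=dil[i], rng=rng, dtype=dtype)
                for i in range(1, L - 1)]
        self.encoder = ModuleList(enc)
        self.bottom = ConvBNReLU(mid, mid, dilation=bottom_dil, rng=rng, dtype=dtype)
        dec = [ConvBNReLU(2 * mid, mid, dilation=dil[i], rng=rng, dtype=dtype)
               for i in range(L - 2, 0, -1)]
        dec.append(ConvBNReLU(2 * mid, cout, dilation=dil[0], rng=rng, dtype=dtype))
        self.decoder = ModuleList(dec)
        self.se_block = SEBlock(cout, spec.se_config, rng=rng, dtype=dtype) if spec.se else None

    def forward(self, x: Tensor) -> Tensor:
        spec = self.spec
        xin = self.conv_in(x)
        skips: list[Tensor] = []
        h = xin
        for i, layer in enumerate(self.encoder):
            h = layer(h)
            skips.append(h)
            if not spec.dilated and i < len(self.encoder) - 1:
                h = maxpool2x2(h)
        h = self.bottom(h)
        for i, layer in enumerate(self.decoder):
            skip = skips[len(skips) - 1 - i]
            if not spec.dilated and i > 0:
                h = upsample_bilinear(h, skip.shape[2:])
            h = layer(concat([h, skip], axis=1))
        residual = self.se_block(xin) if self.se_block is not None else xin
        return h + residual

    def mult_adds(self, H: int, W: int) -> int:
        """Informational multiply-accumulate count for an HxW input
        (one MAC per conv weight application; BN/activation ignored)."""
        spec = self.spec
        total = 9 * spec.in_ch * spec.out_ch * H * W
        h, w = H, W
        sizes = []
        cin = spec.out_ch
        for i, _ in enumerate(self.encoder):
            total += 9 * cin * spec.mid_ch * h * w
            sizes.append((h, w))
            cin = spec.mid_ch
            if not spec.dilated and i < len(self.encoder) - 1:
                h, w = (h + 1) // 2, (w + 1) // 2
        total += 9 * spec.mid_ch * spec.mid_ch * h * w
        for i, _ in enumerate(self.decoder):
            h, w = sizes[len(sizes) - 1 - i]
            cout = spec.out_ch if i == len(self.decoder) - 1 else spec.mid_ch
            total += 9 * 2 * spec.mid_ch * cout * h * w
        if self.se_block is not None:
            total += 2 * self.se_block._fin * self.se_block._fout * (
                spec.out_ch // self.se_block._fin)
        return total
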