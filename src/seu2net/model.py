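"""Assembly of residual U-blocks into the two-level nested U network.

The network is an outer U of eleven stages — six encoder stages with 2x
pooling between them and five decoder stages fed by the concatenation of
the upsampled deeper feature and the encoder skip — where every stage is
itself a residual U-block (:class:`~seu2net.blocks.RSU`).  Each decoder
stage and the deepest encoder stage emits a side output (3x3 conv to the
class channels, upsampled to input size); a 1x1 fusion convolution over
the six concatenated side maps produces the final prediction.

Two variants are configured here: ``u2net`` (no channel attention) and
``seu2net``, which carries a squeeze-and-excitation unit on the residual
branch of each of the eight non-dilated stages (the three dilated
height-4 stages are left plain).

Parameter accounting: :func:`count_parameters` reports, per stage and in
total, the number of persistent array elements of the model — trainable
weights and biases plus the batch-norm running statistics.  The
buffer-inclusive convention is what the published complexity tables of
this model family print, and it is the pinned observable here: the
default two-class head gives 44,052,518 for ``u2net`` and 44,053,702 for
``seu2net`` (a difference of 8 x 148 trainable SE parameters).  The
trainable-only count is reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .blocks import RSU, SEConfig, StageSpec
from .nn import Module, ModuleList, Tensor
from .nn.modules import Conv2d
from .nn.tensor import as_tensor, concat, maxpool2x2, upsample_bilinear

__all__ = [
    "ModelConfig",
    "ComplexityReport",
    "default_config",
    "small_config",
    "U2Net",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1

#: (name, height, in, mid, out, dilated) for the full-size network.
_ENCODER_TABLE = [
    ("en1", 7, 3, 32, 64, False),
    ("en2", 6, 64, 32, 128, False),
    ("en3", 5, 128, 64, 256, False),
    ("en4", 4, 256, 128, 512, False),
    ("en5", 4, 512, 256, 512, True),
    ("en6", 4, 512, 256, 512, True),
]
_DECODER_TABLE = [
    ("de5", 4, 1024, 256, 512, True),
    ("de4", 4, 1024, 128, 256, False),
    ("de3", 5, 512, 64, 128, False),
    ("de2", 6, 256, 32, 64, False),
    ("de1", 7, 128, 16, 64, False),
]

#: Reduced-width stage table for CPU-scale smoke runs and tests (same
#: eleven-stage topology, channels cut 8x).
_SMALL_ENCODER = [
    ("en1", 7, 3, 4, 8, False),
    ("en2", 6, 8, 4, 16, False),
    ("en3", 5, 16, 8, 32, False),
    ("en4", 4, 32, 16, 64, False),
    ("en5", 4, 64, 32, 64, True),
    ("en6", 4, 64, 32, 64, True),
]
_SMALL_DECODER = [
    ("de5", 4, 128, 32, 64, True),
    ("de4", 4, 128, 16, 32, False),
    ("de3", 5, 64, 8, 16, False),
    ("de2", 6, 32, 4, 8, False),
    ("de1", 7, 16, 2, 8, False),
]


@dataclass(frozen=True)
class ModelConfig:
    variant: str
    encoder_stages: tuple[StageSpec, ...]
    decoder_stages: tuple[StageSpec, ...]
    input_channels: int = 3
    num_classes: int = 2
    side_kernel: int = 3

    def __post_init__(self):
        if len(self.encoder_stages) != 6 or len(self.decoder_stages) != 5:
            raise ValueError("the nested U has exactly 6 encoder and 5 decoder stages")
        if self.variant not in ("u2net", "seu2net"):
            raise ValueError(f"unknown variant {self.variant!r}")
        n_se = sum(s.se for s in self.stages)
        n_dil = sum(s.dilated for s in self.stages)
        if self.variant == "seu2net":
            if n_se != 11 - n_dil or any(s.se and s.dilated for s in self.stages):
                raise ValueError("seu2net carries SE on exactly the non-dilated stages")
        elif n_se:
            raise ValueError("u2net has no SE stages")

    @property
    def stages(self) -> tuple[StageSpec, ...]:
        return self.encoder_stages + self.decoder_stages


def _build(variant: str, enc_table, dec_table, se_config: SEConfig) -> ModelConfig:
    se_on = variant == "seu2net"

    def mk(row):
        name, height, cin, mid, cout, dilated = row
        use_se = se_on and not dilated
        return StageSpec(name, height, cin, mid, cout, dilated=dilated,
                         se=use_se, se_config=se_config if use_se else None)

    return ModelConfig(
        variant=variant,
        encoder_stages=tuple(mk(r) for r in enc_table),
        decoder_stages=tuple(mk(r) for r in dec_table),
    )


def default_config(variant: str = "seu2net") -> ModelConfig:
    """The full-size published stage table.

    Eight SE-bearing stages (shared-group SE: group 16, bottleneck 4,
    with biases — 148 parameters per unit) and three dilated stages for
    ``seu2net``; all SE flags cleared for ``u2net``.
    """
    return _build(variant, _ENCODER_TABLE, _DECODER_TABLE,
                  SEConfig("shared_group", group_size=16, bottleneck=4, bias=True))


def small_config(variant: str = "seu2net") -> ModelConfig:
    """Reduced-width eleven-stage configuration for CPU-scale training
    smoke runs; SE in per-channel mode (widths here are not multiples of
    the shared group size)."""
    return _build(variant, _SMALL_ENCODER, _SMALL_DECODER,
                  SEConfig("per_channel", reduction=4))


class U2Net(Module):
    """The nested-U segmentation network with side outputs and fusion."""

    def __init__(self, config: ModelConfig, seed: int | None = None, dtype=np.float32):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        enc0 = config.encoder_stages[0]
        if enc0.in_ch != config.input_channels:
            raise ValueError("first encoder stage must accept input_channels")
        self.encoder = ModuleList(RSU(s, rng=rng, dtype=dtype) for s in config.encoder_stages)
        self.decoder = ModuleList(RSU(s, rng=rng, dtype=dtype) for s in config.decoder_stages)
        # side heads: decoder stages shallow->deep (de1..de5) then en6
        side_sources = [config.decoder_stages[-1 - i].out_ch for i in range(5)]
        side_sources.append(config.encoder_stages[-1].out_ch)
        self.sides = ModuleList(
            Conv2d(c, config.num_classes, config.side_kernel, rng=rng, dtype=dtype)
            for c in side_sources
        )
        self.fuse = Conv2d(6 * config.num_classes, config.num_classes, 1, rng=rng, dtype=dtype)

    def forward(self, x) -> tuple[Tensor, list[Tensor]]:
        """Return (fused logits, six side logit maps), all at input size."""
        x = as_tensor(x)
        size = x.shape[2:]
        skips: list[Tensor] = []
        h = x
        for i, stage in enumerate(self.encoder):
            h = stage(h)
            skips.append(h)
            if i < len(self.encoder) - 1:
                h = maxpool2x2(h)
        deep = skips[-1]                      # en6 output
        dec_outs: list[Tensor] = []
        h = deep
        for i, stage in enumerate(self.decoder):
            skip = skips[len(skips) - 2 - i]
            h = stage(concat([upsample_bilinear(h, skip.shape[2:]), skip], axis=1))
            dec_outs.append(h)
        # sides: de1 (full res) .. de5, en6
        sources = dec_outs[::-1] + [deep]
        side_maps = [
            upsample_bilinear(conv(src), size) for conv, src in zip(self.sides, sources)
        ]
        fused = self.fuse(concat(side_maps, axis=1))
        return fused, side_maps

    def stage_modules(self) -> dict[str, RSU]:
        names = [s.name for s in self.config.stages]
        return dict(zip(names, list(self.encoder) + list(self.decoder)))


@dataclass
class ComplexityReport:
    """Structural audit of a built network.

    ``per_stage_params`` and ``total_params`` count persistent array
    elements (trainable + batch-norm running statistics, the published
    accounting convention); ``trainable_params`` counts trainable only;
    ``total_mult_adds`` is an informational MAC count at the given input
    size (one multiply-accumulate per conv weight application).
    """

    variant: str
    per_stage_params: dict[str, int]
    side_and_fusion_params: int
    total_params: int
    trainable_params: int
    total_mult_adds: int
    input_size: int

    def __post_init__(self):
        assert self.total_params == sum(self.per_stage_params.values()) + self.side_and_fusion_params

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _persistent_size(module: Module) -> int:
    n = sum(p.data.size for p in module.parameters())
    n += sum(b.size for _, b in module.named_buffers())
    return int(n)


def count_parameters(model: U2Net, input_size: int = 512) -> ComplexityReport:
    per_stage = {name: _persistent_size(m) for name, m in model.stage_modules().items()}
    heads = sum(_persistent_size(m) for m in model.sides) + _persistent_size(model.fuse)
    trainable = sum(p.data.size for p in model.parameters())
    mult_adds = 0
    h = w = input_size
    for stage in model.encoder:
        mult_adds += stage.mult_adds(h, w)
        h, w = (h + 1) // 2, (w + 1) // 2
    sizes = []
    h = w = input_size
    for _ in range(5):
        sizes.append((h, w))
        h, w = (h + 1) // 2, (w + 1) // 2
    for stage, (sh, sw) in zip(model.decoder, sizes[::-1]):
        mult_adds += stage.mult_adds(sh, sw)
    ncls = model.config.num_classes
    for conv, (sh, sw) in zip(model.sides, sizes[::-1] + [sizes[-1]]):
        k = model.config.side_kernel
        mult_adds += k * k * conv.weight.data.shape[1] * ncls * sh * sw
    mult_adds += 6 * ncls * ncls * input_size * input_size
    return ComplexityReport(
        variant=model.config.variant,
        per_stage_params=per_stage,
        side_and_fusion_params=int(heads),
        total_params=int(sum(per_stage.values()) + heads),
        trainable_params=int(trainable),
        total_mult_adds=int(mult_adds),
        input_size=input_size,
    )


def save_checkpoint(model: U2Net, path, meta: dict | None = None) -> None:
    """Single-file weight map keyed by stage and layer name, versioned."""
    state = model.state_dict()
    header = {"version": CHECKPOINT_VERSION, "variant": model.config.variant,
              "num_classes": model.config.num_classes, "meta": meta or {}}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(model: U2Net, path) -> dict:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header.get('version')}")
        state = {k: data[k] for k in data.files if k != "__header__"}
    model.load_state_dict(state)
    return header
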