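"""MAEFNet: a lightweight encoder-decoder pectoral-muscle segmenter.

The encoder is MobileNetV3-Large truncated so that its deepest feature map is
at output stride 16 instead of 32 (the would-be stride-32 stage is kept with
its stride forced to 1 only if the parameter budget allows, otherwise
trimmed).  The decoder refines three encoder taps (strides 4/8/16) with a
channel Attention Refinement Module (ARM) followed by a Coordinate Attention
Module (CAM), fuses them progressively with Feature Fusion Modules (FFM), and
projects to two classes (background, muscle) at full input resolution.

The whole model stays within a 1.51 M trainable-parameter budget.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import core
from .nn.core import Tensor
from .nn.modules import (BatchNorm2d, Conv2d, ConvBNAct, InvertedResidual,
                         Module, Sequential, count_parameters, seed_init)

# MobileNetV3-Large inverted-residual settings:
# (kernel, expanded, out, use_se, activation, stride)
_MBV3_LARGE = [
    (3, 16, 16, False, "relu", 1),
    (3, 64, 24, False, "relu", 2),      # -> stride 4
    (3, 72, 24, False, "relu", 1),
    (5, 72, 40, True, "relu", 2),       # -> stride 8
    (5, 120, 40, True, "relu", 1),
    (5, 120, 40, True, "relu", 1),
    (3, 240, 80, False, "hardswish", 2),  # -> stride 16
    (3, 200, 80, False, "hardswish", 1),
    (3, 184, 80, False, "hardswish", 1),
    (3, 184, 80, False, "hardswish", 1),
    (3, 480, 112, True, "hardswish", 1),
    (3, 672, 112, True, "hardswish", 1),
    (5, 672, 160, True, "hardswish", 2),  # would-be stride 32; forced to 1
]
_TAP4_IDX = 2   # after this block the map is at stride 4 (24 ch)
_TAP8_IDX = 5   # stride 8 (40 ch)
_FINAL_STAGE_START = 12  # first block of the would-be stride-32 stage

PARAM_BUDGET = 1_510_000


@dataclass
class MAEFNetConfig:
    encoder_variant: str = "mobilenetv3-large-pruned"
    arm_channels: tuple[int, int, int] = (32, 64, 128)  # taps s4, s8, s16
    cam_reduction: int = 16
    cam_min_channels: int = 8
    ffm_channels: tuple[int, int] = (64, 32)  # deep fusion, shallow fusion
    num_classes: int = 2
    input_channels: int = 3
    param_budget: int = PARAM_BUDGET
    init_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MAEFNetConfig":
        d = dict(d)
        for k in ("arm_channels", "ffm_channels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


class PrunedMobileNetV3(Module):
    """MobileNetV3-Large feature extractor truncated at output stride 16.

    ``final_stage_blocks`` counts how many blocks of the would-be stride-32
    stage are retained (each with stride forced to 1); everything after,
    including the classifier head, is discarded.
    """

    def __init__(self, in_channels: int = 3, final_stage_blocks: int = 1):
        super().__init__()
        self.stem = ConvBNAct(in_channels, 16, kernel=3, stride=2,
                              act="hardswish")
        blocks: list[Module] = []
        settings = _MBV3_LARGE[:_FINAL_STAGE_START + final_stage_blocks]
        in_ch = 16
        for i, (k, exp, out, se, act, stride) in enumerate(settings):
            if i >= _FINAL_STAGE_START:
                stride = 1  # downsampling ratio capped at 16
            blocks.append(InvertedResidual(in_ch, exp, out, k, stride, se, act))
            in_ch = out
        self.blocks = blocks
        self.tap_channels = (
            _MBV3_LARGE[_TAP4_IDX][2],
            _MBV3_LARGE[_TAP8_IDX][2],
            in_ch,
        )

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Return feature maps at strides 4, 8 and 16."""
        x = self.stem(x)
        taps = {}
        for i, block in enumerate(self.blocks):
            x = block(x)
            if i == _TAP4_IDX:
                taps[4] = x
            elif i == _TAP8_IDX:
                taps[8] = x
        taps[16] = x
        return taps[4], taps[8], taps[16]


class ARM(Module):
    """Attention Refinement Module.

    X' = ReLU(BN(conv3x3(X))); the channel gate is
    sigmoid(BN(conv1x1(GAP(X')))) and the output is X' scaled by the gate.
    """

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.reduce = ConvBNAct(in_ch, out_ch, kernel=3, act="relu")
        self.gate_conv = Conv2d(out_ch, out_ch, 1)
        self.gate_bn = BatchNorm2d(out_ch)

    def channel_weights(self, x: Tensor) -> tuple[Tensor, Tensor]:
        xr = self.reduce(x)
        s = core.mean(xr, (2, 3), keepdims=True)
        alpha = core.sigmoid(self.gate_bn(self.gate_conv(s)))
        return xr, alpha

    def forward(self, x: Tensor) -> Tensor:
        xr, alpha = self.channel_weights(x)
        return core.mul(xr, alpha)


class CAM(Module):
    """Coordinate Attention Module.

    Height- and width-pooled descriptors are concatenated along the spatial
    axis, mixed by a shared 1x1 conv (BN + hard-swish), split back, and turned
    into directional sigmoid gates applied multiplicatively to the input.
    """

    def __init__(self, ch: int, reduction: int = 16, min_channels: int = 8):
        super().__init__()
        mid = max(min_channels, ch // reduction)
        self.mix = ConvBNAct(ch, mid, kernel=1, act="hardswish")
        self.to_h = Conv2d(mid, ch, 1, bias=True)
        self.to_w = Conv2d(mid, ch, 1, bias=True)

    def directional_weights(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h, w = x.shape[2], x.shape[3]
        pool_h = core.mean(x, (3,), keepdims=True)            # N,C,H,1
        pool_w = core.swap_hw(core.mean(x, (2,), keepdims=True))  # N,C,W,1
        f = self.mix(core.concat([pool_h, pool_w], axis=2))   # N,mid,H+W,1
        f_h = core.narrow(f, 2, 0, h)
        f_w = core.narrow(f, 2, h, w)
        alpha_h = core.sigmoid(self.to_h(f_h))                # N,C,H,1
        alpha_w = core.swap_hw(core.sigmoid(self.to_w(f_w)))  # N,C,1,W
        return alpha_h, alpha_w

    def forward(self, x: Tensor) -> Tensor:
        alpha_h, alpha_w = self.directional_weights(x)
        return core.mul(core.mul(x, alpha_h), alpha_w)


class FFM(Module):
    """Feature Fusion Module.

    Channel-concatenates two same-resolution maps, reduces with a 3x3
    conv-BN-ReLU to X', and adds back a channel-gated copy:
    out = X' + X' * sigmoid(conv1x1(ReLU(conv1x1(GAP(X'))))).
    """

    def __init__(self, in_ch: int, out_ch: int, gate_reduction: int = 4):
        super().__init__()
        mid = max(8, out_ch // gate_reduction)
        self.reduce = ConvBNAct(in_ch, out_ch, kernel=3, act="relu")
        self.gate1 = Conv2d(out_ch, mid, 1, bias=True)
        self.gate2 = Conv2d(mid, out_ch, 1, bias=True)

    def forward(self, x1: Tensor, x2: Tensor) -> Tensor:
        if x1.shape[2:] != x2.shape[2:]:
            raise ValueError(
                f"FFM inputs must share spatial size, got {x1.shape} vs {x2.shape}")
        xr = self.reduce(core.concat([x1, x2], axis=1))
        s = core.mean(xr, (2, 3), keepdims=True)
        alpha = core.sigmoid(self.gate2(core.relu(self.gate1(s))))
        return core.add(xr, core.mul(xr, alpha))


class MAEFNet(Module):
    def __init__(self, config: MAEFNetConfig | None = None):
        super().__init__()
        self.config = config or MAEFNetConfig()
        cfg = self.config
        seed_init(cfg.init_seed)
        # keep the forced-stride final-stage block only if the whole model
        # still fits the parameter budget; otherwise trim it (budget is the
        # arbiter of the pruning boundary)
        for final_stage_blocks in (1, 0):
            self._build(final_stage_blocks)
            if count_parameters(self) <= cfg.param_budget:
                self.final_stage_blocks = final_stage_blocks
                break
        else:
            raise ValueError(
                "decoder widths exceed the parameter budget even with the "
                "encoder trimmed to its stride-16 stage")

    def _build(self, final_stage_blocks: int) -> None:
        cfg = self.config
        seed_init(cfg.init_seed)
        self.encoder = PrunedMobileNetV3(cfg.input_channels,
                                         final_stage_blocks)
        c4, c8, c16 = self.encoder.tap_channels
        a4, a8, a16 = cfg.arm_channels
        self.arm4 = ARM(c4, a4)
        self.arm8 = ARM(c8, a8)
        self.arm16 = ARM(c16, a16)
        self.cam4 = CAM(a4, cfg.cam_reduction, cfg.cam_min_channels)
        self.cam8 = CAM(a8, cfg.cam_reduction, cfg.cam_min_channels)
        self.cam16 = CAM(a16, cfg.cam_reduction, cfg.cam_min_channels)
        f_deep, f_shallow = cfg.ffm_channels
        self.ffm_deep = FFM(a8 + a16, f_deep)
        self.ffm_shallow = FFM(a4 + f_deep, f_shallow)
        self.head = Conv2d(f_shallow, cfg.num_classes, 1, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        side_h, side_w = x.shape[2], x.shape[3]
        if side_h % 16 or side_w % 16:
            raise ValueError("input sides must be divisible by 16")
        t4, t8, t16 = self.encoder(x)
        e4 = self.cam4(self.arm4(t4))
        e8 = self.cam8(self.arm8(t8))
        e16 = self.cam16(self.arm16(t16))
        up16 = core.bilinear_resize(e16, e8.shape[2], e8.shape[3])
        f8 = self.ffm_deep(e8, up16)
        up8 = core.bilinear_resize(f8, e4.shape[2], e4.shape[3])
        f4 = self.ffm_shallow(e4, up8)
        logits = self.head(f4)
        return core.bilinear_resize(logits, side_h, side_w)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Map a 2-D uint8 grayscale image to a (3, H, W) float32 array in
    [-1, 1] (grayscale replicated over the RGB stem)."""
    x = image.astype(np.float32) / 127.5 - 1.0
    return np.repeat(x[None], 3, axis=0)


def predict_mask(model: MAEFNet, image: np.ndarray) -> np.ndarray:
    """Segment one grayscale image; returns a {0,1} uint8 mask."""
    model.eval()
    with core.no_grad():
        logits = model(Tensor(normalize_image(image)[None]))
    return (logits.data[0, 1] > logits.data[0, 0]).astype(np.uint8)


CHECKPOINT_VERSION = 1


def save_checkpoint(model: MAEFNet, path) -> None:
    """Serialize config + weights to a single .npz file."""
    state = model.state_dict()
    meta = json.dumps({
        "format_version": CHECKPOINT_VERSION,
        "config": model.config.to_dict(),
        "final_stage_blocks": model.final_stage_blocks,
    })
    np.savez_compressed(path, __meta__=np.frombuffer(
        meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> MAEFNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta['format_version']}")
        model = MAEFNet(MAEFNetConfig.from_dict(meta["config"]))
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__meta__"})
    return model
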