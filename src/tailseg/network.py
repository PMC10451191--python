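"""Weighted-attention residual U-Net (WA-ResUNet) assembly.

Encoder: a 3x3 stride-2 convolution stem followed by 2x2 max pooling,
then four stages of ResNet50-style bottleneck residual blocks (3, 4, 6, 3
blocks; stage strides 1, 2, 2, 2; expansion 4), each block optionally
carrying a normalized channel-attention gate on its residual branch after
the third convolution.  Skip features (stem output and the first three
stage outputs) pass through an optional spatial-attention bridge before
being concatenated into the decoder.  The decoder has four up-steps
(x2 upsample, 3x3 convolution, concat bridged skip, two 3x3
convolution+norm+activation layers) plus a final up-step back to input
resolution and a 1x1 projection to C+1 score planes (background
explicit).  Total downsampling is x32, so input extents must be
divisible by 32.

Input intensities are expected in [0, 1]; predicted label = argmax over
score planes, ties broken toward the lower label index.
"""

from __future__ import annotations

import io
import json
import zlib
from dataclasses import asdict, dataclass
from typing import Tuple

import numpy as np

from .errors import ConfigError, DataError
from .nn import (BatchNorm2d, ChannelAttention, Conv2d, ConvTranspose2x,
                 Module, ModuleList, SpatialAttention, tape)

UPSAMPLE_MODES = ("bilinear", "transposed_conv")
EXPANSION = 4


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    num_foreground_classes: int = 4
    stage_blocks: Tuple[int, int, int, int] = (3, 4, 6, 3)
    base_width: int = 64
    use_channel_attention: bool = True
    use_spatial_bridge: bool = True
    upsample_mode: str = "bilinear"
    nam_style: bool = False

    def validate(self) -> None:
        problems = []
        if self.in_channels < 1:
            problems.append("in_channels must be >= 1")
        if self.num_foreground_classes < 1:
            problems.append("num_foreground_classes must be >= 1")
        if len(self.stage_blocks) != 4 or any(b < 1 for b in self.stage_blocks):
            problems.append("stage_blocks must be 4 integers, all >= 1")
        if self.base_width < 4:
            problems.append("base_width must be >= 4")
        if self.upsample_mode not in UPSAMPLE_MODES:
            problems.append(f"upsample_mode must be one of {UPSAMPLE_MODES}")
        if problems:
            raise ConfigError("; ".join(problems))


class _ConvBNAct(Module):
    def __init__(self, cin, cout, k, rng, stride=1):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, rng, stride=stride, padding=k // 2,
                           bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return tape.relu(self.bn(self.conv(x)))


class Bottleneck(Module):
    """1x1 -> 3x3 -> 1x1 residual block with an optional channel gate.

    The gate multiplies the residual branch before the shortcut addition,
    so the shortcut signal is never attenuated.
    """

    def __init__(self, cin, mid, cout, stride, use_ca, nam_style, rng):
        super().__init__()
        self.conv1 = Conv2d(cin, mid, 1, rng, bias=False)
        self.bn1 = BatchNorm2d(mid)
        self.conv2 = Conv2d(mid, mid, 3, rng, stride=stride, padding=1,
                            bias=False)
        self.bn2 = BatchNorm2d(mid)
        self.conv3 = Conv2d(mid, cout, 1, rng, bias=False)
        self.bn3 = BatchNorm2d(cout)
        self.ca = ChannelAttention(cout, nam_style=nam_style) if use_ca else None
        if cin != cout or stride != 1:
            self.short_conv = Conv2d(cin, cout, 1, rng, stride=stride,
                                     bias=False)
            self.short_bn = BatchNorm2d(cout)
        else:
            self.short_conv = None

    def forward(self, x):
        h = tape.relu(self.bn1(self.conv1(x)))
        h = tape.relu(self.bn2(self.conv2(h)))
        h = self.bn3(self.conv3(h))
        if self.ca is not None:
            h = self.ca(h)
        s = x if self.short_conv is None else self.short_bn(self.short_conv(x))
        return tape.relu(tape.add(h, s))


class UpBlock(Module):
    """Decoder step: x2 up, 3x3 conv, concat bridged skip, two fuse convs."""

    def __init__(self, cin, skip_ch, cout, mode, use_bridge, rng):
        super().__init__()
        self.mode = mode
        if mode == "bilinear":
            self.upconv = _ConvBNAct(cin, cout, 3, rng)
        else:
            self.tconv = ConvTranspose2x(cin, cout, rng, bias=False)
            self.tbn = BatchNorm2d(cout)
        self.bridge = SpatialAttention(rng) if use_bridge else None
        self.fuse1 = _ConvBNAct(cout + skip_ch, cout, 3, rng)
        self.fuse2 = _ConvBNAct(cout, cout, 3, rng)

    def _up(self, x):
        if self.mode == "bilinear":
            return self.upconv(tape.upsample_bilinear2x(x))
        return tape.relu(self.tbn(self.tconv(x)))

    def forward(self, x, skip):
        x = self._up(x)
        s = self.bridge(skip) if self.bridge is not None else skip
        return self.fuse2(self.fuse1(tape.concat([s, x], axis=1)))


class WAResUNet(Module):
    """The assembled encoder-decoder; holds its config and build seed."""

    def __init__(self, config: NetworkConfig, seed: int):
        super().__init__()
        config.validate()
        object.__setattr__(self, "config", config)
        object.__setattr__(self, "seed", int(seed))
        rng = np.random.default_rng(seed)
        b = config.base_width
        C = config.num_foreground_classes

        self.stem = _ConvBNAct(config.in_channels, b, 3, rng, stride=2)

        mids = (b, 2 * b, 4 * b, 8 * b)
        outs = tuple(EXPANSION * m for m in mids)
        strides = (1, 2, 2, 2)
        stages = []
        cin = b
        for si in range(4):
            blocks = []
            for bi in range(config.stage_blocks[si]):
                blocks.append(Bottleneck(
                    cin, mids[si], outs[si],
                    stride=strides[si] if bi == 0 else 1,
                    use_ca=config.use_channel_attention,
                    nam_style=config.nam_style, rng=rng))
                cin = outs[si]
            stages.append(ModuleList(blocks))
        self.stages = ModuleList(stages)

        # decoder: skips are stem (b @ /2) and stage outputs 1..3
        skip_chs = (outs[2], outs[1], outs[0], b)
        dec_outs = (outs[2] // 2, outs[1] // 2, outs[0] // 2, b)
        ups = []
        cin = outs[3]
        for skip_ch, cout in zip(skip_chs, dec_outs):
            ups.append(UpBlock(cin, skip_ch, cout, config.upsample_mode,
                               config.use_spatial_bridge, rng))
            cin = cout
        self.ups = ModuleList(ups)
        self.final_up = _ConvBNAct(cin, b, 3, rng)
        self.head = Conv2d(b, C + 1, 1, rng, bias=True)

    # -- forward -------------------------------------------------------
    def forward(self, x):
        x = tape.as_tensor(x)
        s0 = self.stem(x)                    # b @ /2
        h = tape.maxpool2x(s0)               # b @ /4
        skips = []
        for stage in self.stages:
            for block in stage:
                h = block(h)
            skips.append(h)
        # skips: outs[0] @ /4, outs[1] @ /8, outs[2] @ /16, outs[3] @ /32
        h = skips[3]
        for up, skip in zip(self.ups, (skips[2], skips[1], skips[0], s0)):
            h = up(h, skip)
        # final skip-free up-step is always interpolation + 3x3 conv
        h = self.final_up(tape.upsample_bilinear2x(h))
        return self.head(h)

    # -- introspection -------------------------------------------------
    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def parameter_checksum(self) -> int:
        buf = io.BytesIO()
        for name, p in sorted(self.named_parameters()):
            buf.write(name.encode())
            buf.write(np.ascontiguousarray(p.data).tobytes())
        return zlib.crc32(buf.getvalue())


def build_model(config: NetworkConfig, seed: int) -> WAResUNet:
    """Deterministically build a model; same (config, seed) => identical state."""
    return WAResUNet(config, seed)


def ca_res_block_forward(values, block: Bottleneck) -> np.ndarray:
    """Evaluate one bottleneck block in inference mode on a raw array."""
    arr = np.asarray(values, dtype=np.float64)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    was_training = block.training
    block.eval()
    with tape.no_grad():
        out = block(tape.Tensor(arr)).data
    block.train(was_training)
    return out[0] if squeeze else out


def sa_bridge_forward(values, bridge: SpatialAttention | None) -> np.ndarray:
    """Evaluate a spatial-attention bridge (identity when disabled)."""
    arr = np.asarray(values, dtype=np.float64)
    if bridge is None:
        return arr.copy()
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    with tape.no_grad():
        out = bridge(tape.Tensor(arr)).data
    return out[0] if squeeze else out


def model_forward(images, model: WAResUNet) -> np.ndarray:
    """Inference-mode forward: (B, H, W) or (B, 1, H, W) -> (B, C+1, H, W)."""
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[:, None]
    if arr.ndim != 4:
        raise DataError("images must be (B, H, W) or (B, C, H, W)")
    H, W = arr.shape[2:]
    if H % 32 or W % 32:
        raise DataError(
            f"input extents {H}x{W} are not divisible by 32; resize or pad "
            f"to the nearest multiple of 32 before inference")
    was_training = model.training
    model.eval()
    with tape.no_grad():
        out = model(tape.Tensor(arr.astype(model.dtype(), copy=False))).data
    model.train(was_training)
    return out


def predict_mask(images, model: WAResUNet) -> np.ndarray:
    """Argmax labels from score maps; ties break toward the lower label."""
    scores = model_forward(images, model)
    return np.argmax(scores, axis=1)


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_checkpoint(model: WAResUNet, path) -> None:
    meta = json.dumps({"config": asdict(model.config), "seed": model.seed})
    state = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path, expect_config: NetworkConfig | None = None) -> WAResUNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[len("state/"):]: z[k] for k in z.files if k.startswith("state/")}
    cfg_dict = meta["config"]
    cfg_dict["stage_blocks"] = tuple(cfg_dict["stage_blocks"])
    config = NetworkConfig(**cfg_dict)
    if expect_config is not None and config != expect_config:
        raise ConfigError("checkpoint config does not match the expected config")
    model = build_model(config, meta["seed"])
    model.load_state_dict(state)
    return model
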