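"""Standalone attention-gate transforms on feature maps.

Two gates are provided as pure functions of a feature map and an explicit
parameter state, so they can be oracle-tested independently of the
network that embeds them:

* the normalized channel gate — per-channel batch normalisation followed
  by a sigmoid of the normalised signal scaled by the channel's scale
  factor alpha and its share W_c = alpha_c / sum(alpha) of all scales;
* the spatial gate — a sigmoid of a 7x7 convolution (zero padding 3) over
  the stacked per-pixel channel-mean and channel-max planes.

Both gates return the input multiplied elementwise by a map with values
strictly inside (0, 1).  Inputs may be (C, H, W) or batched (B, C, H, W).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .nn import tape


@dataclass
class ChannelAttentionState:
    """Per-channel gate parameters and normalisation statistics."""

    scale: np.ndarray        # alpha, shape (C,)
    shift: np.ndarray        # beta, shape (C,)
    mean: np.ndarray         # per-channel mean, shape (C,)
    variance: np.ndarray     # per-channel variance, shape (C,)
    epsilon: float = 1e-5

    def __post_init__(self):
        self.scale = np.asarray(self.scale, dtype=np.float64)
        self.shift = np.asarray(self.shift, dtype=np.float64)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.variance = np.asarray(self.variance, dtype=np.float64)
        if not (self.scale.shape == self.shift.shape == self.mean.shape
                == self.variance.shape) or self.scale.ndim != 1:
            raise DataError("channel-attention state vectors must share shape (C,)")
        if np.any(self.variance < 0):
            raise DataError("variance must be non-negative")
        if self.epsilon <= 0:
            raise DataError("epsilon must be positive")


@dataclass
class SpatialAttentionState:
    """7x7 kernel (2 input planes -> 1 output plane) and bias."""

    kernel: np.ndarray
    bias: float = 0.0

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if self.kernel.shape == (2, 7, 7):
            self.kernel = self.kernel[None]
        if self.kernel.shape != (1, 2, 7, 7):
            raise DataError(
                f"spatial kernel must map 2 planes to 1 with a 7x7 extent, "
                f"got shape {self.kernel.shape}")
        self.bias = float(self.bias)


def normalized_channel_weights(scale) -> np.ndarray:
    """W_c = alpha_c / sum_k alpha_k; the weights sum to one."""
    scale = np.asarray(scale, dtype=np.float64)
    total = scale.sum()
    if abs(total) < 1e-300 or not np.isfinite(total):
        raise DataError("degenerate channel scales: sum(alpha) is zero")
    return scale / total


def _batched(values):
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 3:
        return values[None], True
    if values.ndim == 4:
        return values, False
    raise DataError(f"feature map must be 3- or 4-dimensional, got {values.ndim}")


def channel_attention(values, state: ChannelAttentionState,
                      nam_style: bool = False) -> np.ndarray:
    """Gate each channel by its normalised-scale sigmoid response.

    gate_c = sigmoid(W_c * alpha_c * xhat + beta_c) with
    xhat = (x - mean_c) / sqrt(variance_c + epsilon); output = input * gate.
    With ``nam_style`` the shift is scaled too:
    gate_c = sigmoid(W_c * (alpha_c * xhat + beta_c)).
    """
    x, squeeze = _batched(values)
    c = x.shape[1]
    if state.scale.shape[0] != c:
        raise DataError(
            f"channel mismatch: feature map has {c} channels, state has "
            f"{state.scale.shape[0]}")
    w = normalized_channel_weights(state.scale)
    sh = (1, c, 1, 1)
    xhat = (x - state.mean.reshape(sh)) / np.sqrt(
        state.variance.reshape(sh) + state.epsilon)
    if nam_style:
        pre = w.reshape(sh) * (state.scale.reshape(sh) * xhat
                               + state.shift.reshape(sh))
    else:
        pre = (w * state.scale).reshape(sh) * xhat + state.shift.reshape(sh)
    out = x * (1.0 / (1.0 + np.exp(-pre)))
    return out[0] if squeeze else out


def spatial_attention(values, state: SpatialAttentionState) -> np.ndarray:
    """Gate each pixel by a 7x7 response over channel mean/max planes.

    map = sigmoid(conv7x7(stack[mean_c(x), max_c(x)]) + bias), zero padding
    3 so the map matches the input's H x W; output = input * map broadcast
    over channels.
    """
    x, squeeze = _batched(values)
    avg = x.mean(axis=1, keepdims=True)
    mx = x.max(axis=1, keepdims=True)
    planes = np.concatenate([avg, mx], axis=1)
    with tape.no_grad():
        pre = tape.conv2d(tape.Tensor(planes), tape.Tensor(state.kernel),
                          tape.Tensor(np.array([state.bias])), padding=3).data
    out = x * (1.0 / (1.0 + np.exp(-pre)))
    return out[0] if squeeze else out
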