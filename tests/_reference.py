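"""Forward-only plain residual U-Net reference.

Recomputes the attention-free network forward pass from a model's
``state_dict`` using scipy/scikit-image building blocks and explicit
loops — an independent code path from the package's tape-based modules.
Inference-mode semantics: batch normalisation uses running statistics.
"""

import numpy as np
from scipy.signal import correlate2d
from skimage.measure import block_reduce

EXPANSION = 4


def conv(x, w, b=None, stride=1, pad=0):
    """x: (C, H, W); w: (O, C, k, k)."""
    C, H, W = x.shape
    O = w.shape[0]
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    k = w.shape[2]
    oh = (H + 2 * pad - k) // stride + 1
    ow = (W + 2 * pad - k) // stride + 1
    out = np.zeros((O, oh, ow))
    for o in range(O):
        acc = np.zeros((xp.shape[1] - k + 1, xp.shape[2] - k + 1))
        for c in range(C):
            acc += correlate2d(xp[c], w[o, c], mode="valid")
        out[o] = acc[::stride, ::stride]
        if b is not None:
            out[o] += b[o]
    return out


def bn(x, sd, prefix, eps=1e-5):
    g = sd[prefix + "gamma"][:, None, None]
    b = sd[prefix + "beta"][:, None, None]
    rm = sd[prefix + "running_mean"][:, None, None]
    rv = sd[prefix + "running_var"][:, None, None]
    return (x - rm) / np.sqrt(rv + eps) * g + b


def relu(x):
    return np.maximum(x, 0.0)


def conv_bn_act(x, sd, prefix, stride=1):
    w = sd[prefix + "conv.weight"]
    pad = w.shape[2] // 2
    return relu(bn(conv(x, w, stride=stride, pad=pad), sd, prefix + "bn."))


def maxpool2(x):
    return block_reduce(x, (1, 2, 2), np.max)


def upsample2(x):
    """x2 bilinear upsampling, half-pixel centres, clamped edges."""
    C, H, W = x.shape
    out = np.zeros((C, 2 * H, 2 * W))
    for i in range(2 * H):
        si = min(max((i + 0.5) / 2 - 0.5, 0), H - 1)
        i0, fi = int(np.floor(si)), si - int(np.floor(si))
        i1 = min(i0 + 1, H - 1)
        for j in range(2 * W):
            sj = min(max((j + 0.5) / 2 - 0.5, 0), W - 1)
            j0, fj = int(np.floor(sj)), sj - int(np.floor(sj))
            j1 = min(j0 + 1, W - 1)
            out[:, i, j] = ((1 - fi) * (1 - fj) * x[:, i0, j0]
                            + (1 - fi) * fj * x[:, i0, j1]
                            + fi * (1 - fj) * x[:, i1, j0]
                            + fi * fj * x[:, i1, j1])
    return out


def bottleneck(x, sd, prefix, stride):
    h = relu(bn(conv(x, sd[prefix + "conv1.weight"]), sd, prefix + "bn1."))
    h = relu(bn(conv(h, sd[prefix + "conv2.weight"], stride=stride, pad=1),
                sd, prefix + "bn2."))
    h = bn(conv(h, sd[prefix + "conv3.weight"]), sd, prefix + "bn3.")
    if prefix + "short_conv.weight" in sd:
        s = bn(conv(x, sd[prefix + "short_conv.weight"], stride=stride),
               sd, prefix + "short_bn.")
    else:
        s = x
    return relu(h + s)


def resunet_forward(image, sd, config):
    """image: (H, W) in [0, 1] -> (C+1, H, W) scores.

    ``config`` is the package's NetworkConfig with both attention toggles
    off and bilinear upsampling.
    """
    assert not config.use_channel_attention and not config.use_spatial_bridge
    x = image[None]
    s0 = conv_bn_act(x, sd, "stem.", stride=2)
    h = maxpool2(s0)
    skips = []
    strides = (1, 2, 2, 2)
    for si in range(4):
        for bi in range(config.stage_blocks[si]):
            stride = strides[si] if bi == 0 else 1
            h = bottleneck(h, sd, f"stages.{si}.{bi}.", stride)
        skips.append(h)
    h = skips[3]
    for i, skip in enumerate((skips[2], skips[1], skips[0], s0)):
        h = conv_bn_act(upsample2(h), sd, f"ups.{i}.upconv.")
        h = np.concatenate([skip, h], axis=0)
        h = conv_bn_act(h, sd, f"ups.{i}.fuse1.")
        h = conv_bn_act(h, sd, f"ups.{i}.fuse2.")
    h = conv_bn_act(upsample2(h), sd, "final_up.")
    return conv(h, sd["head.weight"], sd["head.bias"])
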