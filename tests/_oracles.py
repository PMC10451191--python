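"""Independent brute-force oracles used by several test modules.

Everything here is written as plain scalar loops (or calls into scipy /
scikit-image, which the implementation under test does not use), so the
oracles share no code path with the package.
"""

import math

import numpy as np


def channel_weights_loop(scale):
    total = 0.0
    for s in scale:
        total += s
    return [s / total for s in scale]


def channel_attention_loop(x, scale, shift, mean, var, eps, nam_style=False):
    """Scalar triple-loop evaluation of the channel gate on (C, H, W)."""
    C, H, W = x.shape
    w = channel_weights_loop(list(scale))
    out = np.empty_like(x, dtype=float)
    for c in range(C):
        for i in range(H):
            for j in range(W):
                xhat = (x[c, i, j] - mean[c]) / math.sqrt(var[c] + eps)
                if nam_style:
                    pre = w[c] * (scale[c] * xhat + shift[c])
                else:
                    pre = w[c] * scale[c] * xhat + shift[c]
                gate = 1.0 / (1.0 + math.exp(-pre))
                out[c, i, j] = x[c, i, j] * gate
    return out


def spatial_attention_loop(x, kernel, bias):
    """Sliding-window evaluation of the spatial gate on (C, H, W).

    ``kernel`` has shape (2, 7, 7): plane 0 reads the channel mean,
    plane 1 the channel max; zero padding 3.
    """
    C, H, W = x.shape
    avg = x.mean(axis=0)
    mx = x.max(axis=0)
    planes = [avg, mx]
    out = np.empty_like(x, dtype=float)
    pad = 3
    for i in range(H):
        for j in range(W):
            acc = bias
            for p in range(2):
                for di in range(7):
                    for dj in range(7):
                        ii, jj = i + di - pad, j + dj - pad
                        if 0 <= ii < H and 0 <= jj < W:
                            acc += kernel[p, di, dj] * planes[p][ii, jj]
            gate = 1.0 / (1.0 + math.exp(-acc))
            out[:, i, j] = x[:, i, j] * gate
    return out


def confusion_loop(pred, true, C):
    """Nested-loop per-pixel confusion counts; returns (tp, fp, fn) arrays."""
    tp = np.zeros(C + 1, dtype=int)
    fp = np.zeros(C + 1, dtype=int)
    fn = np.zeros(C + 1, dtype=int)
    H, W = true.shape
    for i in range(H):
        for j in range(W):
            t, p = int(true[i, j]), int(pred[i, j])
            if t == p:
                tp[t] += 1
            else:
                fn[t] += 1
                fp[p] += 1
    return tp, fp, fn


def class_stats_loop(masks, C):
    """Per-pixel histogram scan; returns (image_counts, pixel_counts)."""
    img = np.zeros(C, dtype=int)
    pix = np.zeros(C, dtype=int)
    for mask in masks:
        seen = set()
        H, W = mask.shape
        for i in range(H):
            for j in range(W):
                v = int(mask[i, j])
                if v > 0:
                    pix[v - 1] += 1
                    seen.add(v)
        for v in seen:
            img[v - 1] += 1
    return img, pix


def softmax_nll_loop(scores, target):
    """Scalar -log softmax(scores)[target] for a 1-D score vector."""
    m = max(scores)
    z = [math.exp(s - m) for s in scores]
    return -(scores[target] - m - math.log(sum(z)))


def weighted_ce_loop(scores, targets, weights):
    """Per-pixel weighted CE on (K, H, W) scores / (H, W) targets."""
    K, H, W = scores.shape
    num, den = 0.0, 0.0
    for i in range(H):
        for j in range(W):
            y = int(targets[i, j])
            w = weights[y]
            num += w * softmax_nll_loop([scores[k, i, j] for k in range(K)], y)
            den += w
    return num / den
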