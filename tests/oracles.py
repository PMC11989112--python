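"""Independent brute-force oracles used to pin the package's vectorized code.

Everything here is written with explicit Python loops and elementary
formulas, deliberately avoiding the code paths (and where possible the
libraries) used by the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def sigmoid(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-v))


def signed_angle_oracle(a, n, b) -> float:
    """Unsigned angle via arccos plus an explicit cross-product sign (y-up)."""
    ax, ay = a[0] - n[0], a[1] - n[1]
    bx, by = b[0] - n[0], b[1] - n[1]
    cosv = (ax * bx + ay * by) / (math.hypot(ax, ay) * math.hypot(bx, by))
    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosv))))
    cross = bx * ay - by * ax
    return ang if cross >= 0 else -ang


def mlp_loop(v, w1, b1, w2, b2):
    """Two-layer perceptron with a ReLU hidden layer, element by element."""
    hidden = []
    for i in range(w1.shape[0]):
        s = b1[i]
        for j in range(w1.shape[1]):
            s += w1[i, j] * v[j]
        hidden.append(max(s, 0.0))
    out = []
    for i in range(w2.shape[0]):
        s = b2[i]
        for j in range(w2.shape[1]):
            s += w2[i, j] * hidden[j]
        out.append(s)
    return out


def channel_attention_loop(f, p):
    c, h, w = f.shape
    avg, mx = [], []
    for ch in range(c):
        total, biggest = 0.0, -math.inf
        for i in range(h):
            for j in range(w):
                total += f[ch, i, j]
                biggest = max(biggest, f[ch, i, j])
        avg.append(total / (h * w))
        mx.append(biggest)
    m1 = mlp_loop(avg, p.w1, p.b1, p.w2, p.b2)
    m2 = mlp_loop(mx, p.w1, p.b1, p.w2, p.b2)
    return np.array([sigmoid(m1[i] + m2[i]) for i in range(c)])


def spatial_attention_loop(f, p):
    c, h, w = f.shape
    mean_map = np.zeros((h, w))
    max_map = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            vals = [f[ch, i, j] for ch in range(c)]
            mean_map[i, j] = sum(vals) / c
            max_map[i, j] = max(vals)
    desc = [mean_map, max_map]
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            s = p.bias
            for ch in range(2):
                for ki in range(7):
                    for kj in range(7):
                        ii, jj = i + ki - 3, j + kj - 3
                        if 0 <= ii < h and 0 <= jj < w:
                            s += desc[ch][ii, jj] * p.kernel[ch, ki, kj]
            out[i, j] = sigmoid(s)
    return out


def se_squeeze_loop(f):
    c, h, w = f.shape
    z = []
    for ch in range(c):
        s = 0.0
        for i in range(h):
            for j in range(w):
                s += f[ch, i, j]
        z.append(s / (h * w))
    return np.array(z)


def se_excite_loop(z, p):
    out = mlp_loop(z, p.w1, p.b1, p.w2, p.b2)
    return np.array([sigmoid(v) for v in out])


def adaptive_avg_pool_loop(f, out_h, out_w):
    c, h, w = f.shape
    out = np.zeros((c, out_h, out_w))
    for ch in range(c):
        for bi in range(out_h):
            r0 = math.floor(bi * h / out_h)
            r1 = math.ceil((bi + 1) * h / out_h)
            for bj in range(out_w):
                c0 = math.floor(bj * w / out_w)
                c1 = math.ceil((bj + 1) * w / out_w)
                total, count = 0.0, 0
                for i in range(r0, r1):
                    for j in range(c0, c1):
                        total += f[ch, i, j]
                        count += 1
                out[ch, bi, bj] = total / count
    return out


def spp_loop(f, sizes):
    parts = [adaptive_avg_pool_loop(f, s, s).ravel() for s in sizes]
    return np.concatenate(parts)


def weighted_mean_loop(vectors, weights):
    """Hand-looped weighted mean of equal-length 1-D vectors."""
    total_w = sum(weights)
    out = []
    for i in range(len(vectors[0])):
        s = 0.0
        for vec, w in zip(vectors, weights):
            s += w * vec[i]
        out.append(s / total_w)
    return np.array(out)


def ovr_auc_pairs(y_true, scores, positive) -> float | None:
    """One-vs-rest AUC by counting concordant pairs (ties one half)."""
    pos = [s for yt, s in zip(y_true, scores) if yt == positive]
    neg = [s for yt, s in zip(y_true, scores) if yt != positive]
    if not pos or not neg:
        return None
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
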