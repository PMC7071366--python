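"""Literal-equation reference forward pass.

This module re-implements the classifier forward pass as explicit scalar
loops that transcribe the layer equations one-for-one: the cuboid filter
output is the triple sum over (z, u, v) of filter times receptive field,
bias + ReLU follows, max pooling takes the window maximum over the pooling
grid, and the fully connected layers are plain weighted sums. It is
deliberately slow and is used only as an independent oracle against the
vectorised implementation in :mod:`cinet.network`.
"""
from __future__ import annotations

import math

import numpy as np

from .network import Network, NetworkSpec

__all__ = ["reference_forward"]


def _conv_same(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    h, w, z = x.shape
    fh, fw, _ = f.shape
    a, b = fh // 2, fw // 2
    out = np.zeros((h, w))
    for hh in range(h):
        for ww in range(w):
            s = 0.0
            for zz in range(z):
                for u in range(-a, a + 1):
                    for v in range(-b, b + 1):
                        r, c = hh + u, ww + v
                        if 0 <= r < h and 0 <= c < w:
                            s += f[u + a, v + b, zz] * x[r, c, zz]
            out[hh, ww] = s
    return out


def _conv_valid(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    h, w, z = x.shape
    fh, fw, _ = f.shape
    out = np.zeros((h - fh + 1, w - fw + 1))
    for hh in range(h - fh + 1):
        for ww in range(w - fw + 1):
            s = 0.0
            for zz in range(z):
                for u in range(fh):
                    for v in range(fw):
                        s += f[u, v, zz] * x[hh + u, ww + v, zz]
            out[hh, ww] = s
    return out


def reference_forward(net: Network, x: np.ndarray) -> np.ndarray:
    """Posterior probabilities for one H x W x Z input, by scalar loops."""
    spec: NetworkSpec = net.spec
    act = np.asarray(x, dtype=np.float64)
    if act.shape != spec.input_shape:
        raise ValueError(f"input shape {act.shape} != spec {spec.input_shape}")
    for i, cl in enumerate(spec.conv_layers):
        filters = np.asarray(net.weights[f"conv{i}_w"], dtype=np.float64)
        biases = np.asarray(net.weights[f"conv{i}_b"], dtype=np.float64)
        conv = _conv_same if cl.mode == "same" else _conv_valid
        maps = []
        for k in range(cl.filters):
            m = conv(act, filters[..., k]) + biases[k]
            maps.append(np.maximum(m, 0.0))
        act = np.stack(maps, axis=2)
    if spec.pool is not None:
        size, stride = spec.pool.size, spec.pool.stride
        h, w, c = act.shape
        ho = (h - size) // stride + 1
        wo = (w - size) // stride + 1
        out = np.zeros((ho, wo, c))
        for k in range(c):
            for hh in range(ho):
                for ww in range(wo):
                    best = -math.inf
                    for th in range(size):
                        for tw in range(size):
                            v = act[stride * hh + th, stride * ww + tw, k]
                            if v > best:
                                best = v
                    out[hh, ww, k] = best
        act = out
    vec = act.reshape(-1)
    for i in range(len(spec.fcn_widths)):
        wm = np.asarray(net.weights[f"fc{i}_w"], dtype=np.float64)
        bm = np.asarray(net.weights[f"fc{i}_b"], dtype=np.float64)
        pre = np.zeros(wm.shape[1])
        for j in range(wm.shape[1]):
            s = 0.0
            for d in range(wm.shape[0]):
                s += vec[d] * wm[d, j]
            pre[j] = s + bm[j]
        if i < len(spec.fcn_widths) - 1:
            if spec.hidden_activation == "sigmoid":
                vec = np.array([1.0 / (1.0 + math.exp(-p)) if p >= 0
                                else math.exp(p) / (1.0 + math.exp(p)) for p in pre])
            elif spec.hidden_activation == "tanh":
                vec = np.tanh(pre)
            else:
                vec = np.maximum(pre, 0.0)
        else:
            m = pre.max()
            e = np.exp(pre - m)
            vec = e / e.sum()
    return vec
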