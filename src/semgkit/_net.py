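"""Minimal NumPy primitives for the small convolutional network.

Activations are laid out as ``(batch, depth, time)``; after the first
block the electrode axis is collapsed, so every subsequent convolution
and pooling operation is one-dimensional over time.  Each primitive
provides a forward pass and an analytic backward pass; everything is
plain float64 NumPy, so a fixed seed gives bit-reproducible training on a
single thread.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv1d_forward(
    x: np.ndarray, W: np.ndarray, b: np.ndarray, pad: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Depth-mixing 1-D convolution (cross-correlation) over time.

    ``x`` is ``(N, C_in, T)``, ``W`` is ``(C_out, C_in, k)``.  Returns
    ``(y, x_padded)``; ``x_padded`` is kept for the backward pass.
    """
    pl, pr = pad
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
    patches = sliding_window_view(xp, W.shape[2], axis=2)  # (N, Cin, T_out, k)
    y = np.einsum("nctk,ock->not", patches, W, optimize=True) + b[None, :, None]
    return y, xp


def conv1d_backward(
    dy: np.ndarray, xp: np.ndarray, W: np.ndarray, pad: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`conv1d_forward`; returns ``(dx, dW, db)``."""
    k = W.shape[2]
    t_out = dy.shape[2]
    patches = sliding_window_view(xp, k, axis=2)
    dW = np.einsum("nctk,not->ock", patches, dy, optimize=True)
    db = dy.sum(axis=(0, 2))
    dxp = np.zeros_like(xp)
    for j in range(k):
        dxp[:, :, j : j + t_out] += np.einsum("not,oc->nct", dy, W[:, :, j], optimize=True)
    pl, pr = pad
    dx = dxp[:, :, pl : dxp.shape[2] - pr] if (pl or pr) else dxp
    return dx, dW, db


def collapse_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """First-block convolution: one full-electrode-row filter per output.

    ``x`` is ``(N, T, C)`` raw windows, ``W`` is ``(F, C)``; the channel
    axis is consumed, yielding ``(N, F, T)``.
    """
    return np.einsum("ntc,fc->nft", x, W, optimize=True) + b[None, :, None]


def collapse_backward(
    dy: np.ndarray, x: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dW = np.einsum("nft,ntc->fc", dy, x, optimize=True)
    db = dy.sum(axis=(0, 2))
    dx = np.einsum("nft,fc->ntc", dy, W, optimize=True)
    return dx, dW, db


def relu_forward(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dy: np.ndarray, y: np.ndarray) -> np.ndarray:
    return dy * (y > 0)


def avgpool1d_forward(
    x: np.ndarray, k: int, stride: int, pad: tuple[int, int]
) -> tuple[np.ndarray, int]:
    """Average pooling over time; returns ``(y, padded_length)``."""
    pl, pr = pad
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
    y = sliding_window_view(xp, k, axis=2)[:, :, ::stride, :].mean(axis=3)
    return y, xp.shape[2]


def avgpool1d_backward(
    dy: np.ndarray, k: int, stride: int, pad: tuple[int, int], padded_len: int
) -> np.ndarray:
    n, c, t_out = dy.shape
    dxp = np.zeros((n, c, padded_len))
    share = dy / k
    for j in range(k):
        dxp[:, :, j : j + stride * t_out : stride] += share
    pl, pr = pad
    return dxp[:, :, pl : padded_len - pr] if (pl or pr) else dxp


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-300
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + eps)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
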