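"""Convolutional branch: pad -> conv -> average-pool -> conv -> average-pool
-> flatten, producing the "original representation" v_n of a pair.

The input is the 2×(Nr+Nd) spliced feature matrix. Both convolutions are
valid cross-correlations followed by ReLU; pooling is non-overlapping
averaging along the width axis only (pool window 1×b), with a trailing
remainder truncated. Kernels larger than the surviving input are clamped
to it: with one padding layer and a height-3 first kernel, only 2 rows
survive layer 1, so the nominal height-3 second kernel runs as height 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, conv2d, avg_pool_w

log = logging.getLogger(__name__)

__all__ = ["ConvBranchParams", "init_conv_params", "pad_features",
           "conv_forward", "avg_pool", "cnn_branch_forward",
           "conv_output_shapes", "vn_length"]


@dataclass
class ConvBranchParams:
    pconv: int
    W1: Tensor  # (C1, 1, kh1, kw1)
    b1: Tensor  # (C1,)
    pool1: int
    W2: Tensor  # (C2, C1, kh2, kw2)
    b2: Tensor  # (C2,)
    pool2: int

    def tensors(self):
        return {"conv.W1": self.W1, "conv.b1": self.b1,
                "conv.W2": self.W2, "conv.b2": self.b2}


def _he_uniform(rng, shape, fan_in):
    bound = np.sqrt(6.0 / fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def conv_output_shapes(n_features: int, config) -> dict:
    """Symbolic shape chain of the branch for a 2×n_features input.

    Returns the effective (possibly clamped) kernel sizes along with the
    intermediate map shapes; used both to build parameters and to validate
    configuration before training.
    """
    h = 2 + 2 * config.pconv
    w = n_features + 2 * config.pconv
    kh1 = min(config.conv1_kernel[0], h)
    kw1 = min(config.conv1_kernel[1], w)
    if (kh1, kw1) != tuple(config.conv1_kernel):
        log.warning("conv1 kernel %s clamped to (%d, %d) for input (%d, %d)",
                    config.conv1_kernel, kh1, kw1, h, w)
    h1, w1 = h - kh1 + 1, w - kw1 + 1
    p1 = min(config.pool1_width, w1)
    if p1 != config.pool1_width:
        log.warning("pool1 width %d clamped to %d for map width %d",
                    config.pool1_width, p1, w1)
    w1p = w1 // p1
    kh2 = min(config.conv2_kernel[0], h1)
    kw2 = min(config.conv2_kernel[1], w1p)
    if (kh2, kw2) != tuple(config.conv2_kernel):
        log.warning("conv2 kernel %s clamped to (%d, %d) for input (%d, %d)",
                    config.conv2_kernel, kh2, kw2, h1, w1p)
    h2, w2 = h1 - kh2 + 1, w1p - kw2 + 1
    p2 = min(config.pool2_width, w2)
    if p2 != config.pool2_width:
        log.warning("pool2 width %d clamped to %d for map width %d",
                    config.pool2_width, p2, w2)
    w2p = w2 // p2
    return {
        "padded": (h, w),
        "kernel1": (kh1, kw1), "map1": (h1, w1), "pool1": p1,
        "pooled1": (h1, w1p),
        "kernel2": (kh2, kw2), "map2": (h2, w2), "pool2": p2,
        "pooled2": (h2, w2p),
        "vn_length": h2 * w2p * config.conv2_channels,
    }


def vn_length(n_features: int, config) -> int:
    return conv_output_shapes(n_features, config)["vn_length"]


def init_conv_params(n_features: int, config, rng) -> ConvBranchParams:
    shapes = conv_output_shapes(n_features, config)
    kh1, kw1 = shapes["kernel1"]
    kh2, kw2 = shapes["kernel2"]
    c1, c2 = config.conv1_channels, config.conv2_channels
    return ConvBranchParams(
        pconv=config.pconv,
        W1=_he_uniform(rng, (c1, 1, kh1, kw1), fan_in=kh1 * kw1),
        b1=Tensor(np.zeros(c1), requires_grad=True),
        pool1=shapes["pool1"],
        W2=_he_uniform(rng, (c2, c1, kh2, kw2), fan_in=c1 * kh2 * kw2),
        b2=Tensor(np.zeros(c2), requires_grad=True),
        pool2=shapes["pool2"],
    )


def pad_features(F: np.ndarray, pconv: int) -> np.ndarray:
    """Zero-pad `pconv` layers on every side of one F or a batch of them."""
    if pconv < 0:
        raise ValueError("pconv must be >= 0")
    if pconv == 0:
        return np.asarray(F, dtype=float)
    F = np.asarray(F, dtype=float)
    pad = [(0, 0)] * (F.ndim - 2) + [(pconv, pconv), (pconv, pconv)]
    return np.pad(F, pad)


def conv_forward(x, weights: Tensor, bias: Tensor) -> Tensor:
    """Valid cross-correlation + bias + ReLU on a (B, Cin, H, W) input."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    return conv2d(x, weights, bias).relu()


def avg_pool(x, width: int) -> Tensor:
    """Non-overlapping 1×width average pooling along the last axis."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    return avg_pool_w(x, width)


def cnn_branch_forward(F, params: ConvBranchParams) -> Tensor:
    """Run the full branch on one F (2×V) or a batch (B×2×V).

    Returns v_n as a (len,) tensor for one pair or (B, len) for a batch.
    """
    F = np.asarray(F, dtype=float)
    single = F.ndim == 2
    if single:
        F = F[None]
    padded = pad_features(F, params.pconv)[:, None, :, :]  # (B,1,H,W)
    z1 = conv_forward(padded, params.W1, params.b1)
    q1 = avg_pool(z1, params.pool1)
    z2 = conv_forward(q1, params.W2, params.b2)
    q2 = avg_pool(z2, params.pool2)
    vn = q2.reshape(q2.shape[0], -1)
    return vn.reshape(-1) if single else vn
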