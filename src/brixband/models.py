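"""Reconstruction and regression branches consuming the compact cube.

The reconstruction branch is a lightweight U-Net-style encoder-decoder with
skip connections and a logistic output, restoring the full C-band cube from
the gated/masked compact representation. The regression branch predicts the
scalar SSC value through depthwise separable convolution, efficient channel
attention and generalized-mean pooling, followed by a small affine head.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


def _pad_to_multiple(x: Tensor, multiple: int) -> tuple[Tensor, int, int]:
    """Zero-pad bottom/right so spatial dims divide `multiple`."""
    n, c, h, w = x.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph:
        zeros = Tensor(np.zeros((n, c, ph, w)))
        x = ad.concatenate([x, zeros], axis=2)
    if pw:
        zeros = Tensor(np.zeros((n, c, h + ph, pw)))
        x = ad.concatenate([x, zeros], axis=3)
    return x, h, w


class ReconstructionUNet(nn.Module):
    """Two-level encoder-decoder with skip connections; sigmoid output keeps
    the reconstructed reflectance in [0, 1]."""

    def __init__(self, n_bands: int, rng: np.random.Generator,
                 base_width: int = 16):
        super().__init__()
        b = base_width
        self.enc1 = nn.Conv2d(n_bands, b, 3, rng)
        self.enc2 = nn.Conv2d(b, 2 * b, 3, rng)
        self.bottleneck = nn.Conv2d(2 * b, 4 * b, 3, rng)
        self.dec2 = nn.Conv2d(4 * b + 2 * b, 2 * b, 3, rng)
        self.dec1 = nn.Conv2d(2 * b + b, b, 3, rng)
        self.out = nn.Conv2d(b, n_bands, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        x, h, w = _pad_to_multiple(x, 4)
        d1 = ad.relu(self.enc1(x))                       # (N, b, H, W)
        d2 = ad.relu(self.enc2(ad.avg_pool2d(d1, 2)))    # (N, 2b, H/2, W/2)
        d3 = ad.relu(self.bottleneck(ad.avg_pool2d(d2, 2)))
        u2 = ad.relu(self.dec2(ad.concatenate(
            [ad.upsample_nearest2d(d3, 2), d2], axis=1)))
        u1 = ad.relu(self.dec1(ad.concatenate(
            [ad.upsample_nearest2d(u2, 2), d1], axis=1)))
        out = ad.sigmoid(self.out(u1))
        return out[:, :, :h, :w]


class RegressionHead(nn.Module):
    """Compact SSC predictor: depthwise separable conv -> ECA -> GeM -> MLP.

    The head is parameterized as  y = y_mean + y_scale * f(x)  with y_mean /
    y_scale set from the training labels, so the network body operates at
    unit scale while predictions remain in °Brix.
    """

    def __init__(self, n_bands: int, rng: np.random.Generator,
                 width: int = 32, y_mean: float = 0.0, y_scale: float = 1.0):
        super().__init__()
        self.depthwise = nn.DepthwiseConv2d(n_bands, 3, rng)
        self.pointwise = nn.Conv2d(n_bands, width, 1, rng, padding=0)
        self.eca = nn.EfficientChannelAttention(width, rng)
        self.gem = nn.GeMPool(p_init=3.0)
        self.fc1 = nn.Linear(width, 16, rng)
        self.fc2 = nn.Linear(16, 1, rng)
        self.y_mean = float(y_mean)
        self.y_scale = float(y_scale) if y_scale else 1.0

    def forward(self, x: Tensor) -> Tensor:
        h = ad.relu(self.depthwise(x))
        h = ad.relu(self.pointwise(h))
        h = self.eca(h)
        h = self.gem(h)                                  # (N, width)
        h = ad.relu(self.fc1(h))
        out = self.fc2(h).reshape(-1)                    # (N,)
        return out * self.y_scale + self.y_mean


def rec_loss(x_hat, x):
    """Mean squared error over all voxels (reconstruction loss)."""
    if isinstance(x_hat, Tensor) or isinstance(x, Tensor):
        x_hat = x_hat if isinstance(x_hat, Tensor) else Tensor(x_hat)
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x_hat.shape != x.shape:
            raise ValueError("shape mismatch in rec_loss")
        d = x_hat - x
        return (d * d).mean()
    x_hat, x = np.asarray(x_hat), np.asarray(x)
    if x_hat.shape != x.shape:
        raise ValueError("shape mismatch in rec_loss")
    return float(np.mean((x_hat - x) ** 2))


def huber(y, y_hat, delta: float = 1.0):
    """Huber loss, mean over samples: quadratic within |r| <= delta,
    linear outside; continuous and once-differentiable at the knee."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    if isinstance(y_hat, Tensor) or isinstance(y, Tensor):
        y = y if isinstance(y, Tensor) else Tensor(y)
        y_hat = y_hat if isinstance(y_hat, Tensor) else Tensor(y_hat)
        r = y - y_hat
        absr = ad.sqrt(r * r + 1e-24)
        quad = r * r * 0.5
        lin = absr * delta - 0.5 * delta * delta
        # smooth branch select via a mask on the forward values
        mask = Tensor((np.abs(r.data) <= delta).astype(float))
        return (quad * mask + lin * (1.0 - mask)).mean()
    r = np.abs(np.asarray(y) - np.asarray(y_hat))
    out = np.where(r <= delta, 0.5 * r ** 2, delta * r - 0.5 * delta ** 2)
    return float(np.mean(out))


reg_loss = huber
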