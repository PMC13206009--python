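"""Spectral-spatial attention and probability-based differentiable band
selection with a budget constraint and deployable top-K fixation.

Given a band-importance vector ``a`` from the spectral attention branch, the
selection probability of band i is a thresholded-sigmoid normalization

    p_i = sigma((a_i - tau) / T) / sum_j sigma((a_j - tau) / T),

which, unlike a plain softmax, keeps the explicit effect of the adaptive
threshold tau: bands below tau are suppressed rather than merely shifted.
The effective number of retained bands is estimated by the smooth pass-count

    K_tilde = sum_i sigma((a_i - tau) / T_pass),

and tied to the target budget K through L_pass = (K_tilde - K)^2 / 2.
During training the gate stays soft so both task losses backpropagate into
``a``; for deployment, per-pass selection events (a_i > tau) are counted and
the K most frequently selected bands are fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclass
class SelectorConfig:
    K: int
    n_bands: int
    T: float = 1.0                 # selection temperature (annealed)
    T_pass: float = 0.1            # pass-count smoothing temperature
    T_end: float = 0.1             # anneal target for T
    tau_momentum: float = 0.9      # EMA momentum of the adaptive threshold

    def validate(self) -> None:
        if not 1 <= self.K <= self.n_bands:
            raise ValueError("K must satisfy 1 <= K <= n_bands")
        if self.T <= 0 or self.T_pass <= 0:
            raise ValueError("temperatures must be positive")


@dataclass
class SelectionState:
    """Running selection bookkeeping across forward passes."""

    frequency: np.ndarray          # (C,) int, selection-event counts
    a_sum: np.ndarray              # (C,) accumulated importance
    n_passes: int = 0
    tau: float = 0.5

    @classmethod
    def fresh(cls, n_bands: int, tau: float = 0.5) -> "SelectionState":
        return cls(frequency=np.zeros(n_bands, dtype=np.int64),
                   a_sum=np.zeros(n_bands), n_passes=0, tau=tau)

    @property
    def a_running_mean(self) -> np.ndarray:
        return self.a_sum / max(self.n_passes, 1)


# ---- attention modules ----------------------------------------------------

class SpatialAttention(nn.Module):
    """Spatial mask from band-wise average and max maps.

    The two pooled maps are concatenated and passed through a small
    convolution followed by a logistic squashing, giving a mask in (0, 1)
    with the cube's spatial shape.
    """

    def __init__(self, rng: np.random.Generator, kernel: int = 7):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        pooled = ad.concatenate([avg, mx], axis=1)
        return ad.sigmoid(self.conv(pooled))


class SpectralAttention(nn.Module):
    """Band-importance vector a in (0, 1)^C from the spatially pooled
    spectrum via a lightweight two-layer perceptron."""

    def __init__(self, n_bands: int, rng: np.random.Generator,
                 reduction: int = 4):
        super().__init__()
        hidden = max(n_bands // reduction, 4)
        self.fc1 = nn.Linear(n_bands, hidden, rng)
        self.fc2 = nn.Linear(hidden, n_bands, rng)

    def forward(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))                    # (N, C)
        return ad.sigmoid(self.fc2(ad.relu(self.fc1(pooled))))


# ---- differentiable selection --------------------------------------------

def selection_probabilities(a, tau: float, T: float):
    """Thresholded-sigmoid selection distribution over bands (sums to 1).

    Accepts a numpy array (returns numpy) or a Tensor (stays differentiable).
    """
    if T <= 0:
        raise ValueError("temperature T must be positive")
    if isinstance(a, Tensor):
        s = ad.sigmoid((a - tau) * (1.0 / T))
        return s / s.sum(axis=-1, keepdims=True)
    a = np.asarray(a, dtype=np.float64)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-(a - tau) / T))
    z = s.sum(axis=-1, keepdims=True)
    if np.any(z < 1e-300):
        warnings.warn("all sigmoid terms underflowed; returning uniform "
                      "selection probabilities")
        return np.full_like(a, 1.0 / a.shape[-1])
    return s / z


def soft_pass_count(a, tau: float, T_pass: float):
    """Differentiable estimate of how many bands pass the threshold."""
    if T_pass <= 0:
        raise ValueError("temperature T_pass must be positive")
    if isinstance(a, Tensor):
        return ad.sigmoid((a - tau) * (1.0 / T_pass)).sum(axis=-1)
    a = np.asarray(a, dtype=np.float64)
    return (1.0 / (1.0 + np.exp(-np.clip((a - tau) / T_pass, -500, 500)))
            ).sum(axis=-1)


def pass_loss(k_tilde, K: int):
    """Budget regularizer L_pass = (K_tilde - K)^2 / 2."""
    if K < 1:
        raise ValueError("K must be >= 1")
    d = k_tilde - K
    return d * d * 0.5


def soft_gate(cube, spatial_mask, a, tau: float, T: float):
    """Soft compact representation: X * M_S * sigma((a - tau)/T) per band.

    Keeps all C channels so downstream shapes are static; gates are in
    (0, 1) so the output never exceeds the input elementwise.
    """
    if isinstance(cube, Tensor):
        gate = ad.sigmoid((a - tau) * (1.0 / T))        # (N, C)
        n, c = gate.shape
        return cube * spatial_mask * gate.reshape(n, c, 1, 1)
    gate = 1.0 / (1.0 + np.exp(-np.clip((np.asarray(a) - tau) / T,
                                        -500, 500)))
    return np.asarray(cube) * np.asarray(spatial_mask) \
        * gate[..., :, None, None]


def adaptive_tau(state: SelectionState, a_values: np.ndarray, K: int,
                 momentum: float | None = None) -> float:
    """Track tau toward the (1 - K/C) empirical quantile of ``a`` with an
    exponential moving average, so that about K bands pass on average."""
    a_values = np.asarray(a_values)
    c = a_values.shape[-1]
    momentum = 0.9 if momentum is None else momentum
    target = float(np.quantile(a_values, 1.0 - K / c))
    state.tau = momentum * state.tau + (1.0 - momentum) * target
    return state.tau


# ---- frequency counting and hard fixation --------------------------------

def update_frequencies(state: SelectionState, a_values: np.ndarray,
                       tau: float | None = None) -> None:
    """Record one selection event per sample row: bands with a_i > tau."""
    a_values = np.atleast_2d(np.asarray(a_values))
    tau = state.tau if tau is None else tau
    state.frequency += (a_values > tau).sum(axis=0)
    state.a_sum += a_values.sum(axis=0)
    state.n_passes += a_values.shape[0]


def finalize_topk(frequency: np.ndarray, K: int,
                  a_running_mean: np.ndarray | None = None) -> np.ndarray:
    """Exactly K distinct band indices with the highest selection counts.

    Ties are broken by larger running-mean importance, then lower index.
    Returned sorted ascending.
    """
    frequency = np.asarray(frequency)
    c = frequency.shape[0]
    if K > c:
        raise ValueError("K cannot exceed the number of bands")
    if K < 1:
        raise ValueError("K must be >= 1")
    a_mean = np.zeros(c) if a_running_mean is None else \
        np.asarray(a_running_mean)
    order = sorted(range(c), key=lambda i: (-frequency[i], -a_mean[i], i))
    return np.array(sorted(order[:K]), dtype=np.int64)


@dataclass
class CompactRepresentation:
    values: np.ndarray | Tensor
    active_bands: np.ndarray


def hard_subset(cube, indices) -> CompactRepresentation:
    """Zero every band not in ``indices`` (channel count preserved)."""
    indices = np.asarray(indices, dtype=np.int64)
    if indices.size == 0:
        raise ValueError("at least one band must be selected")
    if len(np.unique(indices)) != len(indices):
        raise ValueError("band indices must be distinct")
    if isinstance(cube, Tensor):
        c = cube.shape[1]
    else:
        cube = np.asarray(cube)
        c = cube.shape[-3]
    if indices.min() < 0 or indices.max() >= c:
        raise IndexError("band index out of range")
    mask = np.zeros(c)
    mask[indices] = 1.0
    if isinstance(cube, Tensor):
        out = cube * Tensor(mask[None, :, None, None])
    else:
        out = cube * mask[..., :, None, None]
    return CompactRepresentation(values=out, active_bands=indices)


def anneal_temperature(epoch: int, n_anneal_epochs: int, t_start: float = 1.0,
                       t_end: float = 0.1) -> float:
    """Geometric interpolation of the selection temperature."""
    if n_anneal_epochs <= 1:
        return t_end
    frac = min(epoch / (n_anneal_epochs - 1), 1.0)
    return float(t_start * (t_end / t_start) ** frac)
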