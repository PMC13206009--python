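"""Reconstruction and regression metrics, baseline selectors, selection
stability, and the band-index <-> wavelength mapping.

Reconstruction fidelity between a ground-truth cube X and a reconstruction
X_hat (both in the normalized [0, 1] reflectance scale) is summarized by
voxel-wise MAE/MSE, PSNR with MAX = 1, band-wise SSIM averaged over bands,
pixelwise spectral Pearson correlation (SCC) and the spectral angle mapper
(SAM, degrees). Regression quality uses MAE, RMSE, R^2 and the residual
predictive deviation RPD = SD(y) / RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ReconMetrics:
    mae: float
    mse: float
    psnr: float          # dB; +inf when MSE == 0
    ssim: float
    scc: float
    sam: float           # degrees


@dataclass
class RegMetrics:
    mae: float
    rmse: float
    r2: float
    rpd: float


@dataclass
class StabilityReport:
    jaccard_to_previous: np.ndarray     # per consecutive epoch pair
    overlap_with_final: np.ndarray      # per epoch, |A ∩ final| / K
    normalized_frequencies: dict[str, np.ndarray]  # per split, max 1
    top15: dict[str, np.ndarray]        # per split, top-15 band indices


_SSIM_C1 = 0.01 ** 2
_SSIM_C2 = 0.03 ** 2


def _ssim_band_global(x: np.ndarray, y: np.ndarray) -> float:
    mu_x, mu_y = x.mean(), y.mean()
    var_x, var_y = x.var(), y.var()
    cov = ((x - mu_x) * (y - mu_y)).mean()
    return ((2 * mu_x * mu_y + _SSIM_C1) * (2 * cov + _SSIM_C2)
            / ((mu_x ** 2 + mu_y ** 2 + _SSIM_C1)
               * (var_x + var_y + _SSIM_C2)))


def recon_metrics(x: np.ndarray, x_hat: np.ndarray,
                  ssim_mode: str = "global") -> ReconMetrics:
    """All reconstruction metrics for cubes of shape (C, H, W) in [0, 1].

    ``ssim_mode='global'`` uses per-band global statistics; ``'gaussian'``
    uses the conventional 11x11 Gaussian-window SSIM per band.
    """
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError("cube shapes differ")
    c, h, w = x.shape
    diff = x_hat - x
    mae = float(np.abs(diff).mean())
    mse = float((diff ** 2).mean())
    psnr = np.inf if mse == 0 else float(10.0 * np.log10(1.0 / mse))

    if ssim_mode == "gaussian":
        from skimage.metrics import structural_similarity

        ssim = float(np.mean([structural_similarity(
            x[i], x_hat[i], data_range=1.0, gaussian_weights=True,
            win_size=min(11, (min(h, w) // 2) * 2 - 1) if min(h, w) >= 3
            else min(h, w), sigma=1.5, use_sample_covariance=False)
            for i in range(c)]))
    else:
        ssim = float(np.mean([_ssim_band_global(x[i], x_hat[i])
                              for i in range(c)]))

    # pixelwise Pearson correlation along the spectral axis
    xs = x.reshape(c, -1)
    ys = x_hat.reshape(c, -1)
    xc = xs - xs.mean(axis=0)
    yc = ys - ys.mean(axis=0)
    denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum(axis=0))
    valid = denom > 0
    corr = np.zeros(xs.shape[1])
    corr[valid] = (xc * yc).sum(axis=0)[valid] / denom[valid]
    scc = float(corr.mean()) if valid.any() else 0.0

    # spectral angle per pixel, averaged, in degrees
    norms = np.sqrt((xs ** 2).sum(axis=0) * (ys ** 2).sum(axis=0))
    ok = norms > 0
    cosang = np.ones(xs.shape[1])
    cosang[ok] = np.clip((xs * ys).sum(axis=0)[ok] / norms[ok], -1.0, 1.0)
    sam = float(np.degrees(np.arccos(cosang)).mean())
    return ReconMetrics(mae=mae, mse=mse, psnr=psnr, ssim=ssim, scc=scc,
                        sam=sam)


def reg_metrics(y: np.ndarray, y_hat: np.ndarray) -> RegMetrics:
    """MAE, RMSE, R^2 and RPD = SD(y)/RMSE for N >= 2 samples."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("need matching vectors with N >= 2")
    res = y - y_hat
    mae = float(np.abs(res).mean())
    rmse = float(np.sqrt((res ** 2).mean()))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero label variance: R^2 and RPD undefined")
    r2 = 1.0 - float((res ** 2).sum()) / ss_tot
    sd = float(y.std())
    rpd = np.inf if rmse == 0 else sd / rmse
    return RegMetrics(mae=mae, rmse=rmse, r2=r2, rpd=rpd)


def band_to_wavelength(index, n_bands: int,
                       wavelength_range: tuple[float, float]):
    """Uniform linear map from band index to nanometres.

    Index 0 maps to the range minimum, index n_bands - 1 to the maximum.
    """
    index = np.asarray(index, dtype=np.float64)
    if np.any(index < 0) or np.any(index > n_bands - 1):
        raise ValueError("band index out of range")
    lo, hi = wavelength_range
    out = lo + index * (hi - lo) / (n_bands - 1)
    return float(out) if out.ndim == 0 else out


def baseline_select(method: str, data: np.ndarray | None, K: int,
                    seed: int = 0,
                    frequency: np.ndarray | None = None,
                    a_running_mean: np.ndarray | None = None,
                    n_bands: int | None = None) -> np.ndarray:
    """Reference band subsets: 'random', per-band 'variance' over training
    cubes (data shaped (N, C, H, W)), or 'frequency' (top-K passthrough)."""
    if method == "random":
        if n_bands is None:
            n_bands = np.asarray(data).shape[1]
        if K > n_bands:
            raise ValueError("K cannot exceed the number of bands")
        rng = np.random.default_rng(seed)
        return np.array(sorted(rng.choice(n_bands, size=K, replace=False)),
                        dtype=np.int64)
    if method == "variance":
        data = np.asarray(data)
        c = data.shape[1]
        if K > c:
            raise ValueError("K cannot exceed the number of bands")
        band_var = data.transpose(1, 0, 2, 3).reshape(c, -1).var(axis=1)
        order = np.argsort(-band_var, kind="stable")
        return np.array(sorted(order[:K]), dtype=np.int64)
    if method == "frequency":
        from .selector import finalize_topk

        return finalize_topk(frequency, K, a_running_mean)
    raise ValueError(f"unknown baseline method {method!r}")


def jaccard(a, b) -> float:
    a, b = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    union = a | b
    return len(a & b) / len(union) if union else 1.0


def stability_report(per_epoch_subsets: list[np.ndarray],
                     final_subset: np.ndarray,
                     per_split_frequencies: dict[str, np.ndarray]
                     ) -> StabilityReport:
    """Epoch-to-epoch Jaccard similarity, overlap@K with the final subset,
    and per-split selection frequencies normalized to max 1."""
    if not per_epoch_subsets:
        raise ValueError("need at least one epoch subset")
    k = len(final_subset)
    jac = np.array([jaccard(a, b) for a, b in
                    zip(per_epoch_subsets[:-1], per_epoch_subsets[1:])])
    fin = set(np.asarray(final_subset).tolist())
    overlap = np.array([len(set(np.asarray(s).tolist()) & fin) / k
                        for s in per_epoch_subsets])
    norm_freq, top15 = {}, {}
    for name, freq in per_split_frequencies.items():
        freq = np.asarray(freq, dtype=np.float64)
        peak = freq.max()
        norm_freq[name] = freq / peak if peak > 0 else freq
        top15[name] = np.argsort(-freq, kind="stable")[:15]
    return StabilityReport(jaccard_to_previous=jac,
                           overlap_with_final=overlap,
                           normalized_frequencies=norm_freq, top15=top15)


def band_entropy(cubes: np.ndarray, n_hist_bins: int = 64) -> np.ndarray:
    """Shannon entropy (bits) of each band's reflectance histogram over a
    cube collection shaped (N, C, H, W) with values in [0, 1]."""
    cubes = np.asarray(cubes)
    if cubes.ndim == 3:
        cubes = cubes[None]
    c = cubes.shape[1]
    out = np.empty(c)
    edges = np.linspace(0.0, 1.0, n_hist_bins + 1)
    for i in range(c):
        counts, _ = np.histogram(cubes[:, i], bins=edges)
        p = counts / counts.sum()
        nz = p[p > 0]
        out[i] = float(-(nz * np.log2(nz)).sum())
    return out
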