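"""Hyperspectral cube I/O, reflectance calibration, normalization, patching.

Cubes are held band-first as ``(C, H, W)`` float arrays. On disk they are
multi-page TIFFs, one page per band. Raw counts are converted to relative
reflectance with white/dark reference frames,

    R(lambda) = (I(lambda) - D(lambda)) / (W(lambda) - D(lambda)),

which removes dark current and illumination nonuniformity. Normalization
clips to per-cube percentiles and rescales to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import tifffile


class AmbiguousLayoutError(ValueError):
    """No axis of the stored array is plausibly the spectral axis."""


class CalibrationError(ValueError):
    pass


@dataclass
class HyperCube:
    values: np.ndarray                     # (C, H, W)
    wavelengths: np.ndarray | None = None  # (C,) nm, strictly increasing
    provenance: str = "raw"                # raw | calibrated | normalized

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("cube must be rank 3 (band, row, col)")


@dataclass
class ReferenceFrames:
    white: np.ndarray
    dark: np.ndarray


def write_array_tiff(path, array: np.ndarray) -> None:
    """Write a (C, H, W) array as a multi-page TIFF, one page per band."""
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


def write_cube(path, cube: HyperCube) -> None:
    write_array_tiff(path, cube.values)


def read_cube(path, expected_bands: int) -> HyperCube:
    """Read a cube and coerce it to band-first with ``expected_bands`` bands.

    Band-last storage is detected by matching axis lengths against the
    expected band number (first axis wins a tie, with a warning). A band
    axis longer than expected is truncated; shorter is edge-padded by
    replicating the last band.
    """
    if expected_bands < 1:
        raise ValueError("expected_bands must be >= 1")
    arr = np.asarray(tifffile.imread(path), dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise AmbiguousLayoutError(f"array rank {arr.ndim}, expected 3")

    candidates = (0, 2)
    exact = [ax for ax in candidates if arr.shape[ax] == expected_bands]
    if len(exact) == 2:
        warnings.warn("both first and last axes match the expected band "
                      "number; treating the first as spectral")
        band_axis = 0
    elif exact:
        band_axis = exact[0]
    else:
        # tolerate moderate truncation/padding: within 25% of expected
        plausible = [ax for ax in candidates
                     if abs(arr.shape[ax] - expected_bands)
                     <= 0.25 * expected_bands]
        if not plausible:
            raise AmbiguousLayoutError(
                f"no axis of shape {arr.shape} is plausibly spectral for "
                f"{expected_bands} bands")
        band_axis = min(plausible,
                        key=lambda ax: abs(arr.shape[ax] - expected_bands))
    if band_axis != 0:
        arr = np.moveaxis(arr, band_axis, 0)
    c = arr.shape[0]
    if c > expected_bands:
        arr = arr[:expected_bands]
    elif c < expected_bands:
        arr = np.pad(arr, [(0, expected_bands - c), (0, 0), (0, 0)],
                     mode="edge")
    return HyperCube(values=arr, provenance="raw")


def calibrate_reflectance(raw: HyperCube, refs: ReferenceFrames) -> HyperCube:
    """Apply white/dark reflectance calibration elementwise."""
    white = np.asarray(refs.white, dtype=np.float64)
    dark = np.asarray(refs.dark, dtype=np.float64)
    denom = white - dark
    bad = ~(np.min(denom, axis=tuple(range(1, denom.ndim))) > 0) \
        if denom.ndim > 1 else denom <= 0
    bad_bands = np.nonzero(np.atleast_1d(bad))[0]
    if bad_bands.size:
        raise CalibrationError(
            f"white - dark not positive in bands {bad_bands.tolist()}")
    values = (raw.values - dark) / denom
    return HyperCube(values=values, wavelengths=raw.wavelengths,
                     provenance="calibrated")


def percentile_normalize(cube: HyperCube, p_lo: float = 1.0,
                         p_hi: float = 99.0) -> HyperCube:
    """Clip to per-cube percentiles [p_lo, p_hi], then min-max to [0, 1]."""
    if not p_lo < p_hi:
        raise ValueError("p_lo must be < p_hi")
    v = cube.values
    lo, hi = np.percentile(v, [p_lo, p_hi])
    if hi <= lo:
        warnings.warn("degenerate intensity range; returning all zeros")
        out = np.zeros_like(v)
    else:
        out = (np.clip(v, lo, hi) - lo) / (hi - lo)
    return HyperCube(values=out, wavelengths=cube.wavelengths,
                     provenance="normalized")


def _reflect_pad_spatial(values: np.ndarray, size: int) -> np.ndarray:
    _, h, w = values.shape
    ph, pw = max(0, size - h), max(0, size - w)
    if ph == 0 and pw == 0:
        return values
    pads = [(0, 0), (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)]
    # reflect needs dim >= 2; fall back to edge replication on degenerate dims
    mode = "reflect" if min(h, w) >= 2 else "edge"
    return np.pad(values, pads, mode=mode)


def extract_patch(cube: HyperCube, size: int = 448, mode: str = "eval",
                  seed=None) -> HyperCube:
    """Square spatial crop: random in train mode, centered in eval mode.

    Cubes smaller than the patch are reflectively padded first, so the
    operation always succeeds.
    """
    if size < 1:
        raise ValueError("patch size must be >= 1")
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    v = _reflect_pad_spatial(cube.values, size)
    _, h, w = v.shape
    if mode == "train":
        rng = np.random.default_rng(seed)
        r0 = int(rng.integers(0, h - size + 1))
        c0 = int(rng.integers(0, w - size + 1))
    else:
        r0, c0 = (h - size) // 2, (w - size) // 2
    out = v[:, r0:r0 + size, c0:c0 + size]
    return HyperCube(values=out.copy(), wavelengths=cube.wavelengths,
                     provenance=cube.provenance)


def augment(patch: HyperCube, seed=None, enable_rotation: bool = True
            ) -> HyperCube:
    """Random horizontal/vertical flips and a 90-degree rotation, each
    applied independently with probability 0.5. Spectral axis untouched."""
    v = patch.values
    _, h, w = v.shape
    if enable_rotation and h != w:
        raise ValueError("90-degree rotation requires square spatial dims")
    rng = np.random.default_rng(seed)
    if rng.random() < 0.5:
        v = v[:, :, ::-1]
    if rng.random() < 0.5:
        v = v[:, ::-1, :]
    if enable_rotation and rng.random() < 0.5:
        v = np.rot90(v, k=1, axes=(1, 2))
    return HyperCube(values=v.copy(), wavelengths=patch.wavelengths,
                     provenance=patch.provenance)
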