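"""Synthetic hyperspectral fruit phantoms with a known SSC mechanism.

Real VNIR cubes of intact fruit are large and instrument-bound; this module
generates small phantoms whose soluble-solids-content (SSC) signal enters the
spectrum through a known, planted set of bands, so that band selection,
reconstruction and regression can all be validated against ground truth.

The phantom mixes three smooth endmembers that mimic the familiar features of
fruit reflectance — a blue pigment-absorption dip, a red-edge sigmoid and a
near-infrared water decline — plus a "sweetness" endmember supported only on
the configured informative bands, whose abundance is affine in the SSC label.
Raw counts are synthesized against per-band white/dark reference frames so the
standard reflectance calibration applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class InvalidConfigError(ValueError):
    pass


class InvalidLabelError(ValueError):
    pass


# reference wavelengths (nm) of SSC-coupled features used for the default
# informative set: pigment absorptions, red-edge shoulder, water bands
_DEFAULT_INFORMATIVE_NM = (450.0, 500.0, 530.0, 560.0, 680.0, 705.0, 730.0,
                           760.0, 840.0, 900.0, 950.0, 980.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Generation settings. Defaults mirror a 176-band VNIR acquisition of
    mandarins with °Brix labels distributed like a commercial harvest."""

    n_bands: int = 176
    height: int = 32
    width: int = 32
    wavelength_range: tuple[float, float] = (404.7, 1010.8)
    ssc_range: tuple[float, float] = (6.8, 14.1)
    ssc_mean: float = 10.23
    ssc_sd: float = 1.35
    informative_bands: frozenset[int] | None = None
    noise_sd: float = 0.01
    band_gain_sd: float = 0.05    # per-sample per-band gain dispersion
    n_samples: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.n_bands < 8:
            raise InvalidConfigError("n_bands must be >= 8")
        if self.height < 1 or self.width < 1:
            raise InvalidConfigError("spatial dims must be positive")
        if not self.ssc_range[0] < self.ssc_range[1]:
            raise InvalidConfigError("ssc_range min must be < max")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be nonnegative")
        if self.n_samples < 1:
            raise InvalidConfigError("n_samples must be >= 1")
        bands = self.resolved_informative_bands()
        if any(b < 0 or b >= self.n_bands for b in bands):
            raise InvalidConfigError("informative_bands out of range")

    def resolved_informative_bands(self) -> tuple[int, ...]:
        if self.informative_bands is not None:
            return tuple(sorted(self.informative_bands))
        lo, hi = self.wavelength_range
        wl = np.linspace(lo, hi, self.n_bands)
        idx = sorted({int(np.argmin(np.abs(wl - nm)))
                      for nm in _DEFAULT_INFORMATIVE_NM if lo <= nm <= hi})
        return tuple(idx)

    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_range[0], self.wavelength_range[1],
                           self.n_bands)


@dataclass
class PhantomSample:
    """One phantom fruit: raw cube, its reference frames, label and mask."""

    cube: np.ndarray          # (C, H, W) raw counts
    white_ref: np.ndarray     # (C, H, W)
    dark_ref: np.ndarray      # (C, H, W)
    ssc_label: float
    fruit_mask: np.ndarray    # (H, W) bool
    sample_id: str = ""


def make_endmembers(n_bands: int, wavelength_range=(404.7, 1010.8),
                    seed: int = 0) -> np.ndarray:
    """Three nonnegative spectral basis curves in [0, 1], shape (3, n_bands).

    Row 0: pigment-absorption dip in the blue; row 1: red-edge sigmoid
    (monotone increasing); row 2: near-infrared water decline.
    A small seeded smooth perturbation makes repeated instruments distinct
    while preserving shape and bounds.
    """
    if n_bands < 8:
        raise InvalidConfigError("n_bands must be >= 8 to resolve endmembers")
    lo, hi = wavelength_range
    wl = np.linspace(lo, hi, n_bands)
    rng = np.random.default_rng(seed)

    pigment = 0.75 - 0.55 * np.exp(-((wl - 460.0) / 45.0) ** 2) \
        - 0.25 * np.exp(-((wl - 670.0) / 35.0) ** 2)
    red_edge = 0.08 + 0.80 / (1.0 + np.exp(-(wl - 705.0) / 18.0))
    water = 0.88 - 0.50 / (1.0 + np.exp(-(wl - 955.0) / 28.0))

    curves = np.stack([pigment, red_edge, water])
    # smooth seeded jitter, amplitude 0.01
    from scipy.ndimage import gaussian_filter1d

    jitter = gaussian_filter1d(rng.normal(0.0, 1.0, size=(3, n_bands)),
                               sigma=3.0, axis=1, mode="nearest")
    curves = np.clip(curves + 0.01 * jitter, 0.0, 1.0)
    return curves


def sweetness_endmember(config: PhantomConfig) -> np.ndarray:
    """Unit-peak curve supported (narrow Gaussian bumps) on the planted
    informative bands; all other bands are essentially zero."""
    idx = np.asarray(config.resolved_informative_bands())
    bands = np.arange(config.n_bands)
    curve = np.zeros(config.n_bands)
    for b in idx:
        curve += np.exp(-0.5 * ((bands - b) / 0.7) ** 2)
    return curve / curve.max()


def _sweetness_abundance(config: PhantomConfig, ssc: float) -> float:
    lo, hi = config.ssc_range
    return (ssc - lo) / (hi - lo)          # in [0, 1], affine in ssc


_BASE_ABUNDANCES = np.array([0.30, 0.25, 0.15])
_SWEET_AMPLITUDE = 0.25


def _seedseq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)


def analytic_fruit_spectrum(config: PhantomConfig, ssc: float,
                            seed) -> np.ndarray:
    """Closed-form per-band fruit reflectance (before spatial shading),
    reproducing exactly what `generate_sample` plants for the same seed.

    Includes the seeded per-sample variation: endmember-abundance jitter and
    a per-band multiplicative gain (pushbroom sensors drift band-wise, which
    is what makes reading a trait from several redundant bands worthwhile).
    """
    rng = np.random.default_rng(_seedseq(seed).spawn(2)[0])
    em = make_endmembers(config.n_bands, config.wavelength_range, config.seed)
    abund = _BASE_ABUNDANCES * (1.0 + 0.05 * rng.normal(size=3))
    mix = abund @ em
    mix = mix + _SWEET_AMPLITUDE * _sweetness_abundance(config, ssc) \
        * sweetness_endmember(config)
    gain = 1.0 + config.band_gain_sd * rng.normal(size=config.n_bands)
    return np.clip(mix * gain, 0.0, 0.98)


def _shading(config: PhantomConfig) -> np.ndarray:
    """Deterministic radial brightness falloff over the fruit surface."""
    h, w = config.height, config.width
    rr, cc = np.mgrid[0:h, 0:w]
    r2 = ((rr - (h - 1) / 2) / max(h / 2, 1)) ** 2 \
        + ((cc - (w - 1) / 2) / max(w / 2, 1)) ** 2
    return 1.0 - 0.25 * np.clip(r2, 0.0, 1.0)


def fruit_ellipse_mask(config: PhantomConfig) -> np.ndarray:
    h, w = config.height, config.width
    rr, cc = np.mgrid[0:h, 0:w]
    return (((rr - (h - 1) / 2) / (0.42 * h)) ** 2
            + ((cc - (w - 1) / 2) / (0.46 * w)) ** 2) <= 1.0


def reference_frames(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-band white/dark reference frames, broadcast to cube shape."""
    wl = config.wavelengths()
    white_curve = 4000.0 * (0.55 + 0.45 * np.exp(-((wl - 780.0) / 280.0) ** 2))
    dark_curve = 120.0 + 10.0 * (wl - wl[0]) / (wl[-1] - wl[0])
    shape = (config.n_bands, config.height, config.width)
    white = np.broadcast_to(white_curve[:, None, None], shape).copy()
    dark = np.broadcast_to(dark_curve[:, None, None], shape).copy()
    return white, dark


def generate_sample(config: PhantomConfig, ssc_value: float,
                    seed) -> PhantomSample:
    """One phantom fruit with raw counts I = D + R*(W-D) plus sensor noise.

    With ``noise_sd == 0`` the calibrated cube equals the analytic mixture
    times the deterministic shading field exactly.
    """
    config.validate()
    lo, hi = config.ssc_range
    if not (lo <= ssc_value <= hi):
        raise InvalidLabelError(
            f"ssc {ssc_value} outside configured range {config.ssc_range}")
    noise_rng = np.random.default_rng(_seedseq(seed).spawn(2)[1])
    white, dark = reference_frames(config)
    mask = fruit_ellipse_mask(config)
    shade = _shading(config)

    spectrum = analytic_fruit_spectrum(config, ssc_value, seed)
    refl = np.where(mask[None], spectrum[:, None, None] * shade[None], 0.02)
    cube = dark + refl * (white - dark)
    if config.noise_sd > 0:
        cube = cube + noise_rng.normal(0.0, config.noise_sd,
                                       size=cube.shape) * (white - dark)
        cube = np.clip(cube, dark, white)
    return PhantomSample(cube=cube, white_ref=white, dark_ref=dark,
                         ssc_label=float(ssc_value), fruit_mask=mask)


def draw_labels(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """SSC labels from a normal truncated to ``ssc_range``."""
    lo, hi = config.ssc_range
    a = (lo - config.ssc_mean) / config.ssc_sd
    b = (hi - config.ssc_mean) / config.ssc_sd
    return stats.truncnorm.rvs(a, b, loc=config.ssc_mean, scale=config.ssc_sd,
                               size=config.n_samples, random_state=rng)


def generate_dataset(config: PhantomConfig, out_dir=None
                     ) -> tuple[list[PhantomSample], pd.DataFrame]:
    """Generate ``config.n_samples`` phantoms plus a manifest table.

    If ``out_dir`` is given, cubes and reference frames are written as
    multi-page TIFFs (one page per band) and the manifest as CSV with
    columns id, path, ssc.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = draw_labels(config, rng)
    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_samples)
    samples, rows = [], []
    for i, (ssc, ss) in enumerate(zip(labels, child_seeds)):
        sample = generate_sample(config, float(ssc), ss)
        sample.sample_id = f"phantom_{i:04d}"
        path = ""
        if out_dir is not None:
            from . import preprocess
            from pathlib import Path

            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            path = str(out / f"{sample.sample_id}.tif")
            preprocess.write_array_tiff(path, sample.cube)
            if i == 0:
                preprocess.write_array_tiff(str(out / "white_ref.tif"),
                                            sample.white_ref)
                preprocess.write_array_tiff(str(out / "dark_ref.tif"),
                                            sample.dark_ref)
        samples.append(sample)
        rows.append({"id": sample.sample_id, "path": path,
                     "ssc": float(ssc)})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path

        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return samples, manifest


def calibrated_dataset(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: stacked calibrated+normalized cubes and labels.

    Returns (X, y) with X of shape (n, C, H, W) in [0, 1]. This is the
    standard entry point for training experiments on phantoms.
    """
    from .preprocess import HyperCube, ReferenceFrames, calibrate_reflectance

    samples, manifest = generate_dataset(config)
    cubes = []
    for s in samples:
        cube = HyperCube(values=s.cube, wavelengths=config.wavelengths(),
                         provenance="raw")
        refs = ReferenceFrames(white=s.white_ref, dark=s.dark_ref)
        cal = calibrate_reflectance(cube, refs)
        cubes.append(np.clip(cal.values, 0.0, 1.0))
    return np.stack(cubes), manifest["ssc"].to_numpy()
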