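# brixband

Reconstruction-assisted, attention-guided **spectral band selection** for
non-destructive prediction of **soluble solids content** (SSC, °Brix) from
visible/near-infrared hyperspectral cubes of intact fruit.

Hyperspectral imaging gives a cube `X ∈ R^{C×H×W}` per fruit — rich, but
redundant and expensive to acquire. For quality grading one wants a small
subset of `K` of the `C` wavelengths that still predicts internal sweetness
well, so that a cheap multispectral sensor can replace the full instrument.
`brixband` learns that subset end-to-end instead of screening wavelengths
offline: a differentiable selector is trained jointly with an SSC regressor
and a full-cube reconstructor, so the retained bands are simultaneously
*task-relevant* (they predict °Brix) and *information-preserving* (the full
spectrum can be approximately recovered from them).

The package is aimed at researchers in fruit-quality spectroscopy and
hyperspectral method development. Because datasets of this kind are
instrument-bound, it ships a synthetic fruit-phantom generator with a fully
known SSC-generating mechanism, so every stage is testable end-to-end.

## The method

Spectral attention scores each band, `a = σ(MLP(GAP(X))) ∈ (0,1)^C`, and
spatial attention produces a mask `M_S ∈ (0,1)^{H×W}`. Selection stays
differentiable through a thresholded-sigmoid relaxation with adaptive
threshold `τ` and temperature `T`:

    p_i = σ((a_i − τ)/T) / Σ_j σ((a_j − τ)/T)

The band budget is enforced through a smooth pass count
`K~ = Σ_i σ((a_i − τ)/T_pass)` and the regularizer
`L_pass = ½ (K~ − K)²`. The softly gated cube
`X_soft[i] = X[i]·M_S·σ((a_i − τ)/T)` feeds two branches — a U-Net-style
reconstructor `X̂ = f_rec(·)` trained with mean-squared error, and a
compact regression head `ŷ = f_reg(·)` (depthwise-separable convolution,
efficient channel attention, generalized-mean pooling) trained with the
Huber loss (`δ` = 1 °Brix). The joint objective

    L = α_t·L_rec + β_t·L_reg + λ·L_pass

shifts emphasis from reconstruction to regression over a three-stage
schedule (joint exploration → attention frozen, selection stabilizes →
band-selection frequencies fixed into a discrete top-K subset, regression
fine-tunes on it). Details, defaults and design choices are in
[docs/methods.md](docs/methods.md).

All trainable parts run on the package's own compact numpy reverse-mode
autodiff core (`brixband.autodiff`, `brixband.nn`), with gradients verified
against finite differences in the test suite.

## Worked example

Simulate a 48-band phantom orchard, train with a 12-band budget, and
inspect the result (about two minutes on a laptop CPU):

```sh
cat > fruit.yaml <<'YAML'
seed: 7
K: 12
phantom:
  n_bands: 48
  height: 24
  width: 24
  n_samples: 48
plan:
  stage_epochs: [30, 15, 5]
  lr: 0.003
  weight_decay: 0.001
  base_width: 8
YAML

brixband simulate --config fruit.yaml --out data
brixband train    --config fruit.yaml --manifest data/manifest.csv --out run
brixband evaluate --run run
brixband select-bands --run run
```

which prints

```
wrote 48 phantom cubes to data
selected 12 bands; test RMSE 1.065 °Brix, R² 0.384
{"mae": 0.6406, "rmse": 1.0648, "r2": 0.3844, "rpd": 1.2746}
 band_index  wavelength_nm  frequency
          0          404.7        526
          5          469.2        575
         19          649.7        575
         20          662.6        426
         25          727.1        575
 ...
```

Reading the output: the trainer fixed 12 of 48 bands from the selection
frequencies accumulated in the stabilization stage; on the held-out test
fruits the 12-band model predicts SSC with an RMSE of 1.06 °Brix against
labels spread with SD ≈ 1.35 °Brix (R² 0.38, RPD 1.3 — screening-level
accuracy, as expected at this tiny training scale). The band table maps
each retained index to its wavelength; the frequency column shows how
consistently each band passed the threshold during stabilization. The run
directory also holds `logs.csv` (per-epoch losses and validation metrics,
enough to plot the training curves), `per_epoch_subsets.csv` (for the
`brixband stability` report), a config snapshot and a checkpoint usable by
`brixband predict` / `brixband reconstruct`.

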