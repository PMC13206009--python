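# Methods

`brixband` implements a unified *select–reconstruct–predict* pipeline for
estimating soluble solids content (SSC, °Brix) of intact fruit from
visible/near-infrared hyperspectral cubes, together with the preprocessing,
distribution-balanced data splitting, progressive training schedule and
evaluation metrics that such a pipeline needs, and a synthetic phantom
generator that makes every stage testable without instrument data.

## The model

A calibrated, normalized cube `X ∈ R^{C×H×W}` first passes through two
attention branches:

- **Spatial attention.** Band-wise average and max maps are concatenated and
  convolved to a single-channel logit map; a logistic squashing gives a mask
  `M_S ∈ (0,1)^{H×W}` that emphasizes spatially informative fruit regions.
- **Spectral attention.** Global average pooling over the spatial axes gives
  a per-band descriptor; a small two-layer perceptron followed by a logistic
  yields a band-importance vector `a ∈ (0,1)^C`.

Band selection is kept differentiable through a thresholded-sigmoid
relaxation. With adaptive threshold `τ` and temperature `T`,

    p_i = σ((a_i − τ)/T) / Σ_j σ((a_j − τ)/T),

which, unlike a softmax, does not cancel `τ` by shift invariance: bands
below threshold are genuinely suppressed. The *soft pass count*

    K~ = Σ_i σ((a_i − τ)/T_pass)

estimates how many bands effectively pass, and the budget regularizer
`L_pass = ½ (K~ − K)²` ties it to the target band count `K`. During training
the cube is gated softly, `X_soft[i] = X[i] · M_S · σ((a_i − τ)/T)`, so
gradients from both downstream branches reach `a`.

Two branches consume the compact representation:

- **Reconstruction** `X̂ = f_rec(X_K)`: a two-level U-Net-style
  encoder–decoder with skip connections and a logistic output in [0,1].
  Its mean-squared error against the full cube discourages the selector
  from collapsing onto a narrow, dataset-specific subset.
- **Regression** `ŷ = f_reg(X_K)`: depthwise-separable convolution,
  efficient channel attention (a 1-D convolution over the pooled channel
  descriptor), generalized-mean pooling with a trainable exponent, and an
  affine head. The head is parameterized as `ŷ = μ_y + s_y · f(X_K)` with
  `μ_y, s_y` set from the training labels, so the network body works at
  unit scale while predictions stay in °Brix. The regression loss is the
  Huber loss with knee `δ` (default 1 °Brix; labels are never
  standardized, so all reported errors are in °Brix).

The joint objective is

    L = α_t · L_rec + β_t · L_reg + λ · L_pass,

with `α_t` decreasing linearly 1.0 → 0.1 and `β_t` increasing 0.1 → 1.0
across Stages 0–1, both constant in Stage 2, and fixed `λ` (default 0.01).

## Progressive schedule and top-K fixation

Training proceeds in three stages (default split 40/30/10 of an 80-epoch
budget; every experiment in this repository uses proportionally shortened
schedules):

- **Stage 0 (exploration).** All modules train jointly.
- **Stage 1 (stabilization).** The attention modules are frozen; selector,
  reconstructor and regressor continue. On every forward pass the selection
  event `a_i > τ` is counted per sample; at the end of the stage the counts
  accumulated on the training and validation subsets (using the
  best-validation weights) rank the bands.
- **Fixation.** The `K` most frequently selected bands, ties broken by
  higher running-mean importance then lower index, become the fixed subset;
  non-selected bands are zero-masked so all downstream shapes stay static.
- **Stage 2 (refinement).** Only the regression head fine-tunes on the
  hard-masked input.

`τ` is not a free parameter: each forward pass it moves toward the
`(1 − K/C)` empirical quantile of the current batch's importance scores
under an exponential moving average (momentum 0.9), so the expected pass
count tracks `K`. `T` anneals geometrically 1.0 → 0.1 over Stages 0–1
(exploration first, commitment later); `T_pass` stays at 0.1.

## Numerical core

All trainable components run on a compact reverse-mode automatic
differentiation engine written on numpy (float64): define-by-run graphs,
explicit backward closures per primitive, im2col convolutions, and an Adam
optimizer with optional decoupled weight decay. Every primitive's gradient
is tested against central finite differences, as are the composite
attention and pass-count gradients. Frozen modules are excluded from
updates by a per-parameter flag; freeze contracts are verified by hashing
parameter values across stage boundaries.

Weight decay earns a note: with spectrally redundant inputs, ridge-style
shrinkage makes spreading weight across correlated bands strictly cheaper
than concentrating it, which converts the otherwise flat
"average-many-bands" direction into a first-order descent direction. Desk-
scale experiments therefore run with `weight_decay = 1e-3` and a slightly
higher learning rate (3e-3) than the library default (1e-3); both are
ordinary small-sample choices and are recorded in each experiment's plan.

## Preprocessing and splitting

Raw counts calibrate to reflectance as `R = (I − D)/(W − D)` with white and
dark reference frames; a non-positive denominator raises an error naming
the offending bands. Cubes normalize per cube by clipping to the 1st/99th
percentiles and min–max scaling to [0,1]; degenerate cubes yield zeros with
a warning. Stored cubes may be band-first or band-last; orientation is
resolved against the expected band count, with truncation or edge padding
(last band replicated) when counts differ. Patching is random-crop in
training and center-crop in evaluation, with reflective padding when the
cube is smaller than the patch; augmentation applies horizontal flip,
vertical flip and a 90° rotation independently with probability 0.5 each
(the transform set is fixed; the probability is this package's choice).

The train/validation/test split (default 8:1:1, largest-remainder sizes)
balances three standardized cost components: mean pairwise Jensen–Shannon
divergence between subset label histograms on quantile bins; absolute
deviations of subset mean and standard deviation from the global values for
label and mean intensity (scaled by the global standard deviation); and the
L2 distance between each subset's average spectrum and the global average
(scaled by the global spectrum norm). Unit weights on the standardized
components. A stratified initialization over (label-bin × intensity-bin)
cells is refined by first-improvement cross-subset swaps accepted only on a
strict cost decrease, with fixed subset sizes, a swap-budget cap and full
determinism under the seed.

## Metrics

Reconstruction: voxel MAE and MSE; PSNR = 10·log10(MAX²/MSE) with MAX = 1
on the normalized reflectance scale (infinite when MSE = 0); SSIM computed
band-wise from global statistics with stabilizers C1 = 0.01², C2 = 0.03²
and averaged over bands (an 11×11 Gaussian-window mode is available and
matches scikit-image); SCC, the Pearson correlation between the true and
reconstructed spectrum at each pixel, averaged (zero-variance pixels
contribute 0); SAM, the spectral angle per pixel in degrees, averaged.
Regression: MAE, RMSE, R² = 1 − SSres/SStot, and RPD = SD(y)/RMSE, so
RPD·RMSE equals the label standard deviation identically. Band index `i`
maps to wavelength by the uniform affine map sending 0 and C−1 to the
instrument range endpoints (404.7 and 1010.8 nm at C = 176).

## The phantom generator

Real cubes of this kind are instrument-bound and large; the generator
produces small phantoms whose SSC mechanism is fully known:

- Three smooth endmembers imitate fruit reflectance: a blue pigment
  absorption dip, a red-edge sigmoid, and a near-infrared water decline.
- A "sweetness" endmember, supported only on a configured set of
  informative bands (by default twelve pigment-, red-edge- and
  water-associated wavelengths mapped to the nearest band), enters the
  mixture with abundance affine in the SSC label. Labels draw from a
  normal with mean 10.23 and SD 1.35 °Brix truncated to [6.8, 14.1].
- Per-sample nuisance: endmember-abundance jitter (5%), a per-band
  multiplicative gain (SD 0.05) imitating band-wise sensor drift — chosen
  so that the gain-limited error of reading the label from a single
  informative band (~0.65 °Brix) versus all eight (~0.23 °Brix) spans the
  RMSE regime the method operates in — a deterministic radial shading
  field, an elliptical fruit mask over a near-dark background, and
  optional i.i.d. Gaussian noise on raw counts, clipped to the reference
  frames.
- Raw counts are synthesized against smooth per-band white/dark reference
  frames, so the standard calibration applies; with noise off, the
  calibrated cube equals the analytic closed form to machine precision.

The generator does **not** model radiative transfer, peel texture, specular
highlights, or the instrument line-spread function. Phantom results
therefore validate the machinery (gradients, schedules, contracts, metric
algebra, information-monotonicity) and the planted-signal identifiability
of the data — not field performance on real fruit.

Problem sizes are deliberately small: phantoms default to 32×32 pixels
(24×24 in the 176-band operating-point run), 16×16 at C = 32 for the
selection experiments, and schedules of a few hundred steps. The package's
defaults for patching (448) and epochs (80) reflect the instrument-scale
settings and are used only as defaults.

## Packaged experiments

- `topk_cardinality_run`: 64 phantoms at C = 176, three stages at reduced
  epochs (6/4/2), budget K = 56; the quantity of record is the cardinality
  of the fixed subset, which is exactly K by construction of the fixation.
- `zero_noise_regression`: regression head alone on noise-free phantoms
  (all stochastic nuisance terms off); held-out R² isolates head capacity.
- `recon_dominance_sweep`: nested prefix subsets of one seeded band
  ordering; a fresh reconstructor per (seed, K) at an equal step budget;
  the seed-averaged MSE-versus-K curve is rank-tested. Nesting makes each
  larger budget a strict information superset, which keeps the comparison
  matched; the pipeline-level `sweep_k` table mixes selection noise into
  the reconstruction column at these scales and is kept for its tabulation
  contract.
- `planted_band_recovery`: the full selector + regressor protocol at
  K = 8 on 32-band phantoms with 8 planted bands, repeated over ten run
  seeds; reports the overlap of each fixed subset with the planted set.

## Known limitations

The recovery experiment documents the clearest one: at desk scale the
per-band task gradient reaching the importance vector through the soft gate
is two to three orders of magnitude weaker than the budget-constraint and
threshold dynamics, so which bands pass the threshold bifurcates early and
locks in by positive feedback before the regression head has learned which
bands matter; the fixed subset then overlaps the planted set only at
chance-to-modest levels (2–5 of 8 across seeds). Weight decay, temperature
schedules, budget-weight settings and reconstruction assistance shift but
do not break this regime at these sample counts and step budgets. The
correlation oracle on the same phantoms ranks the planted bands essentially
perfectly, so the limitation is one of end-to-end gradient-driven selection
at small scale, not of the data. Larger sample counts, longer schedules and
larger spatial contexts — the regime the architecture targets — are outside
what this desk-scale suite can verify.

Other limitations: the engine is CPU/numpy float64 and deliberately small;
no scatter correction or derivative spectra are implemented (out of scope);
the splitter optimizes a local first-improvement criterion, not a global
optimum; checkpoints store weights, not optimizer state.
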