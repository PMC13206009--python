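"""Joint objective and the three-stage exploration-stabilization-refinement
training procedure.

The total objective is  L = alpha_t * L_rec + beta_t * L_reg + lambda * L_pass
with alpha_t decreasing linearly 1.0 -> 0.1 and beta_t increasing 0.1 -> 1.0
over Stages 0-1, then held constant in Stage 2. Stage 0 trains every module
jointly; Stage 1 freezes the attention modules while selector, reconstructor
and regressor continue; between Stages 1 and 2 the accumulated selection
frequencies are fixed into a discrete top-K subset; Stage 2 fine-tunes only
the regression head on the hard-masked compact input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics, models, nn, selector as sel
from .autodiff import Tensor


@dataclass(frozen=True)
class LossWeights:
    alpha: float
    beta: float
    lam: float


@dataclass
class StagePlan:
    stage_epochs: tuple[int, int, int] = (40, 30, 10)
    batch_size: int = 8
    lr: float = 1e-3
    weight_decay: float = 0.0
    lam: float = 0.01
    huber_delta: float = 1.0      # °Brix
    t_start: float = 1.0
    t_end: float = 0.1
    use_recon: bool = True
    base_width: int = 16
    reg_width: int = 32
    seed: int = 0

    @property
    def total_epochs(self) -> int:
        return sum(self.stage_epochs)


def schedule_weights(epoch: int, stage_epochs: tuple[int, int, int],
                     lam: float = 0.01) -> LossWeights:
    """Linear alpha 1.0 -> 0.1 and beta 0.1 -> 1.0 across Stages 0-1;
    constants (0.1, 1.0) within Stage 2."""
    total = sum(stage_epochs)
    if not 0 <= epoch < total:
        raise ValueError("epoch outside the training schedule")
    e01 = stage_epochs[0] + stage_epochs[1]
    if epoch >= e01:
        return LossWeights(alpha=0.1, beta=1.0, lam=lam)
    t = epoch / (e01 - 1) if e01 > 1 else 1.0
    return LossWeights(alpha=1.0 + t * (0.1 - 1.0),
                       beta=0.1 + t * (1.0 - 0.1), lam=lam)


def total_loss(l_rec, l_reg, l_pass, weights: LossWeights):
    """Weighted sum of the three components; components must be >= 0."""
    for name, comp in (("rec", l_rec), ("reg", l_reg), ("pass", l_pass)):
        val = comp.data if isinstance(comp, Tensor) else comp
        if not np.all(np.isfinite(val)) or np.any(np.asarray(val) < 0):
            raise ValueError(f"loss component {name} must be finite and >= 0")
    return l_rec * weights.alpha + l_reg * weights.beta + l_pass * weights.lam


class JointModel(nn.Module):
    """Attention + differentiable selector + reconstruction + regression."""

    def __init__(self, n_bands: int, config: sel.SelectorConfig,
                 rng: np.random.Generator, base_width: int = 16,
                 reg_width: int = 32, y_mean: float = 0.0,
                 y_scale: float = 1.0, use_recon: bool = True):
        super().__init__()
        config.validate()
        self.config = config
        self.use_recon = use_recon
        self.spatial_att = sel.SpatialAttention(rng)
        self.spectral_att = sel.SpectralAttention(n_bands, rng)
        if use_recon:
            self.recon = models.ReconstructionUNet(n_bands, rng,
                                                   base_width=base_width)
        self.reghead = models.RegressionHead(n_bands, rng, width=reg_width,
                                             y_mean=y_mean, y_scale=y_scale)
        self.state = sel.SelectionState.fresh(n_bands)

    def forward_soft(self, x: Tensor, T: float) -> dict:
        a = self.spectral_att(x)                       # (N, C)
        m_s = self.spatial_att(x)                      # (N, 1, H, W)
        gated = sel.soft_gate(x, m_s, a, self.state.tau, T)
        out = {"a": a, "m_s": m_s, "gated": gated}
        k_tilde = sel.soft_pass_count(a, self.state.tau,
                                      self.config.T_pass).mean()
        out["k_tilde"] = k_tilde
        out["y_hat"] = self.reghead(gated)
        if self.use_recon:
            out["x_hat"] = self.recon(gated)
        return out

    def forward_hard(self, x: Tensor, bands: np.ndarray,
                     with_recon: bool = False) -> dict:
        compact = sel.hard_subset(x, bands)
        out = {"y_hat": self.reghead(compact.values)}
        if with_recon and self.use_recon:
            out["x_hat"] = self.recon(compact.values)
        return out


@dataclass
class TrainResult:
    model: JointModel
    selected_bands: np.ndarray
    logs: pd.DataFrame
    state: sel.SelectionState
    per_epoch_subsets: list[np.ndarray]
    stage_hashes: dict[str, str] = field(default_factory=dict)


def _validation_metrics(y: np.ndarray, y_pred: np.ndarray) -> metrics.RegMetrics:
    """Validation scoring tolerant of degenerate tiny subsets."""
    try:
        return metrics.reg_metrics(y, y_pred)
    except ValueError:
        res = np.asarray(y) - np.asarray(y_pred)
        rmse = float(np.sqrt(np.mean(res ** 2)))
        return metrics.RegMetrics(mae=float(np.abs(res).mean()), rmse=rmse,
                                  r2=float("nan"), rpd=float("nan"))


class ProgressiveTrainer:
    """Runs the staged schedule on in-memory arrays.

    ``x_train``/``x_val`` are (N, C, H, W) cubes in [0, 1]; labels in °Brix.
    """

    def __init__(self, x_train: np.ndarray, y_train: np.ndarray,
                 x_val: np.ndarray, y_val: np.ndarray,
                 selector_config: sel.SelectorConfig, plan: StagePlan):
        selector_config.validate()
        self.x_train, self.y_train = x_train, y_train
        self.x_val, self.y_val = x_val, y_val
        self.plan = plan
        self.rng = np.random.default_rng(plan.seed)
        self.model = JointModel(
            n_bands=x_train.shape[1], config=selector_config, rng=self.rng,
            base_width=plan.base_width, reg_width=plan.reg_width,
            y_mean=float(np.mean(y_train)),
            y_scale=float(np.std(y_train)) or 1.0, use_recon=plan.use_recon)
        self.optimizer = nn.Adam(self.model.parameters(), lr=plan.lr,
                                 weight_decay=plan.weight_decay)
        self.logs: list[dict] = []
        self.per_epoch_subsets: list[np.ndarray] = []
        self.selected_bands: np.ndarray | None = None
        self._next_stage = 0
        self._best_val = np.inf
        self._best_state: dict | None = None
        self._epoch = 0

    # ---- helpers ---------------------------------------------------------

    def _batches(self, n: int):
        order = self.rng.permutation(n)
        bs = self.plan.batch_size
        for i in range(0, n, bs):
            yield order[i:i + bs]

    def _temperature(self) -> float:
        e01 = self.plan.stage_epochs[0] + self.plan.stage_epochs[1]
        return sel.anneal_temperature(self._epoch, e01, self.plan.t_start,
                                      self.plan.t_end)

    def _val_predictions(self) -> np.ndarray:
        preds = []
        xv = self.x_val
        for i in range(0, len(xv), self.plan.batch_size):
            xb = Tensor(xv[i:i + self.plan.batch_size])
            if self.selected_bands is not None:
                out = self.model.forward_hard(xb, self.selected_bands)
            else:
                out = self.model.forward_soft(xb, self._temperature())
            preds.append(out["y_hat"].data)
        return np.concatenate(preds)

    def _count_val_frequencies(self) -> None:
        for i in range(0, len(self.x_val), self.plan.batch_size):
            xb = Tensor(self.x_val[i:i + self.plan.batch_size])
            a = self.model.spectral_att(xb)
            sel.update_frequencies(self.model.state, a.data)

    def _train_epoch(self, stage_id: int) -> dict:
        plan, model = self.plan, self.model
        T = self._temperature()
        weights = schedule_weights(self._epoch, plan.stage_epochs, plan.lam)
        sums = {"rec": 0.0, "reg": 0.0, "pass": 0.0, "total": 0.0}
        n_batches = 0
        for idx in self._batches(len(self.x_train)):
            xb = Tensor(self.x_train[idx])
            yb = self.y_train[idx]
            self.optimizer.zero_grad()
            if stage_id < 2:
                out = model.forward_soft(xb, T)
                l_rec = models.rec_loss(out["x_hat"], xb) \
                    if plan.use_recon else Tensor(0.0)
                l_reg = models.huber(yb, out["y_hat"], plan.huber_delta)
                l_pass = sel.pass_loss(out["k_tilde"], model.config.K)
                loss = total_loss(l_rec, l_reg, l_pass, weights)
                # bookkeeping on detached importance values
                a_vals = out["a"].data
                sel.adaptive_tau(model.state, a_vals, model.config.K,
                                 model.config.tau_momentum)
                if stage_id == 1:
                    sel.update_frequencies(model.state, a_vals)
            else:
                out = model.forward_hard(xb, self.selected_bands)
                l_rec, l_pass = Tensor(0.0), Tensor(0.0)
                l_reg = models.huber(yb, out["y_hat"], plan.huber_delta)
                loss = total_loss(l_rec, l_reg, l_pass, weights)
            loss.backward()
            self.optimizer.step()
            for key, comp in (("rec", l_rec), ("reg", l_reg),
                              ("pass", l_pass), ("total", loss)):
                sums[key] += float(comp.data if isinstance(comp, Tensor)
                                   else comp)
            n_batches += 1
        return {k: v / max(n_batches, 1) for k, v in sums.items()}

    # ---- public API ------------------------------------------------------

    def run_stage(self, stage_id: int) -> None:
        """Execute one stage; stages must run in order 0, 1, 2."""
        if stage_id != self._next_stage:
            raise RuntimeError(
                f"stage {stage_id} requested but next stage is "
                f"{self._next_stage}")
        model, plan = self.model, self.plan

        if stage_id == 1:
            model.spatial_att.freeze()
            model.spectral_att.freeze()
            # frequency counting restarts so the deployable subset reflects
            # the stabilized selection phase only
            model.state.frequency[:] = 0
            model.state.a_sum[:] = 0
            model.state.n_passes = 0
        if stage_id == 2:
            if self._best_state is not None:
                self.model.load_state_dict(self._best_state)
            self._count_val_frequencies()
            self.selected_bands = sel.finalize_topk(
                model.state.frequency, model.config.K,
                model.state.a_running_mean)
            for mod in self.model._modules.values():
                mod.freeze()
            model.reghead.unfreeze()

        for _ in range(plan.stage_epochs[stage_id]):
            train_losses = self._train_epoch(stage_id)
            y_pred = self._val_predictions()
            val = _validation_metrics(self.y_val, y_pred)
            if stage_id < 2:
                subset_now = sel.finalize_topk(
                    model.state.frequency, model.config.K,
                    model.state.a_running_mean)
                self.per_epoch_subsets.append(subset_now)
                if val.rmse < self._best_val:
                    self._best_val = val.rmse
                    self._best_state = model.state_dict()
            self.logs.append({
                "stage": stage_id, "epoch": self._epoch,
                "T": self._temperature(), "tau": model.state.tau,
                "loss_rec": train_losses["rec"],
                "loss_reg": train_losses["reg"],
                "loss_pass": train_losses["pass"],
                "loss_total": train_losses["total"],
                "val_rmse": val.rmse, "val_r2": val.r2,
            })
            self._epoch += 1
        self._next_stage += 1

    def train(self) -> TrainResult:
        hashes = {}
        for stage in (0, 1, 2):
            self.run_stage(stage)
            hashes[f"after_stage_{stage}"] = self.model.param_hash()
        return TrainResult(model=self.model,
                           selected_bands=self.selected_bands,
                           logs=pd.DataFrame(self.logs),
                           state=self.model.state,
                           per_epoch_subsets=self.per_epoch_subsets,
                           stage_hashes=hashes)


def train_phantom_pipeline(x: np.ndarray, y: np.ndarray, K: int,
                           plan: StagePlan,
                           val_fraction: float = 0.2) -> TrainResult:
    """Convenience wrapper: seeded train/val split, then the full schedule."""
    rng = np.random.default_rng(plan.seed)
    n = len(x)
    order = rng.permutation(n)
    n_val = max(2, int(round(val_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    config = sel.SelectorConfig(K=K, n_bands=x.shape[1],
                                T=plan.t_start, T_end=plan.t_end)
    trainer = ProgressiveTrainer(x[train_idx], y[train_idx], x[val_idx],
                                 y[val_idx], config, plan)
    return trainer.train()


def evaluate_reconstruction(result: TrainResult, x_eval: np.ndarray,
                            batch_size: int = 8) -> metrics.ReconMetrics:
    """Reconstruction metrics from the hard-masked compact input."""
    model = result.model
    recs = []
    for i in range(0, len(x_eval), batch_size):
        xb = Tensor(x_eval[i:i + batch_size])
        out = model.forward_hard(xb, result.selected_bands, with_recon=True)
        recs.append(out["x_hat"].data)
    x_hat = np.concatenate(recs)
    per = [metrics.recon_metrics(xi, xh) for xi, xh in zip(x_eval, x_hat)]
    return metrics.ReconMetrics(
        mae=float(np.mean([m.mae for m in per])),
        mse=float(np.mean([m.mse for m in per])),
        psnr=float(np.mean([m.psnr for m in per])),
        ssim=float(np.mean([m.ssim for m in per])),
        scc=float(np.mean([m.scc for m in per])),
        sam=float(np.mean([m.sam for m in per])))


def predict(result: TrainResult, x_eval: np.ndarray,
            batch_size: int = 8) -> np.ndarray:
    preds = []
    for i in range(0, len(x_eval), batch_size):
        xb = Tensor(x_eval[i:i + batch_size])
        out = result.model.forward_hard(xb, result.selected_bands)
        preds.append(out["y_hat"].data)
    return np.concatenate(preds)


def save_checkpoint(result: TrainResult, path, config_hash: str = "") -> None:
    """Single-file weights + bookkeeping (band set, frequencies, config hash)."""
    import json

    model = result.model
    meta = {
        "n_bands": int(model.state.frequency.shape[0]),
        "K": int(model.config.K),
        "T_pass": model.config.T_pass,
        "use_recon": model.use_recon,
        "y_mean": model.reghead.y_mean,
        "y_scale": model.reghead.y_scale,
        "base_width": (model.recon.enc1.weight.shape[0]
                       if model.use_recon else 16),
        "reg_width": int(model.reghead.pointwise.weight.shape[0]),
        "tau": model.state.tau,
        "config_hash": config_hash,
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["selected_bands"] = np.asarray(result.selected_bands)
    arrays["frequency"] = model.state.frequency
    arrays["a_sum"] = model.state.a_sum
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[JointModel, np.ndarray]:
    """Rebuild the model and its fixed band subset from a checkpoint."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
        bands = data["selected_bands"].copy()
        frequency = data["frequency"].copy()
        a_sum = data["a_sum"].copy()
    cfg = sel.SelectorConfig(K=meta["K"], n_bands=meta["n_bands"],
                             T_pass=meta["T_pass"])
    model = JointModel(meta["n_bands"], cfg, np.random.default_rng(0),
                       base_width=meta["base_width"],
                       reg_width=meta["reg_width"], y_mean=meta["y_mean"],
                       y_scale=meta["y_scale"],
                       use_recon=meta["use_recon"])
    model.load_state_dict(state)
    model.state.frequency = frequency
    model.state.a_sum = a_sum
    model.state.tau = meta["tau"]
    return model, bands


def _normalize_column(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    return np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)


def sweep_k(candidate_Ks, x: np.ndarray, y: np.ndarray, plan: StagePlan,
            val_fraction: float = 0.25) -> pd.DataFrame:
    """Scaled-down training per candidate K; tabulates the compactness /
    fidelity / prediction trade-off with [0, 1]-normalized metric columns."""
    ks = sorted(set(int(k) for k in candidate_Ks))
    if len(ks) < 2:
        raise ValueError("need at least two candidate K values")
    rng = np.random.default_rng(plan.seed)
    n = len(x)
    order = rng.permutation(n)
    n_val = max(2, int(round(val_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    rows = []
    for k in ks:
        cfg = sel.SelectorConfig(K=k, n_bands=x.shape[1], T=plan.t_start,
                                 T_end=plan.t_end)
        trainer = ProgressiveTrainer(x[train_idx], y[train_idx], x[val_idx],
                                     y[val_idx], cfg, plan)
        result = trainer.train()
        rec = evaluate_reconstruction(result, x[val_idx],
                                      plan.batch_size) if plan.use_recon \
            else None
        reg = metrics.reg_metrics(y[val_idx], predict(result, x[val_idx]))
        rows.append({"K": k,
                     "rec_mse": rec.mse if rec else np.nan,
                     "rec_psnr": rec.psnr if rec else np.nan,
                     "reg_rmse": reg.rmse, "reg_r2": reg.r2})
    table = pd.DataFrame(rows)
    table["rec_mse_norm"] = _normalize_column(table["rec_mse"].to_numpy()) \
        if plan.use_recon else np.nan
    table["reg_r2_norm"] = _normalize_column(table["reg_r2"].to_numpy())
    return table
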