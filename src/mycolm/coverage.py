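"""Supervised transfer: binned coverage targets, fine-tuned model, ensembling.

The coverage model reuses the language model's encoder + transformer trunk
and a shortened decoder that stops at bin resolution (16 bp by default at
full scale); edge bins are cropped and a dense projection with softplus
emits one nonnegative value per track.  Training minimizes a Poisson +
multinomial loss: a Poisson negative log-likelihood on the per-window total
count plus a scaled multinomial negative log-likelihood of the observed
allocation of that total across bins (additive constants independent of the
prediction are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import io as mio
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Module, Dense
from .nn.optim import Adam
from .lm_core import (LmConfig, LanguageModel, Trunk, _DecoderStage,
                      encode_input, _snapshot, _restore)

CROP_BP = 1_024
BIN_WIDTH = 16
N_BINS = 896
CROP_BINS = 64
MULT_SCALE = 5.0


@dataclass
class BinnedTarget:
    """Per-track binned coverage for one window."""

    window_id: str
    values: np.ndarray               # (n_bins,) or (n_bins, n_tracks)
    track_names: list[str] | None = None
    assay_groups: list[str] | None = None


def bin_coverage(values, window=None, crop: int = CROP_BP,
                 bin_width: int = BIN_WIDTH) -> BinnedTarget:
    """Median-impute missing bases, crop both ends, and sum fixed-width bins."""
    values = np.asarray(values, dtype=float).copy()
    missing = np.isnan(values)
    if missing.all():
        raise ValueError("all per-base values are missing")
    if missing.any():
        values[missing] = np.median(values[~missing])
    interior = values[crop:len(values) - crop] if crop else values
    n_bins = len(interior) // bin_width
    binned = interior[:n_bins * bin_width].reshape(n_bins, bin_width).sum(axis=1)
    # kept in double precision here; shard serialization may downcast to float16
    return BinnedTarget(window_id=getattr(window, "window_id", ""),
                        values=binned)


def window_targets(windows, coverage, crop: int = CROP_BP,
                   bin_width: int = BIN_WIDTH) -> np.ndarray:
    """(n_windows, n_bins, n_tracks) binned targets from a CoverageSet."""
    out = []
    for w in windows:
        per_track = []
        for name in coverage.track_names:
            base = coverage.tracks[name][w.chrom][w.start:w.end]
            per_track.append(bin_coverage(base, w, crop, bin_width).values)
        out.append(np.stack(per_track, axis=1))
    return np.stack(out)


# ---------------------------------------------------------------------------
# model

class CoverageModel(Module):
    """LM trunk + shortened decoder + cropped multi-track softplus head."""

    def __init__(self, config: LmConfig, n_tracks: int,
                 decoder_stages: int = 3, crop_bins: int = CROP_BINS,
                 rng=None):
        cfg = config.validate()
        self.config = cfg
        self.n_tracks = n_tracks
        self.decoder_stages = decoder_stages
        self.crop_bins = crop_bins
        bin_positions = cfg.L // 2 ** (cfg.stages - decoder_stages)
        self.n_bins = bin_positions - 2 * crop_bins
        if self.n_bins <= 0:
            raise ValueError(
                f"resolution mismatch: {bin_positions} bin positions "
                f"cannot host 2x{crop_bins} cropped bins")
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.trunk = Trunk(cfg, rng)
        w = cfg.tower_widths
        self.decoder = [
            _DecoderStage(rng, cfg.model_dim, w[cfg.stages - 1 - j],
                          cfg.decoder_kernel)
            for j in range(decoder_stages)]
        self.head = Dense(rng, cfg.model_dim, n_tracks)
        self._rng = np.random.default_rng(cfg.seed + 2)

    @property
    def bin_width(self) -> int:
        return 2 ** (self.config.stages - self.decoder_stages)

    @property
    def crop_bp(self) -> int:
        return self.crop_bins * self.bin_width

    def init_from_lm(self, lm: LanguageModel):
        """Copy all trunk weights (and norm statistics) from a trained LM."""
        src, dst = lm.trunk.params(), self.trunk.params()
        if len(src) != len(dst):
            raise ValueError("trunk configurations are incompatible")
        for s, d in zip(src, dst):
            d.data[...] = s.data
        from .lm_core import _norm_modules
        for s, d in zip(_norm_modules(lm.trunk), _norm_modules(self.trunk)):
            d.run_mean[...] = s.run_mean
            d.run_var[...] = s.run_var
        return self

    def forward(self, x, rng=None) -> Tensor:
        """(B, L, in_channels) -> (B, n_bins, n_tracks), strictly positive."""
        rng = rng if rng is not None else self._rng
        xt = x if isinstance(x, Tensor) else Tensor(x)
        h, skips = self.trunk(xt, rng)
        for j, stage in enumerate(self.decoder):
            h = stage(h, skips[len(skips) - 1 - j], rng)
        if self.crop_bins:
            h = ad.slice_axis1(h, self.crop_bins, h.shape[1] - self.crop_bins)
        return ad.softplus(self.head(h))

    def predict(self, x) -> np.ndarray:
        was_train = self.train_mode
        self.set_train(False)
        out = self.forward(x).data
        self.set_train(was_train)
        return out

    def predict_window(self, seq: str, species: int = 0) -> np.ndarray:
        x = encode_input(mio.seq_to_onehot(seq), species,
                         self.config.n_species)
        return self.predict(x[None])[0]


def build_supervised_model(lm_or_config, n_tracks: int,
                           decoder_stages: int = 3,
                           crop_bins: int = CROP_BINS) -> CoverageModel:
    """Build the coverage model, transfer-initializing when given a trained LM."""
    if isinstance(lm_or_config, LanguageModel):
        model = CoverageModel(lm_or_config.config, n_tracks,
                              decoder_stages, crop_bins)
        model.init_from_lm(lm_or_config)
        return model
    return CoverageModel(lm_or_config, n_tracks, decoder_stages, crop_bins)


# ---------------------------------------------------------------------------
# loss

def poisson_multinomial_loss(pred, obs, mult_scale: float = MULT_SCALE,
                             eps: float = 1e-7) -> float:
    """Total-count Poisson NLL + scaled multinomial allocation NLL.

    With N_hat = sum_i pred_i and N = sum_i obs_i (per window and track):
    Poisson term  N_hat - N ln(N_hat); multinomial term
    -sum_i obs_i ln(pred_i / N_hat); constants independent of the
    prediction (ln N!, the multinomial coefficient) are dropped.  Returns
    the mean over windows and tracks.
    """
    value = float(_pm_loss_tensor(Tensor(np.asarray(pred, dtype=float)),
                                  np.asarray(obs, dtype=float),
                                  mult_scale, eps).data)
    if not np.isfinite(value):
        raise ValueError("non-finite Poisson+multinomial loss")
    return value


def _pm_loss_tensor(pred: Tensor, obs: np.ndarray, mult_scale: float,
                    eps: float = 1e-7) -> Tensor:
    if pred.ndim == 2:
        pred = ad.reshape(pred, (1,) + tuple(pred.shape))
        obs = obs[None]
    pred = ad.add(pred, Tensor(eps))
    log_pred = ad.log(pred)
    total_p = ad.tsum(pred, axis=1)                     # (B, T)
    total_o = obs.sum(axis=1)
    log_total = ad.log(total_p)
    poisson = ad.add(total_p, ad.mul(log_total, Tensor(-total_o)))
    cross = ad.tsum(ad.mul(log_pred, Tensor(obs)), axis=1)
    multinom = ad.add(ad.mul(cross, Tensor(-1.0)),
                      ad.mul(log_total, Tensor(total_o)))
    per = ad.add(poisson, ad.mul(multinom, Tensor(mult_scale)))
    return ad.tmean(per)


# ---------------------------------------------------------------------------
# ensembling

@dataclass
class EnsemblePrediction:
    """Strand/shift ensemble of per-bin predictions."""

    fwd: dict[int, np.ndarray]
    rc: dict[int, np.ndarray]
    ensemble: np.ndarray
    shifts: tuple


def ensemble_predict(model: CoverageModel, seq: str, shifts=(0, 1),
                     rc: bool = True, species: int = 0) -> EnsemblePrediction:
    """Average predictions over input shifts and the reverse complement.

    ``seq`` must be at least L + max(shifts) long; output coordinates stay
    fixed while the input slides.  The reverse-complement prediction is
    computed on the reverse-complemented sequence and un-reversed (bins
    flipped back) before averaging.
    """
    L = model.config.L
    if len(seq) < L + max(shifts):
        raise ValueError("sequence too short for the requested shifts")
    fwd, rcd, parts = {}, {}, []
    for s in shifts:
        sub = seq[s:s + L]
        f = model.predict_window(sub, species)
        fwd[s] = f
        if rc:
            r = model.predict_window(mio.revcomp(sub), species)[::-1]
            rcd[s] = r
            parts.append(0.5 * (f + r))
        else:
            parts.append(f)
    ens = np.mean(parts, axis=0)
    return EnsemblePrediction(fwd=fwd, rc=rcd, ensemble=ens,
                              shifts=tuple(shifts))


# ---------------------------------------------------------------------------
# fine-tuning loop

@dataclass
class FineTuneConfig:
    batch_size: int = 8
    steps_per_epoch: int = 150
    max_epochs: int = 10_000
    patience: int = 150
    lr: float = 2e-5
    beta1: float = 0.7
    beta2: float = 0.9
    clipnorm: float = 0.1
    warmup_steps: int = 20_000
    mult_scale: float = MULT_SCALE
    rc_prob: float = 0.5          # reverse-complement augmentation
    seed: int = 0


RANDOM_INIT_DEFAULTS = dict(lr=1e-4, beta1=0.9, beta2=0.999, warmup_steps=5_000)


def train_supervised(model: CoverageModel, train_windows, train_targets,
                     val_windows=None, val_targets=None,
                     cfg: FineTuneConfig | None = None):
    """Fine-tune on binned coverage with early stopping on validation loss."""
    cfg = cfg or FineTuneConfig()
    rng = np.random.default_rng(cfg.seed)
    drop_rng = np.random.default_rng(cfg.seed + 7)
    opt = Adam(model.params(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2,
               clipnorm=cfg.clipnorm, warmup_steps=cfg.warmup_steps)
    n_sp = model.config.n_species
    inputs = np.stack([encode_input(w.onehot(), w.species, n_sp)
                       for w in train_windows])
    # reverse-complement view: flip positions and base channels, keep the rest
    rc_inputs = inputs.copy()[:, ::-1]
    rc_inputs[:, :, :4] = rc_inputs[:, :, 3::-1]
    if val_windows is not None:
        val_inputs = np.stack([encode_input(w.onehot(), w.species, n_sp)
                               for w in val_windows])
    best, best_val, best_epoch = _snapshot(model), np.inf, -1
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(cfg.max_epochs):
        model.set_train(True)
        losses = []
        for _ in range(cfg.steps_per_epoch):
            idx = rng.integers(0, len(train_windows), size=cfg.batch_size)
            flip = rng.random(cfg.batch_size) < cfg.rc_prob
            xb = np.where(flip[:, None, None], rc_inputs[idx], inputs[idx])
            yb = np.where(flip[:, None, None], train_targets[idx][:, ::-1],
                          train_targets[idx])
            pred = model.forward(xb, drop_rng)
            loss = _pm_loss_tensor(pred, yb, cfg.mult_scale)
            if not np.isfinite(loss.data):
                _restore(model, best)
                return model, history
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        if val_windows is None:
            continue
        val = validate_supervised(model, val_inputs, val_targets,
                                  cfg.mult_scale)
        history["val_loss"].append(val)
        if val < best_val:
            best_val, best_epoch = val, epoch
            best = _snapshot(model)
        if epoch - best_epoch >= cfg.patience:
            break
    if val_windows is not None:
        _restore(model, best)
    return model, history


def validate_supervised(model, val_inputs, val_targets,
                        mult_scale: float = MULT_SCALE,
                        batch_size: int = 8) -> float:
    model.set_train(False)
    losses = []
    for i in range(0, len(val_inputs), batch_size):
        pred = model.forward(val_inputs[i:i + batch_size])
        losses.append(float(_pm_loss_tensor(
            pred, val_targets[i:i + batch_size], mult_scale).data))
    return float(np.mean(losses))
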