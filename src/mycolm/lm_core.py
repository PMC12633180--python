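"""Masked DNA language model: architecture, corruption, loss, training, PPM.

The model is a U-Net-shaped convolutional/transformer network over one-hot
DNA.  An encoder of residual convolution blocks halves the sequence length
per stage while growing channels; a stack of pre-norm transformer blocks
integrates long-range context at the bottleneck; a decoder of
nearest-neighbour upsampling stages with skip connections restores
single-base resolution; a width-1 convolution plus softmax emits a
probability distribution over {A, C, G, T} at every position.

Masked sites are encoded as a zeroed one-hot plus a dedicated mask-indicator
input channel; species conditioning is an appended one-hot.  Training hides
a fixed fraction of positions (80% mask token / 10% random base / 10%
unchanged), applies reverse-complement augmentation, and minimizes a
region-weighted cross-entropy over the masked positions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import io as mio
from .corpus import GenomeWindow
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import (Module, Dense, Conv1D, SeparableConv1D, BatchNorm1D,
                        TransformerBlock)
from .nn.optim import Adam

MASK_RATE = 0.15
BERT_SCHEME = (0.8, 0.1, 0.1)


@dataclass(frozen=True)
class LmConfig:
    """Architecture hyperparameters (defaults mirror the full-scale model)."""

    L: int = 16_384
    conv_kernel: int = 11
    tower_widths: tuple = (96, 128, 160, 192, 256, 320, 384)
    tower_kernel: int = 5
    n_transformer_blocks: int = 8
    n_heads: int = 8
    key_dim: int = 64
    ffn_mult: int = 2
    dropout_conv: float = 0.05
    dropout_attn: float = 0.05
    decoder_kernel: int = 3
    n_species: int = 1
    seed: int = 0

    @property
    def stages(self) -> int:
        return len(self.tower_widths)

    @property
    def model_dim(self) -> int:
        return self.tower_widths[-1]

    @property
    def in_channels(self) -> int:
        return 4 + self.n_species + 1          # one-hot + species + mask flag

    @property
    def ffn_inner(self) -> int:
        return self.ffn_mult * self.model_dim

    def validate(self):
        if self.L % (2 ** self.stages) != 0:
            raise ValueError(
                f"window length {self.L} not divisible by 2^{self.stages}")
        return self


class _ResidualConvBlock(Module):
    """BatchNorm -> GELU -> Conv1D -> dropout -> learned residual scale -> add.

    When the channel count grows across the block, the skip path uses a
    pointwise projection so the residual addition is well defined.
    """

    def __init__(self, rng, c_in, c_out, kernel, dropout):
        self.bn = BatchNorm1D(c_in)
        self.conv = Conv1D(rng, c_in, c_out, kernel)
        self.scale = Tensor(np.full(c_out, 0.1), requires_grad=True)
        self.proj = Dense(rng, c_in, c_out) if c_in != c_out else None
        self.dropout = dropout

    def __call__(self, x, rng):
        h = self.conv(ad.gelu(self.bn(x)))
        h = ad.dropout(h, self.dropout, rng, self.train_mode)
        h = ad.mul(h, self.scale)
        skip = self.proj(x) if self.proj is not None else x
        return ad.add(skip, h)


class Trunk(Module):
    """Initial conv + encoder tower + transformer bottleneck."""

    def __init__(self, config: LmConfig, rng):
        cfg = config.validate()
        w = cfg.tower_widths
        self.stem = Conv1D(rng, cfg.in_channels, w[0], cfg.conv_kernel)
        self.blocks = [
            _ResidualConvBlock(rng, w[max(i - 1, 0)], w[i], cfg.tower_kernel,
                               cfg.dropout_conv)
            for i in range(cfg.stages)]
        self.transformer = [
            TransformerBlock(rng, cfg.model_dim, cfg.n_heads, cfg.key_dim,
                             cfg.ffn_inner, cfg.dropout_attn)
            for _ in range(cfg.n_transformer_blocks)]

    def __call__(self, x: Tensor, rng):
        h = self.stem(x)
        skips = []
        for block in self.blocks:
            h = block(h, rng)
            skips.append(h)                     # pre-pool, resolution L / 2^i
            h = ad.maxpool2(h)
        for tb in self.transformer:
            h = tb(h, rng)
        return h, skips


class _DecoderStage(Module):
    """BN -> GELU -> Dense -> upsample x2 -> +skip -> separable conv -> BN -> GELU."""

    def __init__(self, rng, dim, skip_channels, kernel):
        self.bn1 = BatchNorm1D(dim)
        self.proj = Dense(rng, dim, dim)
        self.skip_proj = Dense(rng, skip_channels, dim)
        self.sep = SeparableConv1D(rng, dim, kernel)
        self.bn2 = BatchNorm1D(dim)

    def __call__(self, x, skip, rng):
        h = self.proj(ad.gelu(self.bn1(x)))
        h = ad.upsample2(h)
        h = ad.add(h, self.skip_proj(skip))
        h = self.sep(h)
        return ad.gelu(self.bn2(h))


class LanguageModel(Module):
    """Full masked LM: trunk + complete decoder + per-base softmax head."""

    def __init__(self, config: LmConfig, rng=None):
        cfg = config.validate()
        self.config = cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.trunk = Trunk(cfg, rng)
        w = cfg.tower_widths
        self.decoder = [
            _DecoderStage(rng, cfg.model_dim, w[cfg.stages - 1 - j],
                          cfg.decoder_kernel)
            for j in range(cfg.stages)]
        self.head = Conv1D(rng, cfg.model_dim, 4, 1)
        self._rng = np.random.default_rng(cfg.seed + 1)

    def forward(self, x, rng=None) -> Tensor:
        """(B, L, in_channels) -> (B, L, 4) row-stochastic probabilities."""
        rng = rng if rng is not None else self._rng
        xt = x if isinstance(x, Tensor) else Tensor(x)
        h, skips = self.trunk(xt, rng)
        for j, stage in enumerate(self.decoder):
            h = stage(h, skips[len(skips) - 1 - j], rng)
        return ad.softmax(self.head(h), axis=-1)

    def predict(self, x) -> np.ndarray:
        was_train = self.train_mode
        self.set_train(False)
        out = self.forward(x).data
        self.set_train(was_train)
        return out


def build_lm(config: LmConfig) -> LanguageModel:
    """Construct a freshly initialized masked LM from its configuration."""
    return LanguageModel(config)


# ---------------------------------------------------------------------------
# input encoding and corruption

def encode_input(onehot: np.ndarray, species: int, n_species: int,
                 mask_flag: np.ndarray | None = None) -> np.ndarray:
    """Append species one-hot and mask-indicator channels to a (L, 4) one-hot."""
    L = onehot.shape[0]
    sp = np.zeros((L, n_species))
    sp[:, species % n_species] = 1.0
    flag = np.zeros((L, 1)) if mask_flag is None else mask_flag.reshape(L, 1)
    return np.concatenate([onehot, sp, flag], axis=1)


@dataclass
class MaskedBatch:
    """Corrupted inputs with targets and bookkeeping for the masked loss."""

    inputs: np.ndarray            # (B, L, in_channels)
    targets: np.ndarray           # (B, L, 4) original one-hot
    mask_positions: np.ndarray    # (B, L) bool, the selected sites
    corruption: np.ndarray        # (B, L) int8: 0 none, 1 masked, 2 random, 3 kept
    loss_weights: np.ndarray      # (B, L)
    rc_applied: np.ndarray        # (B,) bool


def corrupt_batch(windows, rate: float = MASK_RATE, scheme=BERT_SCHEME,
                  rc_prob: float = 0.5, seed: int = 0,
                  n_species: int = 1) -> MaskedBatch:
    """Apply BERT-style corruption with reverse-complement augmentation.

    Selects exactly ``floor(rate * L)`` positions per window uniformly
    without replacement; each selected site is independently masked,
    substituted by a random base, or left unchanged per ``scheme``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if abs(sum(scheme) - 1.0) > 1e-9:
        raise ValueError("scheme probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    inputs, targets, masks, cats, weights, rcs = [], [], [], [], [], []
    for w in windows:
        seq, lw = w.seq, w.loss_weights
        rc = rng.random() < rc_prob
        if rc:
            seq, lw = mio.revcomp(seq), lw[::-1]
        onehot = mio.seq_to_onehot(seq)
        L = len(seq)
        m = int(math.floor(rate * L))
        sel = rng.choice(L, size=m, replace=False)
        cat = np.zeros(L, dtype=np.int8)
        if m:
            cat[sel] = rng.choice([1, 2, 3], size=m, p=list(scheme))
        corrupted = onehot.copy()
        flag = np.zeros(L)
        masked_at = cat == 1
        corrupted[masked_at] = 0.0
        flag[masked_at] = 1.0
        rand_at = np.flatnonzero(cat == 2)
        if rand_at.size:
            corrupted[rand_at] = np.eye(4)[rng.integers(0, 4, size=rand_at.size)]
        inputs.append(encode_input(corrupted, w.species, n_species, flag))
        targets.append(onehot)
        masks.append(cat > 0)
        cats.append(cat)
        weights.append(lw.copy())
        rcs.append(rc)
    return MaskedBatch(inputs=np.stack(inputs), targets=np.stack(targets),
                       mask_positions=np.stack(masks), corruption=np.stack(cats),
                       loss_weights=np.stack(weights),
                       rc_applied=np.array(rcs))


# ---------------------------------------------------------------------------
# loss

@dataclass
class CeLoss:
    """Region-weighted cross entropy: per-window, global, and perplexity."""

    per_window: np.ndarray
    loss: float
    perplexity_: float = field(init=False)

    def __post_init__(self):
        self.perplexity_ = float(np.exp(self.loss))


def weighted_cross_entropy(pred, targets, loss_weights,
                           mask_positions=None, scope: str = "all") -> CeLoss:
    """Weighted per-position cross entropy (natural log).

    Per window: sum_j ce_j * w_j / sum_j w_j, with the sum over
    ``mask_positions`` when ``scope='masked'`` (training convention) and
    over all positions when ``scope='all'`` (evaluation convention).
    """
    pred = np.asarray(pred, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if pred.ndim == 2:
        pred, targets = pred[None], targets[None]
    if mask_positions is not None:
        mask_positions = np.asarray(mask_positions)
        if mask_positions.ndim == 1:
            mask_positions = mask_positions[None]
    loss_weights = np.asarray(loss_weights, dtype=float)
    if loss_weights.ndim == 1:
        loss_weights = loss_weights[None]
    if np.any(loss_weights < 0):
        raise ValueError("loss weights must be nonnegative")
    ce = -(targets * np.log(np.clip(pred, 1e-300, None))).sum(axis=-1)
    w = loss_weights.copy()
    if scope == "masked":
        if mask_positions is None:
            raise ValueError("scope='masked' requires mask_positions")
        w = w * np.asarray(mask_positions, dtype=float)
    denom = w.sum(axis=-1)
    if np.any(denom <= 0):
        raise ValueError("all-zero loss weights over the scored positions")
    per_window = (ce * w).sum(axis=-1) / denom
    return CeLoss(per_window=per_window, loss=float(per_window.mean()))


def perplexity(loss: CeLoss | float) -> float:
    """exp of the global cross-entropy loss."""
    value = loss.loss if isinstance(loss, CeLoss) else float(loss)
    if not np.isfinite(value):
        raise ValueError("loss must be finite")
    return float(np.exp(value))


def _ce_loss_tensor(probs: Tensor, batch: MaskedBatch, scope: str) -> Tensor:
    """Autodiff version of the weighted CE used inside the training loop."""
    ce = ad.mul(ad.tsum(ad.mul(Tensor(batch.targets),
                               ad.log(probs)), axis=2), Tensor(-1.0))
    w = batch.loss_weights.astype(float)
    if scope == "masked":
        w = w * batch.mask_positions
    denom = w.sum(axis=1)
    if np.any(denom <= 0):
        raise ValueError("all-zero loss weights over the scored positions")
    num = ad.tsum(ad.mul(ce, Tensor(w)), axis=1)
    return ad.tmean(ad.mul(num, Tensor(1.0 / denom)))


# ---------------------------------------------------------------------------
# training loop

@dataclass
class TrainConfig:
    batch_size: int = 8
    steps_per_epoch: int = 150
    max_epochs: int = 10_000
    min_epochs: int = 0
    patience: int = 1_000
    lr: float = 1e-4
    beta1: float = 0.7
    beta2: float = 0.9
    clipnorm: float = 0.1
    warmup_steps: int = 20_000
    repeat_eval: int = 5
    rate: float = MASK_RATE
    scheme: tuple = BERT_SCHEME
    rc_prob: float = 0.5
    loss_scope: str = "masked"
    seed: int = 0


@dataclass
class TrainResult:
    model: "LanguageModel"
    history: dict
    best_val_loss: float
    stopped_epoch: int


def _snapshot(model):
    """Copy trainable parameters and normalization running statistics."""
    return ([p.data.copy() for p in model.params()],
            [(bn.run_mean.copy(), bn.run_var.copy())
             for bn in _norm_modules(model)])


def _restore(model, snap):
    params, stats = snap
    for p, saved in zip(model.params(), params):
        p.data[...] = saved
    for bn, (m, v) in zip(_norm_modules(model), stats):
        bn.run_mean[...] = m
        bn.run_var[...] = v


def train_lm(model: LanguageModel, train_windows, val_windows,
             cfg: TrainConfig | None = None) -> TrainResult:
    """Masked-LM training with early stopping on repeat-averaged validation loss.

    Validation loss is the mean over ``repeat_eval`` independent
    mask-and-predict corruption draws.  The best-validation checkpoint is
    restored into ``model`` before returning; a non-finite training loss
    aborts and restores the last good checkpoint.
    """
    cfg = cfg or TrainConfig()
    if not train_windows or not val_windows:
        raise ValueError("need at least one training and one validation window")
    rng = np.random.default_rng(cfg.seed)
    drop_rng = np.random.default_rng(cfg.seed + 7)
    opt = Adam(model.params(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2,
               clipnorm=cfg.clipnorm, warmup_steps=cfg.warmup_steps)
    n_sp = model.config.n_species
    best = _snapshot(model)
    best_val, best_epoch = np.inf, -1
    history = {"train_loss": [], "val_loss": []}

    for epoch in range(cfg.max_epochs):
        model.set_train(True)
        epoch_losses = []
        for _ in range(cfg.steps_per_epoch):
            idx = rng.integers(0, len(train_windows), size=cfg.batch_size)
            batch = corrupt_batch([train_windows[i] for i in idx],
                                  rate=cfg.rate, scheme=cfg.scheme,
                                  rc_prob=cfg.rc_prob,
                                  seed=int(rng.integers(2 ** 31)),
                                  n_species=n_sp)
            probs = model.forward(batch.inputs, drop_rng)
            loss = _ce_loss_tensor(probs, batch, cfg.loss_scope)
            if not np.isfinite(loss.data):
                _restore(model, best)
                return TrainResult(model, history, float(best_val), epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(epoch_losses)))

        val = validate_lm(model, val_windows, repeat_eval=cfg.repeat_eval,
                          rate=cfg.rate, scheme=cfg.scheme,
                          seed=cfg.seed + 1000 + epoch,
                          scope=cfg.loss_scope)
        history["val_loss"].append(val)
        if val < best_val:
            best_val, best_epoch = val, epoch
            best = _snapshot(model)
        if epoch >= cfg.min_epochs and epoch - best_epoch >= cfg.patience:
            break
    _restore(model, best)
    return TrainResult(model, history, float(best_val), len(history["val_loss"]))


def validate_lm(model, windows, repeat_eval: int = 5, rate: float = MASK_RATE,
                scheme=BERT_SCHEME, seed: int = 0, scope: str = "masked",
                batch_size: int = 8) -> float:
    """Mean weighted CE over ``repeat_eval`` independent corruption draws."""
    model.set_train(False)
    losses = []
    for r in range(repeat_eval):
        for i in range(0, len(windows), batch_size):
            chunk = windows[i:i + batch_size]
            batch = corrupt_batch(chunk, rate=rate, scheme=scheme, rc_prob=0.0,
                                  seed=seed * repeat_eval + r,
                                  n_species=model.config.n_species)
            probs = model.predict(batch.inputs)
            ce = weighted_cross_entropy(probs, batch.targets,
                                        batch.loss_weights,
                                        batch.mask_positions, scope=scope)
            losses.append(ce.loss)
    return float(np.mean(losses))


# ---------------------------------------------------------------------------
# mask -> predict -> tile

@dataclass
class PpmResult:
    """Per-position base-probability matrix from mask -> predict -> tile."""

    ppm: np.ndarray          # (L, 4), rows on the simplex
    x_true: np.ndarray       # (L, 4) one-hot truth
    window_id: str
    species: int
    loss_weights: np.ndarray | None = None

    def save_npz(self, path):
        np.savez_compressed(path, x_pred=self.ppm, x_true=self.x_true,
                            window_id=self.window_id, species=self.species,
                            weights=self.loss_weights
                            if self.loss_weights is not None else np.nan)

    @classmethod
    def load_npz(cls, path):
        with np.load(path, allow_pickle=False) as z:
            return cls(ppm=z["x_pred"], x_true=z["x_true"],
                       window_id=str(z["window_id"]), species=int(z["species"]),
                       loss_weights=None)


def mask_predict_tile(model: LanguageModel, window: GenomeWindow,
                      rate: float = MASK_RATE, rc_average: bool = True,
                      seed: int = 0,
                      partition: np.ndarray | None = None) -> PpmResult:
    """Reconstruct a PPM by masking disjoint position sets round by round.

    Positions are partitioned into ``ceil(1/rate)`` rounds; each round masks
    its positions with the mask token, predicts, and records the predicted
    distribution at exactly those positions.  With ``rc_average`` the same is
    done on the reverse complement (with the mirrored partition) and the
    complemented, reversed predictions are averaged in.
    """
    L = window.length
    n_rounds = int(math.ceil(1.0 / rate))
    if partition is None:
        rng = np.random.default_rng(seed)
        partition = np.empty(L, dtype=int)
        partition[rng.permutation(L)] = np.arange(L) % n_rounds
    n_rounds = int(partition.max()) + 1
    onehot = mio.seq_to_onehot(window.seq)
    n_sp = model.config.n_species

    ppm = _tile_pass(model, onehot, partition, n_rounds, window.species, n_sp)
    if rc_average:
        rc_onehot = mio.seq_to_onehot(mio.revcomp(window.seq))
        rc_part = partition[::-1]
        rc_ppm = _tile_pass(model, rc_onehot, rc_part, n_rounds,
                            window.species, n_sp)
        ppm = 0.5 * (ppm + rc_ppm[::-1, ::-1])
    return PpmResult(ppm=ppm, x_true=onehot, window_id=window.window_id,
                     species=window.species, loss_weights=window.loss_weights)


def _tile_pass(model, onehot, partition, n_rounds, species, n_species):
    L = onehot.shape[0]
    inputs = []
    for r in range(n_rounds):
        sel = partition == r
        corrupted = onehot.copy()
        corrupted[sel] = 0.0
        inputs.append(encode_input(corrupted, species, n_species,
                                   sel.astype(float)))
    probs = model.predict(np.stack(inputs))
    ppm = np.empty((L, 4))
    for r in range(n_rounds):
        sel = partition == r
        ppm[sel] = probs[r][sel]
    return ppm


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model, path):
    """Self-describing checkpoint: config JSON + parameters + norm stats."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params())}
    stats = _norm_stats(model)
    for i, (m, v) in enumerate(stats):
        arrays[f"bn_mean{i}"], arrays[f"bn_var{i}"] = m, v
    arrays["config_json"] = np.array(json.dumps(asdict(model.config)))
    arrays["n_norm"] = np.array(len(stats))
    np.savez_compressed(path, **arrays)


def load_checkpoint(path, model_cls=None):
    model_cls = model_cls or LanguageModel
    with np.load(path, allow_pickle=False) as z:
        cfg_dict = json.loads(str(z["config_json"]))
        cfg_dict["tower_widths"] = tuple(cfg_dict["tower_widths"])
        model = model_cls(LmConfig(**cfg_dict))
        for i, p in enumerate(model.params()):
            p.data[...] = z[f"p{i}"]
        for i, bn in enumerate(_norm_modules(model)):
            bn.run_mean[...] = z[f"bn_mean{i}"]
            bn.run_var[...] = z[f"bn_var{i}"]
    return model


def _norm_modules(module, acc=None):
    from .nn.layers import _collect_modules
    acc = []

    def walk(m):
        if isinstance(m, BatchNorm1D):
            acc.append(m)
        for attr in vars(m).values():
            for sub in _collect_modules(attr):
                walk(sub)

    walk(module)
    return acc


def _norm_stats(model):
    return [(bn.run_mean.copy(), bn.run_var.copy())
            for bn in _norm_modules(model)]
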