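"""Masked LM: architecture contract, corruption scheme, losses, tiling."""

import math

import numpy as np
import pytest

from mycolm import io as mio, lm_core
from mycolm.corpus import GenomeWindow
from mycolm.lm_core import (CeLoss, LmConfig, TrainConfig, build_lm,
                            corrupt_batch, mask_predict_tile, perplexity,
                            weighted_cross_entropy)

TINY = LmConfig(L=256, tower_widths=(8, 12), n_transformer_blocks=1,
                n_heads=2, key_dim=4, seed=0)


def _win(seq, species=0):
    return GenomeWindow(species, "chr1", 0, len(seq), seq)


@pytest.fixture(scope="module")
def tiny_model():
    return build_lm(TINY)


class TestArchitecture:
    def test_output_rows_on_probability_simplex(self, tiny_model, rng):
        x = rng.random((2, 256, TINY.in_channels))
        probs = tiny_model.predict(x)
        assert probs.shape == (2, 256, 4)
        np.testing.assert_allclose(probs.sum(-1), 1.0, atol=1e-5)

    def test_indivisible_window_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_lm(LmConfig(L=1_000, tower_widths=(8, 12, 16, 24)))

    def test_parameter_count_grows_with_ffn_width(self):
        import dataclasses
        small = build_lm(TINY).n_params()
        big = build_lm(dataclasses.replace(TINY, ffn_mult=4)).n_params()
        assert big > small

    def test_checkpoint_round_trip(self, tiny_model, tmp_path, rng):
        path = tmp_path / "lm.npz"
        lm_core.save_checkpoint(tiny_model, path)
        back = lm_core.load_checkpoint(path)
        x = rng.random((1, 256, TINY.in_channels))
        np.testing.assert_allclose(tiny_model.predict(x), back.predict(x),
                                   atol=1e-6)


class TestCorruption:
    def test_masked_position_count_is_floor_of_rate(self):
        w = _win("ACGT" * 4_096)                     # L = 16,384
        batch = corrupt_batch([w], rate=0.15, rc_prob=0.0, seed=0)
        assert batch.mask_positions[0].sum() == 2_457
        assert 2_457 == math.floor(0.15 * 16_384)

    def test_zero_rate_leaves_input_unchanged(self):
        w = _win("ACGTACGTACGTACGT")
        batch = corrupt_batch([w], rate=0.0, rc_prob=0.0, seed=0)
        np.testing.assert_array_equal(batch.inputs[0, :, :4], batch.targets[0])
        assert batch.mask_positions.sum() == 0

    def test_corruption_categories_match_scheme_frequencies(self):
        w = _win("ACGT" * 1_024)
        counts = np.zeros(4)
        for seed in range(20):
            batch = corrupt_batch([w], rate=0.15, rc_prob=0.0, seed=seed)
            counts += np.bincount(batch.corruption[0], minlength=4)
        selected = counts[1:].sum()
        frac_masked = counts[1] / selected
        assert abs(frac_masked - 0.80) < 0.01
        assert abs(counts[2] / selected - 0.10) < 0.01

    def test_reverse_complement_flips_sequence_and_weights(self):
        seq = "A" * 10 + "C" * 6
        w = GenomeWindow(0, "c", 0, 16, seq,
                         loss_weights=np.r_[np.ones(10), np.full(6, 0.1)])
        batch = corrupt_batch([w], rate=0.0, rc_prob=1.0, seed=0)
        assert batch.rc_applied[0]
        np.testing.assert_array_equal(
            batch.targets[0], mio.seq_to_onehot(mio.revcomp(seq)))
        np.testing.assert_allclose(batch.loss_weights[0][:6], 0.1)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            corrupt_batch([_win("ACGT")], rate=1.5)


class TestWeightedCrossEntropy:
    def test_uniform_predictor_gives_ln4(self):
        pred = np.full((8, 4), 0.25)
        tgt = np.eye(4)[[0, 1, 2, 3, 0, 1, 2, 3]]
        ce = weighted_cross_entropy(pred, tgt, np.ones(8))
        assert ce.loss == pytest.approx(math.log(4.0), abs=1e-12)
        assert perplexity(ce) == pytest.approx(4.0)

    def test_perfect_predictor_gives_zero(self):
        tgt = np.eye(4)[[0, 3, 2]]
        ce = weighted_cross_entropy(tgt, tgt, np.ones(3))
        assert ce.loss == pytest.approx(0.0, abs=1e-9)
        assert perplexity(ce) == pytest.approx(1.0)

    def test_two_position_hand_arithmetic(self):
        # p_true = (0.5, 0.25), weights (1, 0.1):
        # (ln 2 + 0.1 ln 4) / 1.1 = 0.756146...
        pred = np.array([[0.5, 0.5, 0.0, 0.0], [0.25] * 4])
        tgt = np.eye(4)[[0, 1]]
        ce = weighted_cross_entropy(pred, tgt, np.array([1.0, 0.1]))
        expected = (math.log(2) + 0.1 * math.log(4)) / 1.1
        assert ce.loss == pytest.approx(expected, abs=1e-12)
        assert perplexity(ce) == pytest.approx(math.exp(expected), rel=1e-9)

    def test_weight_scale_invariance(self, rng):
        pred = rng.dirichlet(np.ones(4), size=16)
        tgt = np.eye(4)[rng.integers(0, 4, 16)]
        w = rng.random(16) + 0.1
        a = weighted_cross_entropy(pred, tgt, w).loss
        b = weighted_cross_entropy(pred, tgt, 2.0 * w).loss
        assert a == pytest.approx(b, rel=1e-12)

    def test_masked_scope_restricts_to_selected_positions(self):
        pred = np.stack([np.full(4, 0.25), np.eye(4)[0]])
        tgt = np.eye(4)[[0, 0]]
        mask = np.array([True, False])
        ce = weighted_cross_entropy(pred, tgt, np.ones(2), mask, scope="masked")
        assert ce.loss == pytest.approx(math.log(4.0))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.full((2, 4), 0.25), np.eye(4)[:2],
                                   np.zeros(2))


class _UniformModel:
    """Predicts 0.25 everywhere; enough surface for mask_predict_tile."""

    config = TINY

    def predict(self, x):
        return np.full((x.shape[0], x.shape[1], 4), 0.25)


class TestMaskPredictTile:
    def test_partition_covers_every_position_once(self):
        L = 256
        rate = 0.15
        rng = np.random.default_rng(3)
        n_rounds = math.ceil(1 / rate)
        partition = np.empty(L, dtype=int)
        partition[rng.permutation(L)] = np.arange(L) % n_rounds
        seen = np.zeros(L, dtype=int)
        for r in range(n_rounds):
            seen[partition == r] += 1
        assert np.all(seen == 1)

    def test_uniform_model_gives_uniform_ppm(self):
        w = _win("ACGT" * 64)
        res = mask_predict_tile(_UniformModel(), w, seed=0)
        np.testing.assert_allclose(res.ppm, 0.25)

    def test_rc_equivariance_with_mirrored_partition(self, tiny_model):
        seq = "".join(np.random.default_rng(5).choice(list("ACGT"), 256))
        w = _win(seq)
        w_rc = _win(mio.revcomp(seq))
        rng = np.random.default_rng(9)
        part = np.empty(256, dtype=int)
        part[rng.permutation(256)] = np.arange(256) % 7
        fwd = mask_predict_tile(tiny_model, w, rc_average=True, partition=part)
        rev = mask_predict_tile(tiny_model, w_rc, rc_average=True,
                                partition=part[::-1])
        np.testing.assert_allclose(rev.ppm, fwd.ppm[::-1, ::-1], atol=1e-6)

    def test_ppm_rows_sum_to_one(self, tiny_model):
        w = _win("ACGT" * 64)
        res = mask_predict_tile(tiny_model, w, seed=1)
        np.testing.assert_allclose(res.ppm.sum(1), 1.0, atol=1e-5)

    def test_npz_round_trip(self, tiny_model, tmp_path):
        w = _win("ACGT" * 64)
        res = mask_predict_tile(tiny_model, w, seed=1)
        res.save_npz(tmp_path / "ppm.npz")
        back = lm_core.PpmResult.load_npz(tmp_path / "ppm.npz")
        np.testing.assert_allclose(back.ppm, res.ppm)


class TestTrainingLoop:
    def _windows(self, n=4, L=256, seed=0):
        rng = np.random.default_rng(seed)
        return [_win("".join(rng.choice(list("ACGT"), L))) for _ in range(n)]

    def test_zero_epochs_returns_initial_weights(self):
        model = build_lm(TINY)
        before = [p.data.copy() for p in model.params()]
        cfg = TrainConfig(batch_size=2, steps_per_epoch=2, max_epochs=0,
                          patience=1, seed=0)
        lm_core.train_lm(model, self._windows(), self._windows(2, seed=1), cfg)
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_overfitting_beats_uniform_baseline(self):
        model = build_lm(TINY)
        wins = self._windows(2)
        cfg = TrainConfig(batch_size=2, steps_per_epoch=60, max_epochs=2,
                          patience=2, lr=3e-3, clipnorm=5.0, warmup_steps=5,
                          repeat_eval=1, rc_prob=0.0, seed=0)
        res = lm_core.train_lm(model, wins, wins, cfg)
        assert res.history["train_loss"][-1] < math.log(4.0)

    def test_early_stopping_waits_exactly_patience_epochs(self, monkeypatch):
        model = build_lm(TINY)
        vals = iter([1.0, 1.1, 1.2, 1.3, 1.4, 1.5])
        monkeypatch.setattr(lm_core, "validate_lm",
                            lambda *a, **k: next(vals))
        cfg = TrainConfig(batch_size=2, steps_per_epoch=1, max_epochs=50,
                          patience=2, seed=0)
        res = lm_core.train_lm(model, self._windows(2), self._windows(2), cfg)
        assert len(res.history["val_loss"]) == 3      # best + 2 worse epochs
        assert res.best_val_loss == pytest.approx(1.0)
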