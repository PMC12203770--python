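"""Tests of the network decoders: training, rescaling, ReFIT, resampling."""

import numpy as np
import pytest

from nldbench import metrics
from nldbench.decoders import (
    LSTMConfig,
    TCNConfig,
    TrainConfig,
    build_sequences,
    build_tcn,
    fit_output_rescaler,
    redistribute_velocities,
    refit_finetune,
    refit_relabel,
    train_lstm,
    train_network,
    train_tcn,
    variant_config,
)
from nldbench.linear import fit_ridge
from nldbench.pipeline import _dataset
from nldbench.prep import make_folds, trim_and_holdout
from nldbench.synthetic import TaskConfig, generate_encoding_model, generate_session

SMALL_TCN = TCNConfig(n_channels=24, n_filters=4, hidden=(32,))


def _small_data(session, n_train_trials=50):
    idx = np.arange(session.trials.n_trials)
    train, test = idx[:n_train_trials], idx[n_train_trials:]
    Xtr, Ytr, btr, str_ = _dataset(session, train)
    Xte, Yte, bte, ste = _dataset(session, test)
    return (Xtr, Ytr, btr, str_), (Xte, Yte, bte, ste)


class TestTrainNetwork:
    def test_constant_zero_targets_learned(self, small_session):
        (Xtr, Ytr, _, _), _ = _small_data(small_session)
        zeros = np.zeros_like(Ytr)
        net = build_tcn(SMALL_TCN, seed=0)
        dec = train_network(net, Xtr, zeros,
                           TrainConfig(epochs=2, seed=0))
        pred = dec.predict(Xtr)
        assert np.abs(pred).mean() < 0.01 * max(np.abs(Ytr).max(), 1.0)

    def test_full_determinism(self, small_session):
        (Xtr, Ytr, _, _), (Xte, _, _, _) = _small_data(small_session)
        preds = []
        for _ in range(2):
            net = build_tcn(SMALL_TCN, seed=3)
            dec = train_network(net, Xtr, Ytr, TrainConfig(epochs=2, seed=3))
            preds.append(dec.predict(Xte))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_loss_trace_one_value_per_epoch(self, small_session):
        (Xtr, Ytr, _, _), _ = _small_data(small_session)
        net = build_tcn(SMALL_TCN, seed=0)
        dec = train_network(net, Xtr, Ytr, TrainConfig(epochs=4, seed=0))
        assert len(dec.loss_trace) == 4
        assert dec.loss_trace[-1] < dec.loss_trace[0]

    def test_iteration_budget_mode(self, small_session):
        (Xtr, Ytr, _, _), _ = _small_data(small_session)
        net = build_tcn(SMALL_TCN, seed=0)
        dec = train_network(net, Xtr, Ytr,
                           TrainConfig(epochs=None, iterations=37, seed=0))
        assert dec.iterations == 37

    def test_affine_encoding_tcn_near_ridge(self):
        """On affine (linear-link) encoding the closed-form ridge fit is the
        right model class, and the TCN should land close to it rather than
        beating it or falling far behind."""
        model = generate_encoding_model(24, "linear", seed=7, noise_scale=0.6)
        session = generate_session(TaskConfig(n_trials=600, seed=13),
                                   encoding_model=model)
        kept, hold = trim_and_holdout(session.trials)
        train = make_folds(kept, seed=0).folds[0]["train"]
        Xtr, Ytr, _, _ = _dataset(session, train)
        Xte, Yte, _, _ = _dataset(session, hold)
        ridge_mse = metrics.mse(fit_ridge(Xtr, Ytr).predict(Xte), Yte)
        dec = train_tcn(Xtr, Ytr, config=TCNConfig(n_channels=24),
                        train_config=TrainConfig(epochs=10, seed=0), seed=0)
        tcn_mse = metrics.mse(dec.predict(Xte), Yte)
        assert tcn_mse < 1.1 * ridge_mse

    def test_variant_epochs_budgets(self):
        from nldbench.decoders import VARIANT_EPOCHS

        assert VARIANT_EPOCHS["tcn"] == 10
        assert VARIANT_EPOCHS["nobndp"] == 80
        cfg = variant_config(TCNConfig(), "nobndp")
        assert not cfg.use_batchnorm and not cfg.use_dropout


class TestOutputRescaler:
    def test_identity_when_already_scaled(self, rng):
        y = rng.normal(0, 2, (100, 2))
        r = fit_output_rescaler(y, y)
        np.testing.assert_allclose(r.weight, 1.0, atol=1e-9)
        np.testing.assert_allclose(r.bias, 0.0, atol=1e-9)

    def test_recovers_zscore_transform(self, rng):
        y = rng.normal(3.0, 2.5, (200, 2))
        z = (y - y.mean(axis=0)) / y.std(axis=0)
        r = fit_output_rescaler(z, y)
        np.testing.assert_allclose(r.weight, y.std(axis=0), atol=1e-8)
        np.testing.assert_allclose(r.bias, y.mean(axis=0), atol=1e-8)

    def test_dofs_independent(self, rng):
        p = rng.normal(0, 1, (100, 2))
        y = rng.normal(0, 1, (100, 2))
        r_full = fit_output_rescaler(p, y)
        shuffled = p.copy()
        shuffled[:, 1] = rng.permutation(shuffled[:, 1])
        r_shuf = fit_output_rescaler(shuffled, y)
        assert np.isclose(r_full.weight[0], r_shuf.weight[0])
        assert np.isclose(r_full.bias[0], r_shuf.bias[0])

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            fit_output_rescaler(np.ones((10, 2)), np.random.randn(10, 2))


class TestLSTM:
    def test_sequences_stay_within_trials(self):
        bins = np.array([10, 12, 30])
        starts = np.array([8, 8, 28])
        idx = build_sequences(np.zeros((40, 3)), bins, starts, seq_len=5)
        np.testing.assert_array_equal(idx[0], [8, 8, 8, 9, 10])
        np.testing.assert_array_equal(idx[2], [28, 28, 28, 29, 30])

    def test_constant_targets_with_no_noise(self, small_session):
        (Xtr, Ytr, btr, str_), _ = _small_data(small_session, 40)
        cfg = LSTMConfig(n_channels=24, hidden_size=16, epochs=8, seed=0,
                         bias_noise_sd=0.0, white_noise_sd=0.0, batch_size=64)
        dec = train_lstm(small_session.sbp, btr, np.zeros_like(Ytr), str_, cfg)
        pred = dec.predict_bins(small_session.sbp, btr, str_)
        assert np.abs(pred).mean() < 0.05

    def test_learns_velocity_structure(self, small_session):
        (Xtr, Ytr, btr, str_), (Xte, Yte, bte, ste) = _small_data(small_session, 60)
        cfg = LSTMConfig(n_channels=24, hidden_size=32, epochs=10, seed=0,
                         batch_size=64)
        dec = train_lstm(small_session.sbp, btr, Ytr, str_, cfg)
        pred = dec.predict_bins(small_session.sbp, bte, ste)
        null = np.tile(Yte.mean(axis=0), (len(Yte), 1))
        assert metrics.mse(pred, Yte) < metrics.mse(null, Yte)
        assert dec.loss_trace[-1] < dec.loss_trace[0]


class TestRefit:
    def test_relabel_rules(self):
        pred = np.array([[0.3, -0.3], [-0.3, 0.2], [0.1, -0.1]])
        pos = np.array([[0.2, 0.2], [0.2, 0.9], [0.5, 0.5]])
        centers = np.array([[0.5, 0.5], [0.5, 0.5], [0.5, 0.5]])
        out = refit_relabel(pred, pos, centers, 0.15)
        # toward target, outside -> unchanged; away -> flipped
        assert out[0, 0] == 0.3  # toward (below target, moving up)
        assert out[0, 1] == 0.3  # was away (below target, moving down) -> flip
        assert out[1, 0] == 0.3  # flip
        assert out[1, 1] == -0.2  # above target moving up -> flip
        # inside target -> zero
        np.testing.assert_array_equal(out[2], [0.0, 0.0])

    def test_finetune_zero_iterations_is_identity(self, small_session):
        (Xtr, Ytr, _, _), _ = _small_data(small_session)
        base = train_tcn(Xtr, Ytr, config=SMALL_TCN,
                         train_config=TrainConfig(epochs=1, seed=0), seed=0)
        tuned = refit_finetune(base, Xtr, Ytr, iterations=0)
        np.testing.assert_array_equal(base.predict(Xtr), tuned.predict(Xtr))

    def test_finetune_iteration_count_and_base_untouched(self, small_session):
        (Xtr, Ytr, _, _), _ = _small_data(small_session)
        base = train_tcn(Xtr, Ytr, config=SMALL_TCN,
                         train_config=TrainConfig(epochs=1, seed=0), seed=0)
        before = base.predict(Xtr)
        tuned = refit_finetune(base, Xtr, Ytr, iterations=500)
        assert tuned.iterations == 500
        np.testing.assert_array_equal(base.predict(Xtr), before)

    def test_finetune_reduces_wrong_way_fraction(self, small_session):
        """Training on relabeled (intention-estimated) velocities reduces
        the fraction of away-from-target predictions."""
        s = small_session
        idx = np.arange(s.trials.n_trials)
        X, Y, bins, _ = _dataset(s, idx)
        f = s.trials.frame
        tidx = s.trials.bin_trial_index(s.n_bins)[bins]
        centers = np.column_stack(
            [f.target_idx.to_numpy()[tidx], f.target_mrs.to_numpy()[tidx]]
        )
        pos = s.kinematics.position[bins]
        rng = np.random.default_rng(0)
        corrupted = Y.copy()
        flip = rng.uniform(size=Y.shape) < 0.4
        corrupted[flip] *= -1.0
        base = train_tcn(X, corrupted, config=SMALL_TCN,
                         train_config=TrainConfig(epochs=4, seed=0), seed=0)
        relabeled = refit_relabel(corrupted, pos, centers, 0.15)
        tuned = refit_finetune(base, X, relabeled, iterations=500, seed=0)

        def wrong_way(pred):
            outside = np.abs(pos - centers) > 0.075
            away = (pred * (centers - pos) < 0) & outside
            return away.mean()

        assert wrong_way(tuned.predict(X)) < wrong_way(base.predict(X))


class TestRedistribution:
    def test_off_mode_identity(self, rng):
        rows = np.arange(100)
        v = rng.normal(0, 1, (100, 2))
        np.testing.assert_array_equal(
            redistribute_velocities(rows, v, mode=None), rows
        )

    def test_triangular_speed_density(self, rng):
        v = rng.normal(0, 1.0, (10_000, 2)) * np.abs(rng.normal(0, 1, (10_000, 1)))
        rows = np.arange(len(v))
        resampled = redistribute_velocities(rows, v, seed=0)
        assert len(resampled) == len(rows)
        speed = np.abs(v).mean(axis=1)[resampled]
        smax = np.abs(v).mean(axis=1).max()
        hist, edges = np.histogram(speed, bins=30, range=(0, smax), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        c = smax / 2
        target = np.where(centers <= c, 2 * centers / (smax * c),
                          2 * (smax - centers) / (smax * (smax - c)))
        width = edges[1] - edges[0]
        tv = 0.5 * np.sum(np.abs(hist - target)) * width
        assert tv < 0.1

    def test_seeded_determinism(self, rng):
        v = rng.normal(0, 1, (500, 2))
        rows = np.arange(500)
        a = redistribute_velocities(rows, v, seed=7)
        b = redistribute_velocities(rows, v, seed=7)
        np.testing.assert_array_equal(a, b)


class TestNormalizationInvariance:
    def test_affine_input_transform_leaves_predictions_unchanged(
        self, small_session
    ):
        """With input normalization on, training on an affinely transformed
        copy of the data yields identical rescaled holdout predictions."""
        (Xtr, Ytr, _, _), (Xte, _, _, _) = _small_data(small_session)
        preds = []
        for a, b in [(1.0, 0.0), (3.0, 5.0)]:
            net = build_tcn(SMALL_TCN, seed=0)
            dec = train_network(
                net, a * Xtr + b, Ytr,
                TrainConfig(epochs=3, seed=0, normalize_inputs=True),
            )
            preds.append(dec.predict(a * Xte + b))
        np.testing.assert_allclose(preds[0], preds[1], atol=1e-5)


class TestCheckpointing:
    def test_ridge_json_roundtrip(self, rng, tmp_path):
        from nldbench.linear import load_ridge, save_ridge

        x = rng.normal(0, 1, (30, 5))
        y = rng.normal(0, 1, (30, 2))
        model = fit_ridge(x, y)
        save_ridge(model, tmp_path / "rr.json", provenance={"fold": 0})
        loaded = load_ridge(tmp_path / "rr.json")
        np.testing.assert_allclose(loaded.predict(x), model.predict(x))

    def test_tcn_checkpoint_roundtrip(self, small_session, tmp_path):
        from nldbench.decoders import load_decoder, save_decoder

        (Xtr, Ytr, _, _), (Xte, _, _, _) = _small_data(small_session)
        dec = train_tcn(Xtr, Ytr, config=SMALL_TCN,
                        train_config=TrainConfig(epochs=2, seed=0), seed=0)
        save_decoder(dec, tmp_path / "tcn.h5")
        loaded = load_decoder(tmp_path / "tcn.h5")
        np.testing.assert_allclose(loaded.predict(Xte), dec.predict(Xte))
        assert loaded.loss_trace == pytest.approx(dec.loss_trace)

    def test_lstm_checkpoint_roundtrip(self, small_session, tmp_path):
        from nldbench.decoders import load_decoder, save_decoder

        (Xtr, Ytr, btr, str_), (Xte, Yte, bte, ste) = _small_data(small_session, 40)
        cfg = LSTMConfig(n_channels=24, hidden_size=8, epochs=1, seed=0,
                         batch_size=64)
        dec = train_lstm(small_session.sbp, btr, Ytr, str_, cfg)
        save_decoder(dec, tmp_path / "lstm.h5")
        loaded = load_decoder(tmp_path / "lstm.h5")
        np.testing.assert_allclose(
            loaded.predict_bins(small_session.sbp, bte, ste),
            dec.predict_bins(small_session.sbp, bte, ste),
        )
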