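"""Tests of the task simulator and the neural-encoding generator."""

import numpy as np
import pytest
from scipy.signal import welch
from scipy.stats import kurtosis

from nldbench.session import BinnedSession
from nldbench.synthetic import (
    TaskConfig,
    encode_sbp,
    generate_encoding_model,
    generate_raw_segment,
    generate_session,
    generate_task_trials,
    kinematic_features,
)


class TestTaskTrials:
    def test_target_geometry_and_bounds(self):
        kin, trials = generate_task_trials(TaskConfig(n_trials=40, seed=0))
        assert (trials["target_width"] == 0.15).all()
        assert kin.position.min() >= 0.0 and kin.position.max() <= 1.0
        half = trials["target_width"].to_numpy() / 2
        for col in ("target_idx", "target_mrs"):
            c = trials[col].to_numpy()
            assert (c - half >= -1e-12).all() and (c + half <= 1 + 1e-12).all()

    def test_velocity_is_discrete_derivative(self):
        kin, _ = generate_task_trials(TaskConfig(n_trials=20, seed=3))
        dt = kin.bin_ms / 1000.0
        expected = np.diff(kin.position, axis=0) / dt
        np.testing.assert_allclose(kin.velocity[1:], expected, atol=1e-9)
        assert np.all(kin.velocity[0] == 0.0)

    def test_seeded_determinism(self):
        a_kin, a_tr = generate_task_trials(TaskConfig(n_trials=10, seed=42))
        b_kin, b_tr = generate_task_trials(TaskConfig(n_trials=10, seed=42))
        np.testing.assert_array_equal(a_kin.position, b_kin.position)
        assert a_tr.frame.equals(b_tr.frame)

    def test_trials_contiguous_and_valid(self):
        kin, trials = generate_task_trials(TaskConfig(n_trials=25, seed=9))
        trials.validate(n_bins=kin.n_bins)
        assert trials.frame.end_bin.iloc[-1] == kin.n_bins

    @pytest.mark.parametrize(
        "field,value",
        [
            ("target_width", 0.0),
            ("target_width", 1.5),
            ("hold_time_ms", 20_000.0),
            ("bin_ms", 0.0),
            ("n_trials", 0),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = TaskConfig(**{field: value})
        with pytest.raises(ValueError, match=field):
            cfg.validate()

    @pytest.mark.parametrize("seed", range(10))
    def test_velocity_distribution_peaked_with_heavy_tails(self, seed):
        kin, _ = generate_task_trials(TaskConfig(n_trials=60, seed=seed))
        v = kin.velocity.ravel()
        assert kurtosis(v) > 0.0  # heavier-tailed than Gaussian
        speed = np.abs(v)
        assert (speed < 0.1 * speed.max()).mean() > 0.5  # holding dominates

    def test_failed_trials_marked_and_long(self):
        cfg = TaskConfig(n_trials=40, seed=5, failure_rate=0.5)
        kin, trials = generate_task_trials(cfg)
        f = trials.frame
        assert (~f.success).sum() > 0
        spans = f.end_bin - f.start_bin
        assert spans[~f.success].min() > spans[f.success].max()


class TestEncodingModel:
    def test_channel_cardinality_and_determinism(self):
        m1 = generate_encoding_model(96, "saturating", seed=0)
        m2 = generate_encoding_model(96, "saturating", seed=0)
        assert m1.n_channels == 96 and m1.weights.shape == (96, 6)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        m3 = generate_encoding_model(96, "saturating", seed=1)
        assert not np.array_equal(m1.weights, m3.weights)

    def test_linear_model_affine_recoverable(self):
        """Least squares on noiseless linear-encoding data recovers the
        ground-truth affine map to numerical precision."""
        model = generate_encoding_model(4, "linear", seed=2)
        kin, _ = generate_task_trials(TaskConfig(n_trials=30, seed=4))
        expected = model.expected_sbp(kin)
        x = np.column_stack([kinematic_features(kin), np.ones(kin.n_bins)])
        coef, *_ = np.linalg.lstsq(x, expected, rcond=None)
        truth = np.vstack([(model.weights * model.gain[:, None]).T,
                           model.baseline])
        assert np.abs(coef - truth).max() < 1e-6
        resid = expected - x @ coef
        assert np.mean(resid**2) < 1e-10

    def test_expected_sbp_nonnegative(self):
        for link in ("linear", "saturating"):
            model = generate_encoding_model(16, link, seed=3)
            kin, _ = generate_task_trials(TaskConfig(n_trials=20, seed=6))
            assert model.expected_sbp(kin).min() >= 0.0

    def test_unknown_context_lists_known(self):
        model = generate_encoding_model(4, "saturating", seed=0)
        kin, _ = generate_task_trials(TaskConfig(n_trials=5, seed=0))
        with pytest.raises(ValueError, match="spring"):
            encode_sbp(kin, model, context="zero-g")

    def test_degenerate_model_constant_baseline(self):
        model = generate_encoding_model(6, "linear", seed=1)
        model.weights[:] = 0.0
        model.noise_sd[:] = 0.0
        kin, _ = generate_task_trials(TaskConfig(n_trials=5, seed=2))
        sbp = encode_sbp(kin, model, seed=0)
        np.testing.assert_allclose(sbp, np.tile(model.baseline, (kin.n_bins, 1)))

    def test_context_shift_changes_sbp_not_kinematics(self):
        model = generate_encoding_model(8, "saturating", seed=4)
        kin, _ = generate_task_trials(TaskConfig(n_trials=10, seed=8))
        a = encode_sbp(kin, model, context="normal", seed=0)
        b = encode_sbp(kin, model, context="spring-wrist", seed=0)
        assert np.abs(a - b).max() > 0.0

    def test_normal_context_is_identity(self):
        model = generate_encoding_model(8, "saturating", seed=4)
        b0, w0, g0 = model.shifted_params("normal")
        np.testing.assert_array_equal(w0, model.weights)
        np.testing.assert_array_equal(g0, model.gain)

    def test_zero_magnitude_shift_is_identity_everywhere(self):
        model = generate_encoding_model(8, "saturating", seed=4,
                                        shift_magnitude=0.0)
        for ctx in model.known_contexts():
            b, w, g = model.shifted_params(ctx)
            np.testing.assert_allclose(w, model.weights)
            np.testing.assert_allclose(g, model.gain)
            np.testing.assert_allclose(b, model.baseline)

    def test_high_snr_linear_regression_recovers_tuning(self):
        """Per-channel OLS of SBP on kinematic features recovers the
        ground-truth weights within 3 standard errors."""
        model = generate_encoding_model(6, "linear", seed=5, noise_scale=0.01)
        kin, _ = generate_task_trials(TaskConfig(n_trials=60, seed=10))
        sbp = encode_sbp(kin, model, seed=1)
        x = np.column_stack([kinematic_features(kin), np.ones(kin.n_bins)])
        coef, res, *_ = np.linalg.lstsq(x, sbp, rcond=None)
        n, p = x.shape
        xtx_inv = np.linalg.inv(x.T @ x)
        truth = (model.weights * model.gain[:, None]).T
        for c in range(6):
            resid = sbp[:, c] - x @ coef[:, c]
            sigma2 = resid @ resid / (n - p)
            se = np.sqrt(np.diag(xtx_inv) * sigma2)
            assert np.all(np.abs(coef[:6, c] - truth[:, c]) < 3 * se[:6] + 1e-9)


class TestSession:
    def test_multi_context_block_structure(self):
        s = generate_session(
            TaskConfig(n_trials=10, seed=1),
            contexts=[(c, 10) for c in ("normal", "spring", "wrist", "spring-wrist")],
            n_channels=8,
        )
        assert s.trials.n_trials == 40
        assert s.contexts == ["normal", "spring", "wrist", "spring-wrist"]
        # block order: contexts change at most 3 times
        labels = s.trials["context"].to_numpy()
        changes = (labels[1:] != labels[:-1]).sum()
        assert changes == 3

    def test_single_context_session(self):
        s = generate_session(TaskConfig(n_trials=30, seed=2), n_channels=8)
        assert s.trials.n_trials == 30
        assert s.sbp.shape == (s.n_bins, 8)
        assert s.sbp.min() >= 0.0 and not np.isnan(s.sbp).any()

    def test_session_determinism_roundtrip(self, tmp_path):
        a = generate_session(TaskConfig(n_trials=12, seed=3), n_channels=6)
        b = generate_session(TaskConfig(n_trials=12, seed=3), n_channels=6)
        np.testing.assert_array_equal(a.sbp, b.sbp)
        a.save(tmp_path / "a.h5")
        b.save(tmp_path / "b.h5")
        assert (tmp_path / "a.h5").read_bytes() == (tmp_path / "b.h5").read_bytes()
        loaded = BinnedSession.load(tmp_path / "a.h5")
        np.testing.assert_array_equal(loaded.sbp, a.sbp)
        np.testing.assert_array_equal(
            loaded.kinematics.velocity, a.kinematics.velocity
        )
        assert loaded.trials.n_trials == a.trials.n_trials

    def test_trial_table_csv_export(self, tmp_path):
        s = generate_session(TaskConfig(n_trials=5, seed=4), n_channels=4)
        s.trials.to_csv(tmp_path / "trials.csv")
        text = (tmp_path / "trials.csv").read_text()
        assert text.splitlines()[0].startswith("start_bin,end_bin")
        assert len(text.splitlines()) == 6


class TestRawSegment:
    def test_zero_power_and_length(self):
        assert np.all(
            generate_raw_segment(0.5, 30000, {"band": (300, 1000), "power": 0.0})
            == 0.0
        )
        sig = generate_raw_segment(1.0, 30000, {"band": (300, 1000), "power": 1.0})
        assert sig.shape == (30000,)

    def test_power_concentrated_in_band(self):
        sig = generate_raw_segment(
            2.0, 30000, {"band": (300, 1000), "power": 1.0}, seed=3
        )
        f, pxx = welch(sig, fs=30000, nperseg=4096)
        in_band = (f >= 250) & (f <= 1100)
        assert pxx[in_band].sum() / pxx.sum() > 0.9
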