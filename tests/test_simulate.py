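import hashlib

import numpy as np
import pytest

from hybridbci.gate import gate_ratios
from hybridbci.io import TRAJECTORY_CLASSES, load_manifest
from hybridbci.preprocess import STAGE1_FILTER, bandpass_zero_phase, trim_warnings
from hybridbci.simulate import (
    SessionShift,
    SimulationConfig,
    iter_trial_keys,
    simulate_dataset,
    simulate_trial,
    subject_profile,
    trajectory_template,
)

FS = 256.0


class TestTrajectoryTemplate:
    def test_up_down_leaves_lateral_channels_silent(self):
        t = trajectory_template("up_down", 10.0, FS)
        assert np.all(t[:, 1] == 0) and np.all(t[:, 2] == 0)
        np.testing.assert_array_equal(t[:, 0], t[:, 3])

    def test_right_left_leaves_frontal_channels_silent(self):
        t = trajectory_template("right_left", 10.0, FS)
        assert np.all(t[:, 0] == 0) and np.all(t[:, 3] == 0)
        np.testing.assert_array_equal(t[:, 1], -t[:, 2])

    def test_diagonal_classes_flip_horizontal_sign_only(self):
        left = trajectory_template("left_cross", 10.0, FS)
        right = trajectory_template("right_cross", 10.0, FS)
        np.testing.assert_array_equal(left[:, 0], right[:, 0])
        np.testing.assert_array_equal(left[:, 3], right[:, 3])
        np.testing.assert_array_equal(left[:, 1], -right[:, 1])
        np.testing.assert_array_equal(left[:, 2], -right[:, 2])

    def test_peak_amplitude_is_one(self):
        for cls in TRAJECTORY_CLASSES:
            assert np.abs(trajectory_template(cls, 10.0, FS)).max() == pytest.approx(1.0)

    @pytest.mark.parametrize("period", [1.0, 2.0, 4.0])
    def test_dominant_frequency_is_sweep_rate(self, period):
        t = trajectory_template("left_cross", 10.0, FS, motion_period=period)
        for col in range(4):
            spec = np.abs(np.fft.rfft(t[:, col]))
            freqs = np.fft.rfftfreq(t.shape[0], 1 / FS)
            assert freqs[np.argmax(spec)] == pytest.approx(1 / period, abs=0.11)

    def test_random_gaze_has_no_template(self):
        with pytest.raises(ValueError, match="random_gaze"):
            trajectory_template("random_gaze", 10.0, FS)


class TestSubjectProfile:
    def test_deterministic_and_distinct(self):
        cfg = SimulationConfig(seed=5)
        a = subject_profile(cfg, 0)
        b = subject_profile(cfg, 0)
        np.testing.assert_array_equal(a.channel_gains, b.channel_gains)
        assert a.ssvep_gain == b.ssvep_gain
        c = subject_profile(cfg, 1)
        assert not np.array_equal(a.channel_gains, c.channel_gains)

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            subject_profile(SimulationConfig(n_subjects=3), 3)

    def test_amplitude_multiplier_spread_is_moderate(self):
        cfg = SimulationConfig(seed=7)
        gains = [subject_profile(cfg, i).ssvep_gain for i in range(15)]
        cv = np.std(gains) / np.mean(gains)
        assert 0.05 < cv < 0.6


class TestSimulateTrial:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(seed=3)
        prof = subject_profile(cfg, 0)
        a = simulate_trial(cfg, prof, "evening", "left_cross", 2)
        b = simulate_trial(cfg, prof, "evening", "left_cross", 2)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_trial_shape_and_metadata(self):
        cfg = SimulationConfig(seed=3)
        rec = simulate_trial(cfg, subject_profile(cfg, 0), "morning",
                             "random_gaze", 1)
        assert rec.samples.shape == (4096, 4)
        assert rec.key == ("sub01", "morning", "random_gaze", 1)

    def test_invalid_enums_rejected(self):
        cfg = SimulationConfig(seed=3)
        prof = subject_profile(cfg, 0)
        with pytest.raises(ValueError):
            simulate_trial(cfg, prof, "midnight", "up_down", 1)
        with pytest.raises(ValueError):
            simulate_trial(cfg, prof, "morning", "sideways", 1)

    def test_led_off_trials_have_lower_band_ratio(self):
        """The 6-8/4-10 Hz band-area ratio separates LED-on from LED-off."""
        cfg = SimulationConfig(seed=9)
        prof = subject_profile(cfg, 0)

        def mean_ratio(class_label):
            vals = []
            for rep in range(1, 11):
                rec = simulate_trial(cfg, prof, "morning", class_label, rep)
                x = trim_warnings(rec, cfg.warning_seconds).samples
                filt = bandpass_zero_phase(x, STAGE1_FILTER, cfg.fs)
                vals.append(gate_ratios(filt[:768], cfg.fs).mean())
            return np.mean(vals)

        assert mean_ratio("random_gaze") < mean_ratio("up_down")

    def test_neutral_shift_matches_session_variances(self):
        """With the identity shift the two sessions are identically distributed."""
        cfg = SimulationConfig(seed=13, session_shift=SessionShift.neutral())
        prof = subject_profile(cfg, 0)
        var = {}
        for session in ("morning", "evening"):
            v = [simulate_trial(cfg, prof, session, "up_down", r).samples.var(axis=0)
                 for r in range(1, 51)]
            var[session] = np.mean(v, axis=0)
        np.testing.assert_allclose(var["morning"], var["evening"], rtol=0.10)


class TestSimulateDataset:
    def test_small_dataset_counts_and_determinism(self, tmp_path):
        cfg = SimulationConfig(n_subjects=1, reps_per_class=1, seed=2)
        m1 = simulate_dataset(cfg, tmp_path / "a")
        assert len(m1) == 10  # 1 subject x 2 sessions x 5 classes x 1 rep
        m2 = simulate_dataset(cfg, tmp_path / "b")
        for e1, e2 in zip(m1.entries, m2.entries):
            h1 = hashlib.sha256((m1.root / e1.path).read_bytes()).hexdigest()
            h2 = hashlib.sha256((m2.root / e2.path).read_bytes()).hexdigest()
            assert h1 == h2
        loaded = load_manifest(tmp_path / "a" / "manifest.csv")
        assert len(loaded) == 10
        rec = next(loaded.iter_recordings())
        assert rec.samples.shape == (4096, 4)

    def test_default_protocol_yields_1500_keys(self):
        assert sum(1 for _ in iter_trial_keys(SimulationConfig())) == 1500

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(warning_seconds=9.0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(ssvep_amp=-1.0).validate()
        with pytest.raises(ValueError):
            SessionShift(gain_drift=(0.0, 1.0)).validate()
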