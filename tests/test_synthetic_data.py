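import numpy as np
import pytest
from scipy.signal import welch

from emodyn.bands import RHYTHM_EDGES
from emodyn.synthetic_data import (CohortConfig, ConfigError,
                                   generate_cohort, generate_latent_state,
                                   generate_recording, read_recording_csv,
                                   write_recording_csv)

FS = 125.0


def small_config(**kw):
    defaults = dict(n_per_condition=2, duration=60.0, seed=7)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestGenerateRecording:
    def test_fixed_seed_bit_identical(self):
        cfg = small_config()
        a = generate_recording(cfg, "grayscale", 3)
        b = generate_recording(cfg, "grayscale", 3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_shape_15_channels_300s(self):
        cfg = small_config(duration=300.0)
        rec = generate_recording(cfg, "color", 0)
        assert rec.data.shape == (15, 37500)
        assert rec.fs == FS

    def test_alpha_only_config_concentrates_power(self):
        gains = {"grayscale": {"alpha": 1.0}, "color": {"alpha": 1.0}}
        cfg = small_config(duration=120.0, band_gains=gains,
                           noise_gain={"grayscale": 0.0, "color": 0.0},
                           modulation_depth=0.0,
                           emotion_rate={"grayscale": 3.0, "color": 10.0})
        rec = generate_recording(cfg, "grayscale", 1)
        f, P = welch(rec.data, fs=FS, nperseg=1024)
        lo, hi = RHYTHM_EDGES["alpha"]
        in_band = P[:, (f >= lo) & (f < hi)].sum(axis=1)
        assert np.all(in_band / P.sum(axis=1) >= 0.9)

    def test_band_power_ratios_track_gains(self):
        cfg = small_config(duration=120.0,
                           noise_gain={"grayscale": 0.0, "color": 0.0},
                           modulation_depth=0.0)
        rec = generate_recording(cfg, "grayscale", 5)
        f, P = welch(rec.data, fs=FS, nperseg=1024)
        gains = cfg.band_gains["grayscale"]
        total_gain = sum(gains.values())
        total_power = 0.0
        band_power = {}
        for name, (lo, hi) in RHYTHM_EDGES.items():
            bp = P[:, (f >= lo) & (f < hi)].sum(axis=1).mean()
            band_power[name] = bp
            total_power += bp
        for name in RHYTHM_EDGES:
            got = band_power[name] / total_power
            want = gains[name] / total_gain
            assert abs(got - want) / want < 0.15

    def test_unknown_condition_rejected(self):
        with pytest.raises(ConfigError, match="condition"):
            generate_recording(small_config(), "sepia", 0)

    def test_channels_z_scored(self):
        rec = generate_recording(small_config(), "grayscale", 2)
        np.testing.assert_allclose(rec.data.std(axis=1), 1.0, rtol=1e-9)
        np.testing.assert_allclose(rec.data.mean(axis=1), 0.0, atol=1e-9)


class TestLatentState:
    @pytest.mark.parametrize("rate", [3.0, 8.0])
    def test_empirical_crossing_rate(self, rate):
        dur = 300.0
        counts = []
        for seed in range(5):
            lat = generate_latent_state(int(dur * FS), FS, rate,
                                        np.random.default_rng(seed))
            counts.append(int((np.diff(lat >= 0) != 0).sum()))
        got = np.mean(counts) / dur * 60.0
        assert abs(got - rate) / rate < 0.2

    def test_unit_variance_zero_mean(self):
        lat = generate_latent_state(10_000, FS, 5.0, np.random.default_rng(0))
        assert lat.mean() == pytest.approx(0.0, abs=1e-12)
        assert lat.std() == pytest.approx(1.0, rel=1e-9)


class TestGenerateCohort:
    def test_cohort_size_and_labels(self):
        recs, truth = generate_cohort(small_config())
        assert len(recs) == 4
        assert truth.conditions.count("grayscale") == 2
        assert truth.conditions.count("color") == 2

    def test_paper_scale_cohort_count(self):
        cfg = CohortConfig(n_per_condition=19, duration=10.0)
        recs, _ = generate_cohort(cfg)
        assert len(recs) == 38

    def test_ground_truth_orderings(self):
        cfg = small_config()
        _, truth = generate_cohort(cfg)
        assert truth.higher_cli_condition == "grayscale"
        assert truth.higher_emotion_rate_condition == "color"
        assert truth.modulation_sign == "negative"

    def test_modulation_sign_follows_rate_ordering(self):
        cfg = small_config(emotion_rate={"grayscale": 10.0, "color": 3.0})
        _, truth = generate_cohort(cfg)
        assert truth.modulation_sign == "positive"

    def test_cohort_deterministic(self):
        a, _ = generate_cohort(small_config())
        b, _ = generate_cohort(small_config())
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.data, rb.data)


class TestConfigValidation:
    def test_bad_sizes_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_per_condition=1)
        with pytest.raises(ConfigError):
            CohortConfig(duration=0.0)

    def test_bad_gains_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(band_gains={"a": {"alpha": -1.0}},
                         emotion_rate={"a": 1.0})
        with pytest.raises(ConfigError):
            CohortConfig(band_gains={"a": {"sigma": 1.0}},
                         emotion_rate={"a": 1.0})

    def test_missing_rate_rejected(self):
        with pytest.raises(ConfigError, match="emotion_rate"):
            CohortConfig(band_gains={"a": {"alpha": 1.0}, "b": {"alpha": 2.0}},
                         emotion_rate={"a": 1.0})


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        rec = generate_recording(small_config(duration=5.0), "color", 4)
        path = write_recording_csv(rec, tmp_path / "sub.csv")
        back = read_recording_csv(path)
        assert back.channel_labels == rec.channel_labels
        assert back.fs == rec.fs
        assert back.meta["condition"] == "color"
        np.testing.assert_allclose(back.data, rec.data, atol=1e-10)

    def test_edf_export_unsupported(self, tmp_path):
        rec = generate_recording(small_config(duration=5.0), "color", 4)
        with pytest.raises(NotImplementedError):
            write_recording_csv(rec, tmp_path / "sub.edf")
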