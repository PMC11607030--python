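"""Synthetic diathermy audio and synthetic adapter impulse responses."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import freqz, welch

from laparosound.audio import read_wav
from laparosound.synth import (ChannelProfile, TissueSoundSpec,
                               default_channel_profiles, default_tissue_specs,
                               make_dataset, synth_adapter_ir, synth_tissue_sound)


class TestTissueSounds:
    def test_deterministic_for_fixed_seed(self):
        spec = default_tissue_specs()["liver"]
        a = synth_tissue_sound(spec, 1.0, seed=1)
        b = synth_tissue_sound(spec, 1.0, seed=1)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_idle_rms_tracks_noise_floor(self):
        spec = TissueSoundSpec("idle", 0.0, 0.0, 0.0, 1.0, -60.0, (1.0, 30.0))
        sig = synth_tissue_sound(spec, 2.0, seed=7)
        rms_db = 20 * np.log10(sig.rms())
        assert abs(rms_db - (-60.0)) <= 3.0

    def test_spectral_peak_inside_declared_band(self):
        spec = default_tissue_specs()["fat"]  # centered at 3 kHz
        sig = synth_tissue_sound(spec, 1.5, seed=3)
        f, pxx = welch(sig.samples, fs=sig.fs, nperseg=4096)
        peak = f[np.argmax(pxx)]
        assert spec.center_freq_hz - spec.bandwidth_hz / 2 <= peak \
            <= spec.center_freq_hz + spec.bandwidth_hz / 2

    @pytest.mark.parametrize("cls", ["liver", "muscle", "fascia"])
    def test_spectral_centroid_near_center(self, cls):
        spec = default_tissue_specs()[cls]
        sig = synth_tissue_sound(spec, 2.0, seed=11)
        f, pxx = welch(sig.samples, fs=sig.fs, nperseg=4096)
        centroid = float(np.sum(f * pxx) / np.sum(pxx))
        assert abs(centroid - spec.center_freq_hz) <= spec.bandwidth_hz

    def test_duration_outside_range_rejected(self):
        spec = default_tissue_specs()["liver"]
        with pytest.raises(ValueError, match="duration"):
            synth_tissue_sound(spec, 10.0, seed=0)

    def test_idle_spec_must_have_zero_burst_rate(self):
        with pytest.raises(ValueError, match="idle"):
            TissueSoundSpec("idle", 0.0, 0.0, 5.0, 1.0, -50.0, (1.0, 20.0))


class TestMakeDataset:
    def test_manifest_row_count(self, tmp_path):
        manifest = make_dataset(tmp_path, n_per_class=4, seed=0)
        assert len(manifest) == 4 * 5
        assert set(manifest["class"]) == {"liver", "muscle", "fat", "fascia", "idle"}

    def test_reproducible_manifests_and_audio(self, tmp_path):
        m1 = make_dataset(tmp_path / "a", n_per_class=3, seed=5)
        m2 = make_dataset(tmp_path / "b", n_per_class=3, seed=5)
        pd.testing.assert_frame_equal(m1, m2)
        for rel in m1["path"]:
            a = read_wav(tmp_path / "a" / rel)
            b = read_wav(tmp_path / "b" / rel)
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_tissue_durations_in_declared_range(self, tmp_path):
        manifest = make_dataset(tmp_path, n_per_class=10, seed=42)
        tissue = manifest[manifest["class"] != "idle"]
        assert (tissue["duration_s"] >= 0.76).all()
        assert (tissue["duration_s"] <= 5.17).all()

    def test_too_few_per_class_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            make_dataset(tmp_path, n_per_class=1, seed=0)


class TestAdapterIRs:
    def test_reference_profile_is_identity_channel(self, reference_ir):
        freqs = np.linspace(100, 7500, 200)
        _, resp = freqz(reference_ir.samples, worN=freqs, fs=reference_ir.fs)
        dev_db = np.abs(20 * np.log10(np.abs(resp)))
        assert dev_db.max() <= 0.1

    def test_dual_channel_band_average(self, dual_channel_ir):
        freqs = np.linspace(100, 7500, 500)
        _, resp = freqz(dual_channel_ir.samples, worN=freqs, fs=dual_channel_ir.fs)
        avg_db = np.mean(20 * np.log10(np.abs(resp)))
        assert abs(avg_db - (-9.4)) <= 0.5

    def test_tube_attenuation_at_1khz(self, tube_ir):
        _, resp = freqz(tube_ir.samples, worN=[100.0, 1000.0], fs=tube_ir.fs)
        mag_db = 20 * np.log10(np.abs(resp))
        assert mag_db[1] - mag_db[0] <= -35.0

    @pytest.mark.parametrize("name", ["reference", "dual_channel", "luer_lock", "tube"])
    def test_magnitude_matches_breakpoints(self, profiles, name):
        profile = profiles[name]
        ir = synth_adapter_ir(profile)
        freqs = np.array([f for f, _ in profile.breakpoints if f < ir.fs / 2])
        _, resp = freqz(ir.samples, worN=freqs, fs=ir.fs)
        got = 20 * np.log10(np.abs(resp))
        assert np.max(np.abs(got - profile.gain_db_at(freqs))) <= 2.0

    @pytest.mark.parametrize("name", ["reference", "dual_channel", "luer_lock", "tube"])
    def test_irs_causal_and_finite(self, profiles, name):
        ir = synth_adapter_ir(profiles[name])
        assert np.all(np.isfinite(ir.samples))
        assert np.isfinite(ir.energy) and ir.energy > 0
        # minimum-phase: energy front-loaded, no pre-ringing tail at the start
        assert np.argmax(np.abs(ir.samples)) < len(ir) // 4

    def test_positive_gain_profile_rejected(self):
        bad = ChannelProfile("boost", ((100.0, 3.0), (1000.0, 0.0)))
        with pytest.raises(ValueError):
            synth_adapter_ir(bad)

    def test_decreasing_breakpoint_freqs_rejected(self):
        with pytest.raises(ValueError):
            ChannelProfile("bad", ((1000.0, 0.0), (100.0, -3.0)))


class TestClassSeparability:
    def test_linear_probe_beats_chance(self):
        """Mean log-mel vectors of the default classes support a linear probe."""
        from sklearn.linear_model import LogisticRegression

        from laparosound.data import balance_idle
        from laparosound.pipeline import patches_for_manifest, synth_manifest

        specs = default_tissue_specs()
        manifest = balance_idle(synth_manifest(6, seed=7, specs=specs), seed=7)
        data = patches_for_manifest(manifest, specs)
        feats = data.x.mean(axis=1)  # time-averaged mel profile per patch
        clf = LogisticRegression(max_iter=500).fit(feats, data.y)
        acc = clf.score(feats, data.y)
        assert acc > 0.2  # chance for 5 classes

        # pairwise distance between class-mean patches strictly positive
        means = np.stack([data.x[data.y == c].mean(axis=0)
                          for c in np.unique(data.y)])
        for i in range(len(means)):
            for j in range(i + 1, len(means)):
                assert np.linalg.norm(means[i] - means[j]) > 0
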