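"""Sensor-space QC: Welch PSD, bad channels, trial rejection, HFC."""

import numpy as np
import pytest

from opmbursts.preprocess import (
    PSDResult,
    TrialMatrix,
    detect_bad_channels,
    homogeneous_field_correction,
    reject_bad_trials,
    segment_trials,
    welch_psd,
)
from opmbursts.synth import BurstSpec, build_helmet_array, make_source_model, \
    simulate_recording

from conftest import make_recording


class TestWelch:
    def test_sinusoid_power_satisfies_parseval(self):
        # unit-amplitude tone has variance 1/2; one-sided density integrates to it
        fs, dur = 1200.0, 600.0
        t = np.arange(int(fs * dur)) / fs
        rec = make_recording(np.sin(2 * np.pi * 20 * t), fs)
        psd = welch_psd(rec)
        total = np.trapezoid(psd.psd[0], psd.freqs)
        assert total == pytest.approx(0.5, rel=0.05)

    def test_white_noise_density_level(self):
        fs, dur, sd = 1200.0, 600.0, 3e-13
        rng = np.random.default_rng(0)
        rec = make_recording(rng.normal(scale=sd, size=int(fs * dur)), fs)
        psd = welch_psd(rec)
        assert psd.psd[0].mean() == pytest.approx(sd**2 / (fs / 2), rel=0.05)

    def test_zero_channel_gives_zero_psd(self):
        rec = make_recording(np.zeros(4000), 200.0)
        assert (welch_psd(rec).psd == 0).all()

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(make_recording(np.zeros(100), 200.0), segment_s=2.0)


def _flat_psd(asd_fT_levels, n_freqs=50, f_max=200.0):
    freqs = np.linspace(1, f_max, n_freqs)
    psd = np.array([[(a * 1e-15) ** 2] * n_freqs for a in asd_fT_levels])
    return PSDResult(freqs=freqs, psd=psd,
                     channel_names=[f"CH{i:02d}" for i in range(len(asd_fT_levels))])


class TestBadChannels:
    def test_noisy_dead_and_clean_channels(self):
        psd = _flat_psd([20.0, 5.0, 0.0])   # above floor, below floor, dead
        bad = detect_bad_channels(psd, floor_limit=16.0, band=(5, 150))
        assert bad == ["CH00", "CH02"]

    def test_monotone_in_floor_limit(self):
        rng = np.random.default_rng(1)
        psd = _flat_psd(rng.uniform(2, 40, size=24))
        flags16 = set(detect_bad_channels(psd, floor_limit=16.0))
        flags20 = set(detect_bad_channels(psd, floor_limit=20.0))
        assert flags20 <= flags16

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            detect_bad_channels(_flat_psd([5.0]), band=(300, 400))


class TestTrialSegmentation:
    def test_trial_matrix_shape(self, tiny_dataset):
        trials = segment_trials(tiny_dataset.recording)
        assert trials.data.shape == (22, tiny_dataset.recording.n_channels, 3200)
        assert trials.labels.is_rest.sum() == 2

    def test_empty_events_empty_matrix(self):
        rec = make_recording(np.zeros((2, 4000)), 200.0)
        trials = segment_trials(rec)
        assert trials.n_trials == 0

    def test_trial_past_recording_end_rejected(self, tiny_dataset):
        rec = tiny_dataset.recording
        short = rec.copy_with(data=rec.data[:, :-400])
        with pytest.raises(ValueError, match="past"):
            segment_trials(short)


class TestTrialRejection:
    @staticmethod
    def _trials(data, fs=200.0):
        import pandas as pd
        n = data.shape[0]
        labels = pd.DataFrame(dict(trial_index=range(n), is_rest=False,
                                   cue="left", start_s=np.arange(n) * 16.0))
        return TrialMatrix(data=data, labels=labels,
                           kept=np.ones(n, dtype=bool), fs=fs)

    def test_single_loud_trial_rejected(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((11, 3, 400))
        data[7] *= 10
        kept = reject_bad_trials(self._trials(data), k=3).kept
        assert not kept[7] and kept.sum() == 10

    def test_identical_trials_all_kept(self):
        data = np.tile(np.random.default_rng(1).standard_normal((1, 2, 100)),
                       (5, 1, 1))
        assert reject_bad_trials(self._trials(data), k=3).kept.all()

    def test_infinite_threshold_keeps_everything(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((6, 2, 100)) * rng.uniform(1, 50, (6, 1, 1))
        assert reject_bad_trials(self._trials(data), k=np.inf).kept.all()

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((9, 2, 200)) * rng.uniform(0.5, 4, (9, 1, 1))
        k1 = reject_bad_trials(self._trials(data), k=2).kept
        k2 = reject_bad_trials(self._trials(data * 1e7), k=2).kept
        assert np.array_equal(k1, k2)


class TestHFC:
    @staticmethod
    def _array_recording(data, rng=0):
        array = build_helmet_array(6, 0.12, rng=rng)
        from opmbursts.containers import RawRecording
        return RawRecording(data=data, fs=200.0,
                            channel_names=list(array.channel_names),
                            positions=array.channel_positions,
                            axes=array.channel_axes)

    def test_pure_uniform_field_annihilated(self):
        rng = np.random.default_rng(0)
        array = build_helmet_array(6, 0.12, rng=1)
        b = rng.standard_normal((3, 500))
        data = array.channel_axes @ b
        corrected, removed = homogeneous_field_correction(self._array_recording(data, 1))
        assert np.linalg.norm(corrected.data) < 1e-10 * np.linalg.norm(data)
        assert np.allclose(removed, data)

    def test_orthogonal_component_untouched(self):
        rng = np.random.default_rng(2)
        array = build_helmet_array(6, 0.12, rng=3)
        S = array.channel_axes
        P = np.eye(S.shape[0]) - S @ np.linalg.pinv(S)
        data = P @ rng.standard_normal((S.shape[0], 500))
        corrected, _ = homogeneous_field_correction(self._array_recording(data, 3))
        assert np.allclose(corrected.data, data, atol=1e-12 * np.abs(data).max())

    def test_projector_idempotent(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((18, 400))
        rec = self._array_recording(data, 5)
        once, _ = homogeneous_field_correction(rec)
        twice, _ = homogeneous_field_correction(once)
        assert np.allclose(twice.data, once.data, atol=1e-12 * np.abs(data).max())

    def test_rank_deficient_model_warns(self):
        data = np.zeros((4, 100))
        axes = np.tile([0.0, 0.0, 1.0], (4, 1))
        from opmbursts.containers import RawRecording
        rec = RawRecording(data=data, fs=100.0, channel_names=list("abcd"),
                           positions=np.zeros((4, 3)), axes=axes)
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            homogeneous_field_correction(rec)

    def test_strong_drift_removed_source_preserved(self, small_schedule):
        # drift amplitude >> source amplitude; HFC must recover the projection
        array = build_helmet_array(8, 0.12, rng=6)
        model = make_source_model(2)
        ds = simulate_recording(small_schedule, model, array, BurstSpec(),
                                noise_sd=0.0, drift_amplitude=1e-10,
                                fs=200.0, rng=8)
        clean = np.zeros_like(ds.recording.data)
        from opmbursts.synth import region_lead_field
        for r in range(model.n_regions):
            gain = region_lead_field(model, array, r) @ ds.truth_orientations[r]
            clean += np.outer(gain, ds.truth_sources[r])
        corrected, removed = homogeneous_field_correction(ds.recording)

        drift = ds.recording.data - clean
        residual_drift, _ = np.linalg.lstsq(
            ds.recording.axes, corrected.data, rcond=None)[:2]
        # uniform-component power after vs before correction, in dB
        before = np.linalg.norm(ds.recording.axes @ np.linalg.lstsq(
            ds.recording.axes, drift, rcond=None)[0])
        after = np.linalg.norm(ds.recording.axes @ residual_drift)
        assert 20 * np.log10(before / max(after, 1e-30)) > 60

        ch = np.argmax(np.abs(clean).max(axis=1))
        r = np.corrcoef(corrected.data[ch], (clean - ds.recording.axes @
                        np.linalg.lstsq(ds.recording.axes, clean, rcond=None)[0])[ch])[0, 1]
        assert r > 0.99
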