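"""Synthetic scene generation: signal shapes, labels, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import butter, sosfilt

from bowpam.scene_synth import (CallTemplate, IceGeometrySpec, SceneSpec,
                                synth_call, synth_clip, synth_dataset,
                                synth_icefield)
from bowpam.spectro_prep import tile_spectrogram


def band_power(x, f_lo, f_hi, rate=5000.0):
    sos = butter(4, [f_lo, f_hi], btype="bandpass", fs=rate, output="sos")
    return np.mean(sosfilt(sos, x) ** 2)


class TestSynthCall:
    def test_constant_tone_peaks_at_its_frequency(self):
        x = synth_call(CallTemplate("simple_fm", 500, 500, 2.0), 5000)
        pad = np.zeros(120 * 5000, dtype=float)
        pad[: x.size] = x
        tile = tile_spectrogram(pad, clip_seconds=120)
        peak = tile.freqs_hz[tile.values[:, 3].argmax()]
        assert abs(peak - 500) <= 5000 / 4096

    def test_downsweep_instantaneous_frequency_decreases(self):
        x = synth_call(CallTemplate("simple_fm", 800, 200, 2.0), 5000)
        crossings = np.flatnonzero(np.diff(np.signbit(x)))
        periods = np.diff(crossings) * 2  # samples per cycle
        inst_freq = 5000.0 / periods
        # average in 10 coarse bins to suppress zero-crossing quantization
        per_bin = inst_freq.size // 10
        binned = inst_freq[: per_bin * 10].reshape(10, per_bin).mean(axis=1)
        assert np.all(np.diff(binned) < 0)
        assert binned[0] > 700 and binned[-1] < 300

    def test_harmonic_level_follows_decay_ratio(self):
        # harmonic_decay 0.5 puts the first overtone 6 dB below the
        # fundamental: band power ratio ~0.25, measured by narrowband
        # filtering around f and 2f
        t = CallTemplate("song_unit", 300, 300, 3.0, n_harmonics=2,
                         harmonic_decay=0.5)
        x = synth_call(t, 5000)
        p1 = band_power(x, 280, 320)
        p2 = band_power(x, 580, 620)
        ratio_db = 10 * np.log10(p2 / p1)
        assert ratio_db == pytest.approx(-6.0, abs=1.0)

    def test_fundamental_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            synth_call(CallTemplate("simple_fm", 2600, 100, 1.0), 5000)

    def test_harmonics_above_nyquist_are_clipped(self):
        t = CallTemplate("song_unit", 2000, 2000, 0.5, n_harmonics=5)
        x = synth_call(t, 5000)
        assert np.all(np.isfinite(x)) and np.abs(x).max() == pytest.approx(1.0)


class TestSynthClip:
    def fm(self, snr=10.0):
        return CallTemplate("simple_fm", 400, 250, 1.5, snr_db=snr)

    def transient(self):
        return CallTemplate("ice_transient", 900, 100, 0.1)

    def test_no_events_is_negative(self):
        clip = synth_clip(SceneSpec(5000, 30.0, events=(), seed=1))
        assert clip.label == 0

    def test_confounders_do_not_set_the_label(self):
        events = ((self.fm(), 5.0), (self.transient(), 1.0),
                  (self.transient(), 10.0), (self.transient(), 20.0))
        clip = synth_clip(SceneSpec(5000, 30.0, events=events, seed=1))
        assert clip.label == 1
        only_conf = tuple(e for e in events if e[0].kind == "ice_transient")
        clip0 = synth_clip(SceneSpec(5000, 30.0, events=only_conf, seed=1))
        assert clip0.label == 0

    def test_same_seed_bit_identical(self):
        spec = SceneSpec(5000, 30.0, events=((self.fm(), 3.0),), seed=42)
        a, b = synth_clip(spec), synth_clip(spec)
        assert np.max(np.abs(a.waveform - b.waveform)) == 0.0

    def test_peak_bounded(self):
        spec = SceneSpec(5000, 30.0, events=((self.fm(30.0), 3.0),), seed=7)
        assert np.abs(synth_clip(spec).waveform).max() <= 1.0

    def test_event_past_clip_end_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(5000, 30.0, events=((self.fm(), 29.5),))

    def test_snr_calibration_in_band(self):
        # a 20 dB event should raise in-band power during the event by
        # roughly its nominal SNR relative to noise-only sections
        ev = CallTemplate("simple_fm", 400, 300, 5.0, snr_db=20.0)
        clip = synth_clip(SceneSpec(5000, 30.0, events=((ev, 10.0),), seed=3))
        w = clip.waveform.astype(float)
        p_event = band_power(w[10 * 5000:15 * 5000], 50, 1000)
        p_noise = band_power(w[20 * 5000:25 * 5000], 50, 1000)
        snr_est = 10 * np.log10(max(p_event - p_noise, 1e-12) / p_noise)
        assert snr_est == pytest.approx(20.0, abs=3.0)


class TestSynthDataset:
    def test_manifest_counts_and_grid(self):
        clips, manifest = synth_dataset(3, 7, clip_duration=10.0, seed=5)
        assert len(manifest) == 10
        assert manifest["label"].sum() == 3
        assert [c.label for c in clips] == manifest["label"].tolist()
        times = pd.to_datetime(manifest["start_time"])
        deltas = times.diff().dropna().unique()
        assert list(deltas) == [pd.Timedelta(minutes=10)]

    def test_seed_reproducibility(self):
        clips1, m1 = synth_dataset(2, 2, clip_duration=10.0, seed=9)
        clips2, m2 = synth_dataset(2, 2, clip_duration=10.0, seed=9)
        pd.testing.assert_frame_equal(m1, m2)
        for a, b in zip(clips1, clips2):
            assert np.max(np.abs(a.waveform - b.waveform)) == 0.0

    def test_wav_round_trip(self, tmp_path):
        from scipy.io import wavfile
        clips, manifest = synth_dataset(1, 1, clip_duration=5.0, seed=2,
                                        out_dir=tmp_path)
        rate, data = wavfile.read(manifest["path"][0])
        assert rate == 5000
        np.testing.assert_array_equal(data, clips[0].waveform)


class TestSynthIcefield:
    def test_half_plane_water_side(self):
        spec = IceGeometrySpec((40, 40), "half_plane",
                               {"edge_col": 8}, recorder=(20, 20))
        field = synth_icefield(spec)
        assert field.ground_truth["edge_distance_km"] == pytest.approx(12 * 3.125)

    def test_half_plane_ice_side(self):
        spec = IceGeometrySpec((40, 40), "half_plane",
                               {"edge_col": 12}, recorder=(20, 5))
        field = synth_icefield(spec)
        assert field.ground_truth["edge_distance_km"] == pytest.approx(-8 * 3.125)

    def test_uniform_open_water_flagged_undefined(self):
        field = synth_icefield(IceGeometrySpec((10, 10), "uniform",
                                               {"value": 0.0}))
        assert field.ground_truth["edge_distance_defined"] is False

    def test_disk_patch_area_consistency(self):
        spec = IceGeometrySpec((41, 41), "disk_patch", {"radius_cells": 4.0})
        field = synth_icefield(spec)
        gt = field.ground_truth
        assert gt["patch_area_km2"] == pytest.approx(gt["patch_cells"] * 3.125 ** 2)
        assert (field.concentration >= 15).sum() == gt["patch_cells"]

    def test_noise_field_range_and_determinism(self):
        spec = IceGeometrySpec((32, 32), "noise_threshold", seed=4)
        a, b = synth_icefield(spec), synth_icefield(spec)
        np.testing.assert_array_equal(a.concentration, b.concentration)
        assert a.concentration.min() >= 0 and a.concentration.max() <= 100
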