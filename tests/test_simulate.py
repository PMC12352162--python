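"""Synthetic session generator: task schedule, background noise, burst
injection and behavioral labels."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from burstdecode import simulate as sim


class TestSchedule:
    def test_single_list_structure(self):
        s = sim.generate_schedule(1, seed=0)
        assert s.n_words == 12
        assert len(s.distractor_windows) == 1
        assert s.distractor_windows[0][1] == 20.0
        assert len(s.recall_windows) == 1
        assert s.recall_windows[0][1] == 30.0

    def test_word_count_scales_with_lists(self):
        assert sim.generate_schedule(20, seed=1).n_words == 240

    def test_determinism(self):
        assert sim.generate_schedule(3, seed=5) == sim.generate_schedule(3, seed=5)

    def test_isi_within_bounds_and_epochs_abut(self):
        s = sim.generate_schedule(2, seed=2)
        for li in range(2):
            words = [w for w in s.word_events if w.list_index == li]
            for a, b in zip(words, words[1:]):
                isi = b.onset_s - (a.onset_s + a.duration_s)
                assert 0.75 <= isi <= 1.0
            d_on, d_dur = s.distractor_windows[li]
            assert d_on == pytest.approx(words[-1].onset_s + 1.6)
            assert s.recall_windows[li][0] == pytest.approx(d_on + d_dur)

    def test_invalid_list_count(self):
        with pytest.raises(ValueError):
            sim.generate_schedule(0, seed=0)


class TestBackground:
    def test_unsupported_sampling_rate(self):
        with pytest.raises(ValueError):
            sim.simulate_background(1, 1.0, 600, seed=0)

    def test_line_noise_present_and_absent(self):
        for amp, expect_peak in ((0.0, False), (10.0, True)):
            x = sim.simulate_background(1, 60.0, 500, line_amp_uv=amp, seed=3)[0]
            f, pxx = sps.welch(x, fs=500, nperseg=4096)
            i60 = np.argmin(np.abs(f - 60.0))
            neighborhood = pxx[(np.abs(f - 60) > 2) & (np.abs(f - 60) < 10)]
            is_peak = pxx[i60] > 10 * neighborhood.mean()
            assert is_peak == expect_peak

    def test_spectral_slope(self):
        x = sim.simulate_background(1, 60.0, 500, line_amp_uv=0.0, seed=4)[0]
        f, pxx = sps.welch(x, fs=500, nperseg=8192)
        sel = (f >= 2) & (f <= 100)
        slope = np.polyfit(np.log10(f[sel]), np.log10(pxx[sel]), 1)[0]
        assert -2.4 <= slope <= -1.6

    def test_channels_independent(self):
        # raw 1/f traces have few effective degrees of freedom, so whiten by
        # differencing before measuring the cross-channel correlation
        x = sim.simulate_background(2, 60.0, 500, line_amp_uv=0.0, seed=5)
        r = np.corrcoef(np.diff(x))[0, 1]
        assert abs(r) < 0.05

    def test_rms_scaling(self):
        x = sim.simulate_background(1, 10.0, 500, line_amp_uv=0.0, rms_uv=20.0,
                                    seed=6)[0]
        assert np.std(x) == pytest.approx(20.0, rel=0.05)


def _spec(rate, band="hg"):
    base = sim.HG_SPEC if band == "hg" else sim.BETA_SPEC
    from dataclasses import replace

    return replace(base, rate_hz=rate)


class TestInjectBursts:
    def test_zero_rate_leaves_signal_untouched(self):
        x = np.zeros((1, 5000))
        windows = [(1.0, 3.0, "WORD", 0, 0)]
        out, truth = sim.inject_bursts(x, 500.0, windows, _spec(0.0), seed=0)
        assert truth.empty
        assert not out.any()

    def test_poisson_count_within_band(self):
        # rate 1 Hz over 100 x 3 s windows -> ~Poisson(300)
        windows = [(3.5 * i, 3.0, "WORD", i, 0) for i in range(100)]
        x = np.zeros((1, int(3.5 * 100 * 500) + 2000))
        _, truth = sim.inject_bursts(x, 500.0, windows, _spec(1.0), seed=1)
        lo, hi = 300 - 1.96 * np.sqrt(300), 300 + 1.96 * np.sqrt(300)
        assert lo <= len(truth) <= hi

    def test_class_multiplier_scales_rate(self):
        windows = ([(4.0 * i, 3.0, "WORD", i, 0) for i in range(60)]
                   + [(4.0 * (60 + i), 3.0, "WORD", 60 + i, 1) for i in range(60)])
        x = np.zeros((1, int(4.0 * 120 * 500) + 2000))
        spec = _spec(1.0).with_multipliers({1: (3.0, 1.0)})
        _, truth = sim.inject_bursts(x, 500.0, windows, spec, seed=2)
        n0 = (truth.label == 0).sum()
        n1 = (truth.label == 1).sum()
        assert n1 / n0 == pytest.approx(3.0, rel=0.25)

    def test_truth_matches_planted_waveform(self):
        x = np.zeros((1, 5000))
        windows = [(2.0, 3.0, "WORD", 0, 0)]
        out, truth = sim.inject_bursts(x, 500.0, windows, _spec(2.0), seed=3)
        rebuilt = sim.plant_bursts(np.zeros_like(x), 500.0, truth)
        assert np.array_equal(out, rebuilt)

    def test_determinism(self):
        windows = [(1.0, 3.0, "WORD", 0, 0)]
        a = sim.inject_bursts(np.zeros((2, 4000)), 500.0, windows, _spec(2.0), seed=9)
        b = sim.inject_bursts(np.zeros((2, 4000)), 500.0, windows, _spec(2.0), seed=9)
        assert np.array_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestSimulateSession:
    def test_recall_probability_zero(self):
        s = sim.simulate_session(n_lists=2, n_channels=1, seed=0, recall_p=0.0)
        assert not s.recalled.any()
        assert (s.recall_counts == 0).all()

    def test_recalled_count_within_binomial_band(self):
        s = sim.simulate_session(n_lists=20, n_channels=1, seed=1, recall_p=0.25)
        n, p = 240, 0.25
        half = 1.96 * np.sqrt(n * p * (1 - p))
        assert n * p - half <= s.recalled.sum() <= n * p + half

    def test_counts_consistent_with_flags(self):
        s = sim.simulate_session(n_lists=3, n_channels=1, seed=2, recall_p=0.5)
        for li in range(3):
            idx = [i for i, w in enumerate(s.schedule.word_events)
                   if w.list_index == li]
            assert s.recall_counts[li] == s.recalled[idx].sum()

    def test_truth_bursts_inside_recording(self):
        s = sim.simulate_session(n_lists=2, n_channels=2, seed=3)
        assert (s.truth_bursts.onset_s >= 0).all()
        assert (s.truth_bursts.offset_s <= s.duration_s).all()

    def test_bit_reproducible(self):
        a = sim.simulate_session(n_lists=2, n_channels=2, seed=11)
        b = sim.simulate_session(n_lists=2, n_channels=2, seed=11)
        assert np.array_equal(a.signal, b.signal)
        pd.testing.assert_frame_equal(a.truth_bursts, b.truth_bursts)

    def test_roundtrip_on_disk(self, tmp_path):
        s = sim.simulate_session(n_lists=2, n_channels=2, seed=4, recall_p=0.3)
        sim.write_session(s, tmp_path)
        r = sim.read_session(tmp_path)
        assert r.fs_hz == s.fs_hz
        assert np.allclose(r.signal, s.signal, atol=1e-3)  # float32 on disk
        assert np.array_equal(r.recalled, s.recalled)
        assert np.array_equal(r.recall_counts, s.recall_counts)
        assert len(r.truth_bursts) == len(s.truth_bursts)
        assert r.schedule.n_words == s.schedule.n_words
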