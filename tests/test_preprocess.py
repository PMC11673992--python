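"""Filtering, screening, trimming, segmentation and band decomposition."""

import numpy as np
import pytest
from scipy import signal as sps

from emocsp import (ALL_BAND, CANONICAL_BANDS, SUB_BANDS, EEGRecording,
                    bandpass_fir, decompose_bands, merge_class_signal,
                    notch_filter, reference_cohort,
                    reject_artifact_components, screen_subjects,
                    segment_overlap, solve_overlap_for_count,
                    trim_head_tail)
from emocsp.preprocess import n_overlap_windows
from emocsp.simulate import DEFAULT_TRACK_PLAN, NEUTRAL, POSITIVE

FS = 250.0


def sine_recording(freqs, duration=8.0, fs=FS, n_ch=2):
    t = np.arange(int(duration * fs)) / fs
    x = sum(np.sin(2 * np.pi * f * t) for f in np.atleast_1d(freqs))
    data = np.tile(x[:, None], (1, n_ch))
    return EEGRecording(data=data, fs=fs,
                        channel_labels=[f"ch{i}" for i in range(n_ch)])


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestNotch:
    def test_50hz_suppressed(self):
        rec = sine_recording(50.0)
        out = notch_filter(rec, 50.0, q=30.0)
        assert rms(out.data) < 0.1 * rms(rec.data)

    def test_10hz_preserved(self):
        rec = sine_recording(10.0)
        out = notch_filter(rec, 50.0, q=30.0)
        assert rms(out.data) == pytest.approx(rms(rec.data), rel=0.01)

    def test_mixture_fft_oracle(self):
        rec = sine_recording([10.0, 50.0], duration=16.0)
        out = notch_filter(rec, 50.0, q=30.0)
        f, p_in = sps.periodogram(rec.data[:, 0], fs=FS)
        _, p_out = sps.periodogram(out.data[:, 0], fs=FS)
        i50 = np.argmin(np.abs(f - 50.0))
        i10 = np.argmin(np.abs(f - 10.0))
        assert 10 * np.log10(p_in[i50] / p_out[i50]) >= 20.0
        assert p_out[i10] == pytest.approx(p_in[i10], rel=0.05)

    def test_notch_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            notch_filter(sine_recording(10.0), 130.0)


class TestBandpassFIR:
    def test_stopband_tone_removed(self):
        rec = sine_recording(2.0, duration=12.0)
        out = bandpass_fir(rec, 4.0, 8.0, order=800)
        assert rms(out.data) < 0.1 * rms(rec.data)

    def test_passband_tone_preserved(self):
        rec = sine_recording(6.0, duration=12.0)
        out = bandpass_fir(rec, 4.0, 8.0, order=800)
        assert rms(out.data) == pytest.approx(rms(rec.data), rel=0.05)

    def test_edge_frequencies_by_welch_oracle(self):
        # forward-backward order-800 filter: the -6 dB (power ratio 0.25)
        # crossings of the empirical transfer sit within 0.5 Hz of the edges
        rng = np.random.default_rng(0)
        data = rng.standard_normal((int(240 * FS), 1))
        rec = EEGRecording(data=data, fs=FS, channel_labels=["c0"])
        out = bandpass_fir(rec, 0.5, 45.0, order=800)
        f, p_in = sps.welch(rec.data[:, 0], fs=FS, nperseg=8192)
        _, p_out = sps.welch(out.data[:, 0], fs=FS, nperseg=8192)
        ratio = p_out / p_in
        inside = (f > 2.0) & (f < 43.0)
        assert ratio[inside].mean() == pytest.approx(1.0, abs=0.1)
        for edge in (0.5, 45.0):
            band = (f > edge - 0.5) & (f < edge + 0.5)
            assert ratio[band].min() < 0.25 < ratio[band].max()

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            bandpass_fir(sine_recording(5.0), 8.0, 4.0)

    def test_band_filter_idempotent_in_power(self):
        rng = np.random.default_rng(3)
        rec = EEGRecording(data=rng.standard_normal((int(60 * FS), 2)),
                           fs=FS, channel_labels=["a", "b"])
        alpha = bandpass_fir(rec, 8.0, 13.0, order=800)
        again = bandpass_fir(alpha, 8.0, 13.0, order=800)
        assert rms(again.data) == pytest.approx(rms(alpha.data), rel=0.05)


class TestDecomposeBands:
    def test_canonical_five(self):
        rec = sine_recording(10.0, duration=6.0)
        out = decompose_bands(rec, CANONICAL_BANDS, order=400)
        assert set(out) == {"delta", "theta", "alpha", "beta", "gamma"}

    def test_sub_bands_four(self):
        rec = sine_recording(10.0, duration=6.0)
        out = decompose_bands(rec, SUB_BANDS, order=400)
        assert set(out) == {"beta1", "beta2", "gamma1", "gamma2"}

    def test_empty_band_list(self):
        assert decompose_bands(sine_recording(10.0), []) == {}

    def test_band_edges(self):
        names = {b.name: (b.low, b.high) for b in CANONICAL_BANDS}
        assert names["delta"] == (0.5, 4.0)
        assert names["gamma"] == (30.0, 45.0)
        assert (ALL_BAND.low, ALL_BAND.high) == (0.5, 45.0)


class TestScreening:
    def test_reference_cohort_retains_seven(self):
        retained, _ = screen_subjects(reference_cohort())
        assert len(retained) == 7

    def test_bdi_boundary(self):
        records = reference_cohort()
        high = [r for r in records if r.bdi == 22]
        assert high and all(not r.retained for r in
                            screen_subjects(records)[0] if r.bdi == 22)
        # BDI exactly 21 with good SAM scores is retained ("above 21")
        r = records[0]
        r.bdi = 21
        retained, _ = screen_subjects(records)
        assert any(x.subject_id == r.subject_id for x in retained)

    def test_reasons_reported(self):
        _, reasons = screen_subjects(reference_cohort())
        assert "Beck" in reasons[2]
        assert "motion" in reasons[15]
        assert reasons[1] == "-"

    def test_missing_fields_rejected(self):
        records = reference_cohort()
        records[0].sam_val_pos = None
        with pytest.raises(ValueError):
            screen_subjects(records)


class TestTrimMerge:
    def test_60s_track_trims_to_40(self):
        x = np.ones((int(60 * FS), 3))
        out = trim_head_tail(x, FS, 10.0, 10.0)
        assert out.shape[0] == int(40 * FS)

    def test_zero_trim_identity(self):
        x = np.arange(30.0).reshape(10, 3)
        assert np.array_equal(trim_head_tail(x, 1.0, 0.0, 0.0), x)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            trim_head_tail(np.ones((int(15 * FS), 2)), FS, 10.0, 10.0)

    def _default_session_recording(self):
        timeline, t = [], 0.0
        for cls, dur in DEFAULT_TRACK_PLAN:
            timeline.append((t, t + dur, cls))
            t += dur
        data = np.zeros((int(t * FS), 2))
        return EEGRecording(data=data, fs=FS, channel_labels=["a", "b"],
                            timeline=timeline)

    def test_music_class_merges_to_200s(self):
        rec = self._default_session_recording()
        merged = merge_class_signal(rec, POSITIVE, 10.0, 10.0)
        assert merged.shape[0] == int(200 * FS)

    def test_neutral_merges_to_120s(self):
        rec = self._default_session_recording()
        merged = merge_class_signal(rec, NEUTRAL)
        assert merged.shape[0] == int(120 * FS)

    def test_single_segment_identity(self):
        data = np.random.default_rng(0).standard_normal((500, 2))
        rec = EEGRecording(data=data, fs=FS, channel_labels=["a", "b"],
                           timeline=[(0.0, 2.0, POSITIVE)])
        assert np.array_equal(merge_class_signal(rec, POSITIVE), data)


class TestSegmentation:
    def test_200s_70pct_gives_219_windows(self):
        sig = np.zeros((int(200 * FS), 19))
        wins = segment_overlap(sig, FS, 3.0, 0.70)
        assert wins.shape == (219, 750, 19)

    def test_exact_fit_single_window(self):
        wins = segment_overlap(np.zeros((750, 2)), FS, 3.0, 0.5)
        assert wins.shape[0] == 1

    def test_6s_50pct_three_windows(self):
        wins = segment_overlap(np.zeros((1500, 1)), FS, 3.0, 0.5)
        assert wins.shape[0] == 3

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            segment_overlap(np.zeros((100, 1)), FS, 3.0, 0.5)

    def test_count_matches_bruteforce_enumeration(self, rng):
        # floor((N - L)/step) + 1 against explicit start-index enumeration
        for _ in range(50):
            N = int(rng.integers(50, 2000))
            L = int(rng.integers(10, 49))
            step = int(rng.integers(1, L + 1))
            starts = [s for s in range(0, N) if s + L <= N and s % step == 0]
            assert n_overlap_windows(N, L, step) == len(starts)

    def test_windows_are_views_of_signal(self, rng):
        sig = rng.standard_normal((1000, 2))
        wins = segment_overlap(sig, 100.0, 1.0, 0.5)
        step = 50
        for k, w in enumerate(wins):
            assert np.array_equal(w, sig[k * step:k * step + 100])


class TestSolveOverlap:
    def test_music_class_target(self):
        assert solve_overlap_for_count(50000, 750, 219) == pytest.approx(
            0.70)

    def test_target_one_is_zero_overlap(self):
        assert solve_overlap_for_count(1000, 100, 1) == 0.0

    def test_neutral_balancing_roundtrip(self):
        # 120 s of neutral data balanced up to the music-class count
        n, L, target = int(120 * FS), 750, 219
        frac = solve_overlap_for_count(n, L, target)
        wins = segment_overlap(np.zeros((n, 1)), FS, 3.0, frac)
        assert wins.shape[0] >= target
        # one step coarser would miss the target
        step = int(round(L * (1 - frac)))
        assert n_overlap_windows(n, L, step + 1) < target

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            solve_overlap_for_count(1000, 100, 10000)


class TestArtifactRejection:
    def _clean_recording(self, rng, n=2000, c=4):
        mixing = rng.standard_normal((c, c))
        src = rng.standard_normal((n, c))
        return EEGRecording(data=src @ mixing.T, fs=100.0,
                            channel_labels=[f"c{i}" for i in range(c)])

    def test_clean_input_roundtrips(self, rng):
        rec = self._clean_recording(rng)
        out = reject_artifact_components(rec, seed=0)
        for c in range(rec.data.shape[1]):
            r = np.corrcoef(rec.data[:, c], out.data[:, c])[0, 1]
            assert r > 0.99

    def test_spike_component_removed(self, rng):
        rec = self._clean_recording(rng)
        spike = np.zeros(rec.n_samples)
        spike[1000:1010] = 60.0  # high-kurtosis transient source
        rec.data += np.outer(spike, rng.standard_normal(4))
        out = reject_artifact_components(rec, seed=0)
        e_in = np.sum(rec.data[1000:1010] ** 2)
        e_out = np.sum(out.data[1000:1010] ** 2)
        assert e_out < 0.1 * e_in

    def test_single_channel_rejected(self):
        rec = EEGRecording(data=np.random.default_rng(0)
                           .standard_normal((100, 1)),
                           fs=10.0, channel_labels=["x"])
        with pytest.raises(ValueError):
            reject_artifact_components(rec)
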