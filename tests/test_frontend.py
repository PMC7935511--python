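"""Frontend: spectral subtraction, MFCC, VAD, CMS, segmenting."""

import numpy as np
import pytest
from scipy.fft import dct

from pdvoice.cohort import AudioSegment
from pdvoice.frontend import (
    FeatureMatrix,
    MfccConfig,
    apply_cms,
    compute_mfcc,
    energy_vad,
    frame_signal,
    mel_filterbank,
    spectral_subtract,
    split_segments,
)

SR = 16000


def _noise_segment(rng, seconds, level=0.01):
    x = level * rng.standard_normal(int(seconds * SR))
    return AudioSegment(x, SR)


class TestSpectralSubtraction:
    def test_matched_noise_power_drops_10db(self):
        rng = np.random.default_rng(0)
        noise = _noise_segment(rng, 3.0)
        cal = _noise_segment(rng, 5.0)
        out = spectral_subtract(noise, cal)
        p_in = np.mean(noise.samples**2)
        p_out = np.mean(out.samples**2)
        assert 10 * np.log10(p_in / p_out) >= 10.0
        assert len(out.samples) == len(noise.samples)

    def test_tone_snr_strictly_improves(self):
        rng = np.random.default_rng(1)
        t = np.arange(3 * SR) / SR
        tone = 0.1 * np.sin(2 * np.pi * 1000 * t)
        noise = 0.02 * rng.standard_normal(len(t))
        seg = AudioSegment(tone + noise, SR)
        cal = _noise_segment(rng, 5.0, level=0.02)

        def tone_band_snr(x):
            spec = np.abs(np.fft.rfft(x)) ** 2
            freqs = np.fft.rfftfreq(len(x), 1 / SR)
            sig = spec[np.abs(freqs - 1000) < 20].sum()
            rest = spec[np.abs(freqs - 1000) >= 20].sum()
            return sig / rest

        out = spectral_subtract(seg, cal)
        assert tone_band_snr(out.samples) > tone_band_snr(seg.samples)

    def test_identity_limit(self):
        """oversubtraction 0 with floor 1 leaves a strong signal untouched."""
        rng = np.random.default_rng(2)
        t = np.arange(2 * SR) / SR
        seg = AudioSegment(0.5 * np.sin(2 * np.pi * 440 * t), SR)
        cal = _noise_segment(rng, 5.0, level=1e-4)
        out = spectral_subtract(seg, cal, oversubtraction=0.0, floor=1.0)
        resid = np.sqrt(np.mean((out.samples - seg.samples) ** 2))
        assert resid < 0.01 * np.sqrt(np.mean(seg.samples**2))

    def test_rate_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            spectral_subtract(
                _noise_segment(rng, 1.0), AudioSegment(rng.standard_normal(8000), 8000)
            )


class TestMfcc:
    def test_frame_count_formula(self):
        cfg = MfccConfig.baseline_high_quality()
        seg = AudioSegment(np.random.default_rng(0).standard_normal(SR) * 0.1, SR)
        fm = compute_mfcc(seg, cfg)
        assert fm.n_frames == (SR - 320) // 160 + 1 == 99

    @pytest.mark.parametrize(
        "cfg,dim",
        [
            (MfccConfig.baseline_high_quality(), 60),
            (MfccConfig.xvector_telephone(), 24),
            (MfccConfig.xvector_high_quality(), 31),
        ],
    )
    def test_dimension_contract(self, cfg, dim):
        assert cfg.dim == dim
        rng = np.random.default_rng(1)
        seg = AudioSegment(0.1 * rng.standard_normal(cfg.sample_rate), cfg.sample_rate)
        assert compute_mfcc(seg, cfg).values.shape[1] == dim

    def test_tone_excites_matching_filter(self):
        t = np.arange(SR) / SR
        seg = AudioSegment(0.3 * np.sin(2 * np.pi * 1000 * t), SR)
        cfg = MfccConfig.baseline_high_quality()
        win = cfg.window_samples
        frames = frame_signal(seg.samples, win, cfg.step_samples)
        n_fft = 1 << (win - 1).bit_length()
        spec = np.abs(np.fft.rfft(frames * np.hamming(win), n=n_fft, axis=1)) ** 2
        fb = mel_filterbank(23, n_fft, SR, 20, 7000)
        energies = (spec @ fb.T).mean(axis=0)
        centers = np.array(
            [np.argmax(row) for row in fb]
        ) * (SR / 2) / (n_fft // 2)
        assert abs(centers[np.argmax(energies)] - 1000) == np.abs(centers - 1000).min()

    def test_silence_has_floor_energy(self):
        rng = np.random.default_rng(4)
        seg = AudioSegment(1e-6 * rng.standard_normal(SR), SR)
        fm = compute_mfcc(seg, MfccConfig.baseline_high_quality())
        assert fm.values[:, 0].std() < 0.5  # near-constant rows at the floor

    def test_dct_matches_matrix_oracle(self):
        rng = np.random.default_rng(5)
        logmel = rng.standard_normal((10, 23))
        ours = dct(logmel, type=2, norm="ortho", axis=1)
        n = 23
        k = np.arange(n)
        basis = np.cos(np.pi * (2 * k[None, :] + 1) * k[:, None] / (2 * n))
        scale = np.full(n, np.sqrt(2 / n))
        scale[0] = np.sqrt(1 / n)
        oracle = (basis * scale[:, None]) @ logmel.T
        assert np.max(np.abs(ours - oracle.T)) < 1e-10

    def test_translation_covariance(self):
        """Shifting the input by one step shifts frames by one (away from the
        delta edge padding)."""
        rng = np.random.default_rng(6)
        cfg = MfccConfig.baseline_high_quality()
        x = 0.1 * rng.standard_normal(SR)
        a = compute_mfcc(AudioSegment(x, SR), cfg)
        b = compute_mfcc(AudioSegment(x[cfg.step_samples :], SR), cfg)
        # delta-delta regression reaches 4 frames from the edges
        assert np.allclose(a.values[5 : b.n_frames - 3], b.values[4:-4], atol=1e-9)
        # static coefficients shift exactly
        assert np.allclose(a.values[1:, :20], b.values[:, :20], atol=1e-12)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            compute_mfcc(
                AudioSegment(np.zeros(100), SR), MfccConfig.baseline_high_quality()
            )


class TestVad:
    def _features(self, log_e):
        cfg = MfccConfig.baseline_high_quality()
        vals = np.column_stack([log_e, np.zeros((len(log_e), 19))])
        return FeatureMatrix(vals, np.arange(len(log_e)) * 0.01,
                             MfccConfig(add_deltas=False))

    def test_uniform_energy_all_removed(self):
        mask = energy_vad(self._features(np.full(50, 10.0)), abs_floor=1.0,
                          mean_scale=1.0)
        assert not mask.keep.any()

    def test_degenerate_threshold_keeps_all(self):
        mask = energy_vad(self._features(np.full(50, 10.0)), abs_floor=-np.inf,
                          mean_scale=0.0)
        assert mask.keep.all()

    def test_recovers_constructed_activity_mask(self):
        """Alternating speech bursts and silence: the energy mask matches the
        construction on at least 95% of frames."""
        rng = np.random.default_rng(7)
        sr = SR
        pattern = []
        truth = []
        for k in range(6):
            speech = 0.2 * rng.standard_normal(sr // 2)  # 0.5 s loud
            silence = 1e-4 * rng.standard_normal(sr // 2)
            pattern.extend([speech, silence])
            truth.extend([np.ones(sr // 2), np.zeros(sr // 2)])
        x = np.concatenate(pattern)
        truth = np.concatenate(truth)
        cfg = MfccConfig.baseline_high_quality()
        fm = compute_mfcc(AudioSegment(x, sr), cfg)
        mask = energy_vad(fm)
        win, step = cfg.window_samples, cfg.step_samples
        frame_truth = np.array(
            [truth[i * step : i * step + win].mean() > 0.5 for i in range(fm.n_frames)]
        )
        agreement = np.mean(mask.keep == frame_truth)
        assert agreement >= 0.95


class TestCms:
    def _fm(self, values):
        return FeatureMatrix(values, np.arange(len(values)) * 0.01,
                             MfccConfig(add_deltas=False))

    def test_constant_becomes_zero(self):
        out = apply_cms(self._fm(np.full((100, 5), 3.7)))
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_matches_explicit_window_mean_oracle(self):
        """Defining identity: output = input minus the exact centered window
        mean (loop oracle, shrinking at the edges)."""
        rng = np.random.default_rng(8)
        vals = rng.standard_normal((120, 4))
        out = apply_cms(self._fm(vals), window_ms=300.0)
        half = 15  # (300 ms / 10 ms step) / 2
        n = len(vals)
        for i in range(n):
            lo, hi = max(i - half, 0), min(i + half + 1, n)
            expected = vals[i] - vals[lo:hi].mean(axis=0)
            assert np.allclose(out.values[i], expected, atol=1e-12)

    def test_slow_drift_removed(self):
        """A low-frequency channel drift is attenuated by an order of
        magnitude while staying exactly shape-preserving."""
        t = np.arange(600)
        drift = np.sin(2 * np.pi * t / 600)[:, None]
        out = apply_cms(self._fm(drift))
        assert out.values.shape == drift.shape
        assert np.abs(out.values[30:-30]).max() < 0.1 * np.abs(drift).max()

    def test_linear_ramp_interior_zero(self):
        ramp = np.linspace(0, 10, 200)[:, None]
        out = apply_cms(self._fm(ramp))
        assert np.max(np.abs(out.values[20:-20])) < 1e-9


class TestSplitSegments:
    def _seg(self, seconds):
        n = int(seconds * SR)
        return AudioSegment(
            np.random.default_rng(9).standard_normal(max(n, 1)) * 0.1, SR,
            subject_id="s", session_id="s-0", task="free_speech",
        )

    def test_matched_pieces_tile_input(self):
        pieces = split_segments(self._seg(10.0), 1.0, 5.0)
        durs = [p.duration for p in pieces]
        assert all(1.0 <= d <= 5.0 + 1e-9 for d in durs)
        assert abs(sum(durs) - 10.0) < 1e-9
        total = np.concatenate([p.samples for p in pieces])
        assert len(total) == SR * 10

    def test_tiny_input_dropped(self):
        assert split_segments(self._seg(0.010), 1.0, 5.0) == []

    def test_short_remainder_merged_or_kept(self):
        pieces = split_segments(self._seg(10.5), 1.0, 5.0)
        assert abs(sum(p.duration for p in pieces) - 10.5) < 1e-9
        assert all(p.duration >= 0.025 for p in pieces)

    def test_mismatched_long_file_fragments_with_parent(self):
        pieces = split_segments(self._seg(250.0), mismatched=True)
        assert len(pieces) >= 3
        assert all(p.duration < 100.0 for p in pieces)
        parents = {p.parent_id for p in pieces}
        assert len(parents) == 1 and None not in parents

    def test_mismatched_short_file_untouched(self):
        pieces = split_segments(self._seg(30.0), mismatched=True)
        assert len(pieces) == 1
        assert pieces[0].parent_id is None
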