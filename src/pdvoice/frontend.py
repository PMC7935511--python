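"""Preprocessing and cepstral feature extraction shared by both branches.

Pipeline order for a recording: optional spectral subtraction (high-quality
channel, calibrated on the session's silence recording) -> log-energy +
MFCCs on overlapping windows -> energy VAD mask -> sliding-window cepstral
mean subtraction -> optional delta / delta-delta appension -> silent-frame
removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.fft import dct, rfft
from scipy import signal as sps

from pdvoice.cohort import AudioSegment

_PREEMPH = 0.97
_LOG_FLOOR = 1e-10


@dataclass(frozen=True)
class MfccConfig:
    """Cepstral extraction configuration.

    The baseline branch uses 20 ms windows, 23 Mel filters and 19 cepstra
    plus log-energy with deltas; the embedding (x-vector) branch uses 25 ms
    windows and more cepstra without deltas.
    """

    sample_rate: int = 16000
    window_ms: float = 20.0
    step_ms: float = 10.0
    n_filters: int = 23
    fmin_hz: float = 20.0
    fmax_hz: float = 7000.0
    n_ceps: int = 19
    include_log_energy: bool = True
    add_deltas: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.fmin_hz < self.fmax_hz <= self.sample_rate / 2):
            raise ValueError("need 0 <= fmin < fmax <= sample_rate/2")
        if self.n_ceps > self.n_filters - 1:
            # coefficient 0 is excluded (log-energy is carried separately),
            # so at most n_filters - 1 cepstra are available
            raise ValueError("n_ceps must be <= n_filters - 1")
        if self.step_ms > self.window_ms:
            raise ValueError("step must not exceed window")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_ms * self.sample_rate / 1000))

    @property
    def step_samples(self) -> int:
        return int(round(self.step_ms * self.sample_rate / 1000))

    @property
    def dim(self) -> int:
        static = self.n_ceps + (1 if self.include_log_energy else 0)
        return static * (3 if self.add_deltas else 1)

    # --- presets mirroring the two study channels and branches -------------

    @classmethod
    def baseline_high_quality(cls, sample_rate: int = 16000) -> "MfccConfig":
        return cls(sample_rate=sample_rate, window_ms=20, n_filters=23,
                   fmin_hz=20, fmax_hz=7000, n_ceps=19, add_deltas=True)

    @classmethod
    def baseline_telephone(cls) -> "MfccConfig":
        return cls(sample_rate=8000, window_ms=20, n_filters=23,
                   fmin_hz=300, fmax_hz=3700, n_ceps=19, add_deltas=True)

    @classmethod
    def xvector_telephone(cls) -> "MfccConfig":
        return cls(sample_rate=8000, window_ms=25, n_filters=24,
                   fmin_hz=20, fmax_hz=3700, n_ceps=23, add_deltas=False)

    @classmethod
    def xvector_high_quality(cls) -> "MfccConfig":
        return cls(sample_rate=16000, window_ms=25, n_filters=31,
                   fmin_hz=20, fmax_hz=7600, n_ceps=30, add_deltas=False)


@dataclass
class FeatureMatrix:
    """frames x dim acoustic features with extraction provenance."""

    values: np.ndarray
    frame_times: np.ndarray
    config: MfccConfig
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class VadMask:
    keep: np.ndarray  # boolean per frame


# ---------------------------------------------------------------------------
# spectral subtraction
# ---------------------------------------------------------------------------


def spectral_subtract(
    segment: AudioSegment,
    calibration: AudioSegment,
    oversubtraction: float = 2.0,
    floor: float = 0.02,
    frame_ms: float = 32.0,
    ) -> AudioSegment:
    """Magnitude-domain stationary-noise removal.

    The noise magnitude spectrum is the mean short-time magnitude of the
    calibration-silence recording.  Each short-time magnitude of the input
    has ``oversubtraction`` times that spectrum subtracted and is floored at
    ``floor`` times it; phase is preserved and the output has the input's
    length.
    """
    if segment.sample_rate != calibration.sample_rate:
        raise ValueError("segment and calibration sample rates differ")
    sr = segment.sample_rate
    nperseg = int(round(frame_ms * sr / 1000))
    if len(calibration.samples) < nperseg:
        raise ValueError("calibration shorter than one analysis frame")
    noverlap = nperseg // 2
    win = sps.get_window("hann", nperseg)

    _, _, cal_stft = sps.stft(
        calibration.samples, fs=sr, window=win, nperseg=nperseg, noverlap=noverlap
    )
    noise_mag = np.abs(cal_stft).mean(axis=1, keepdims=True)

    _, _, X = sps.stft(
        segment.samples, fs=sr, window=win, nperseg=nperseg, noverlap=noverlap
    )
    mag = np.abs(X)
    phase = np.angle(X)
    cleaned = np.maximum(mag - oversubtraction * noise_mag, floor * noise_mag)
    _, y = sps.istft(
        cleaned * np.exp(1j * phase), fs=sr, window=win, nperseg=nperseg, noverlap=noverlap
    )
    n = len(segment.samples)
    if len(y) < n:
        y = np.pad(y, (0, n - len(y)))
    return segment.replace_samples(y[:n])


# ---------------------------------------------------------------------------
# MFCC extraction
# ---------------------------------------------------------------------------


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, sample_rate: int,
                   fmin: float, fmax: float) -> np.ndarray:
    """Triangular Mel filterbank on rfft bins: (n_filters, n_fft//2 + 1)."""
    mels = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_filters + 2)
    hz = _mel_to_hz(mels)
    bins = np.linspace(0, sample_rate / 2, n_fft // 2 + 1)
    fb = np.zeros((n_filters, len(bins)))
    for i in range(n_filters):
        lo, center, hi = hz[i], hz[i + 1], hz[i + 2]
        up = (bins - lo) / max(center - lo, 1e-9)
        down = (hi - bins) / max(hi - center, 1e-9)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def frame_signal(x: np.ndarray, window: int, step: int) -> np.ndarray:
    """Frames as rows: floor((n - window)/step) + 1 of them (n >= window)."""
    n = len(x)
    if n < window:
        raise ValueError("signal shorter than one analysis window")
    n_frames = (n - window) // step + 1
    idx = np.arange(window)[None, :] + step * np.arange(n_frames)[:, None]
    return x[idx]


def compute_mfcc(segment: AudioSegment, config: MfccConfig) -> FeatureMatrix:
    """Log-energy + MFCCs (DCT-II orthonormal, coefficient 0 excluded).

    Per frame: log-energy on the raw frame; pre-emphasis, Hamming window,
    power spectrum, triangular Mel filterbank, log, DCT keeping coefficients
    1..n_ceps.  Deltas and delta-deltas (regression over +/-2 frames) are
    appended when ``config.add_deltas``.
    """
    if config.sample_rate != segment.sample_rate:
        raise ValueError("config sample_rate does not match segment")
    win, step = config.window_samples, config.step_samples
    frames = frame_signal(segment.samples, win, step)

    # log-energy on the raw frame, at 16-bit full scale so that conventional
    # VAD floors (natural-log units) apply to [-1, 1] float waveforms
    log_e = np.log(np.maximum(np.sum((32768.0 * frames) ** 2, axis=1), _LOG_FLOOR))

    pre = frames.copy()
    pre[:, 1:] -= _PREEMPH * frames[:, :-1]
    pre[:, 0] *= 1.0 - _PREEMPH
    hamming = np.hamming(win)
    n_fft = 1 << (win - 1).bit_length()
    spec = np.abs(rfft(pre * hamming, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(config.n_filters, n_fft, config.sample_rate,
                        config.fmin_hz, config.fmax_hz)
    logmel = np.log(np.maximum(spec @ fb.T, _LOG_FLOOR))
    ceps = dct(logmel, type=2, norm="ortho", axis=1)[:, 1 : config.n_ceps + 1]

    cols = [log_e[:, None], ceps] if config.include_log_energy else [ceps]
    static = np.hstack(cols)
    values = np.hstack([static, *_deltas(static)]) if config.add_deltas else static
    frame_times = (step * np.arange(len(frames)) + win / 2) / config.sample_rate
    prov = {"subject_id": segment.subject_id, "session_id": segment.session_id,
            "task": segment.task}
    return FeatureMatrix(values, frame_times, config, prov)


def _deltas(static: np.ndarray, n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """First and second temporal derivatives by +/-n-frame regression."""

    def one(x: np.ndarray) -> np.ndarray:
        denom = 2 * sum(k * k for k in range(1, n + 1))
        padded = np.pad(x, ((n, n), (0, 0)), mode="edge")
        out = np.zeros_like(x)
        for k in range(1, n + 1):
            out += k * (padded[n + k : n + k + len(x)] - padded[n - k : n - k + len(x)])
        return out / denom

    d = one(static)
    return d, one(d)


def add_deltas(features: FeatureMatrix) -> FeatureMatrix:
    """Append delta and delta-delta columns to a static FeatureMatrix."""
    d, dd = _deltas(features.values)
    cfg = replace(features.config, add_deltas=True)
    return FeatureMatrix(np.hstack([features.values, d, dd]),
                         features.frame_times, cfg, dict(features.provenance))


# ---------------------------------------------------------------------------
# VAD and CMS
# ---------------------------------------------------------------------------


def energy_vad(features: FeatureMatrix, abs_floor: float = 5.0,
               mean_scale: float = 0.5) -> VadMask:
    """Keep a frame iff log-energy > abs_floor + mean_scale * mean log-energy."""
    if not features.config.include_log_energy:
        raise ValueError("energy VAD requires the log-energy column")
    log_e = features.values[:, 0]
    thresh = abs_floor + mean_scale * log_e.mean()
    return VadMask(keep=log_e > thresh)


def apply_cms(features: FeatureMatrix, window_ms: float = 300.0) -> FeatureMatrix:
    """Sliding-window cepstral mean subtraction.

    A centered running mean over ``window_ms`` (shrinking at the edges) is
    subtracted from every column.  Intended for static features, before
    deltas are computed.
    """
    step_ms = features.config.step_ms
    half = max(int(round(window_ms / step_ms)) // 2, 0)
    x = features.values
    n = len(x)
    cum = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    means = (cum[hi] - cum[lo]) / (hi - lo)[:, None]
    return FeatureMatrix(x - means, features.frame_times, features.config,
                         dict(features.provenance))


def extract_features(
    segment: AudioSegment,
    config: MfccConfig,
    calibration: AudioSegment | None = None,
    vad_abs_floor: float = 5.0,
    vad_mean_scale: float = 0.5,
    cms_window_ms: float = 300.0,
) -> FeatureMatrix:
    """Full frontend for one segment: (denoise) -> MFCC -> VAD -> CMS -> deltas.

    Returns kept (voiced) frames only.  The VAD threshold is computed on raw
    log-energies; CMS is applied to static features before deltas.
    """
    if calibration is not None:
        segment = spectral_subtract(segment, calibration)
    static_cfg = replace(config, add_deltas=False)
    feats = compute_mfcc(segment, static_cfg)
    mask = energy_vad(feats, vad_abs_floor, vad_mean_scale)
    feats = apply_cms(feats, cms_window_ms)
    if config.add_deltas:
        feats = add_deltas(feats)
    kept = feats.values[mask.keep]
    return FeatureMatrix(kept, feats.frame_times[mask.keep], feats.config,
                         dict(feats.provenance))


# ---------------------------------------------------------------------------
# segmenting
# ---------------------------------------------------------------------------

MIN_SEGMENT_S = 0.025
MAX_SEGMENT_S = 100.0


def split_segments(
    segment: AudioSegment,
    min_s: float = 1.0,
    max_s: float = 5.0,
    mismatched: bool = False,
) -> list[AudioSegment]:
    """Tile a recording into non-overlapping pieces.

    Matched mode cuts pieces of ``max_s`` with a final remainder merged into
    the previous piece when the merge stays within ``max_s``, kept alone if
    at least 25 ms, dropped otherwise.  Mismatched mode keeps any duration in
    [25 ms, 100 s], fragmenting longer inputs into equal pieces < 100 s that
    share a parent id (their embeddings are averaged downstream).
    """
    sr = segment.sample_rate
    x = segment.samples
    dur = segment.duration
    parent = f"{segment.subject_id}:{segment.session_id}:{segment.task}"

    def piece(lo: int, hi: int, i: int, flag_parent: bool) -> AudioSegment:
        p = segment.replace_samples(x[lo:hi])
        p.parent_id = parent if flag_parent else None
        return p

    if mismatched:
        if dur < MIN_SEGMENT_S:
            return []
        if dur <= MAX_SEGMENT_S:
            return [piece(0, len(x), 0, False)]
        k = int(np.ceil(dur / MAX_SEGMENT_S))
        bounds = np.linspace(0, len(x), k + 1).astype(int)
        return [piece(bounds[i], bounds[i + 1], i, True) for i in range(k)]

    step = int(round(max_s * sr))
    min_n = int(round(min_s * sr))
    cuts = list(range(0, len(x), step))
    spans = [(lo, min(lo + step, len(x))) for lo in cuts]
    if len(spans) >= 2 and spans[-1][1] - spans[-1][0] < min_n:
        lo_prev, hi_prev = spans[-2]
        if (spans[-1][1] - lo_prev) <= int(round(max_s * sr)) + 1:
            spans = spans[:-2] + [(lo_prev, spans[-1][1])]
    out = []
    for lo, hi in spans:
        if (hi - lo) / sr >= MIN_SEGMENT_S:
            if (hi - lo) / sr >= min_s or len(spans) == 1 or (lo, hi) == spans[-1]:
                out.append(piece(lo, hi, len(out), False))
    return out
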