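"""Seeded synthetic voice cohorts.

The clinical recordings this pipeline was designed for cannot be shipped, so
experiments run on a source-filter voice synthesizer: an impulse-train /
aspiration-noise excitation passed through a cascade of formant resonators.
Subject identity lives in the base parameters (pitch, formant frequencies,
aspiration level), drawn per subject from gender-specific distributions.
The patient class is a deterministic shift of those parameters — reduced
formant dispersion, raised aspiration noise, flattened pitch modulation —
a crude hypokinetic-dysarthria proxy whose magnitude (``effect_size``) is
expressed in units of the subject-level standard deviation.

Sessions perturb a linear channel (gain and spectral tilt) and add a
stationary noise floor; each session also yields a 5 s calibration-silence
recording of that noise floor alone, used downstream for spectral
subtraction.  The telephone channel band-limits to 300–3400 Hz and resamples
to 8 kHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import signal

Task = Literal["repetition", "free_speech", "ddk", "reading"]
TASKS: tuple[str, ...] = ("repetition", "free_speech", "ddk", "reading")

#: per-gender mean source-filter parameters: fundamental (Hz), formants (Hz)
_BASE_PARAMS = {
    "M": {"f0": 120.0, "formants": (500.0, 1500.0, 2500.0, 3500.0)},
    "F": {"f0": 210.0, "formants": (590.0, 1770.0, 2950.0, 4130.0)},
}
_ASPIRATION_LEVEL = 0.05  # noise-to-pulse amplitude ratio at effect 0
_PITCH_MOD_SD = 0.06      # relative SD of the slow f0 modulation
_NOISE_FLOOR = 2.0e-3     # channel noise RMS relative to full scale
_CALIBRATION_S = 5.0


@dataclass(frozen=True)
class SynthCohortConfig:
    """Parameters of a synthetic cohort.

    ``effect_size`` is the class separation applied to the per-subject
    envelope parameters, in units of ``subject_sd``; 0 means the class label
    carries no acoustic signal.
    """

    n_pd: int
    n_hc: int
    gender: str = "M"
    sessions_per_subject: int = 1
    tasks: tuple[str, ...] = ("free_speech",)
    task_duration_s: float = 10.0
    channel: str = "high_quality"
    sample_rate: int = 16000
    effect_size: float = 1.0
    subject_sd: float = 0.08
    session_sd: float = 0.05
    frame_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd < 0 or self.n_hc < 0:
            raise ValueError("subject counts must be non-negative")
        if self.sessions_per_subject < 1:
            raise ValueError("sessions_per_subject must be >= 1")
        if self.task_duration_s <= 0:
            raise ValueError("task_duration_s must be positive")
        if self.gender not in ("M", "F"):
            raise ValueError(f"unknown gender {self.gender!r}")
        for t in self.tasks:
            if t not in TASKS:
                raise ValueError(f"unknown task {t!r}")
        if self.channel == "telephone":
            if self.sample_rate != 8000:
                raise ValueError("telephone channel requires sample_rate=8000")
        elif self.channel == "high_quality":
            if self.sample_rate not in (16000, 96000):
                raise ValueError(
                    "high_quality channel requires sample_rate in {16000, 96000}"
                )
        else:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    label: str  # "PD" | "HC"
    gender: str
    sessions: tuple[str, ...]


@dataclass
class AudioSegment:
    """A labeled mono waveform with provenance."""

    samples: np.ndarray
    sample_rate: int
    subject_id: str | None = None
    session_id: str | None = None
    task: str | None = None
    is_calibration_silence: bool = False
    parent_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or len(self.samples) < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def replace_samples(self, samples: np.ndarray) -> "AudioSegment":
        return AudioSegment(
            samples=samples,
            sample_rate=self.sample_rate,
            subject_id=self.subject_id,
            session_id=self.session_id,
            task=self.task,
            is_calibration_silence=self.is_calibration_silence,
            parent_id=self.parent_id,
        )


@dataclass
class NoiseBank:
    """Synthetic corruption sources for data augmentation."""

    rirs: list[np.ndarray]
    noises: list[AudioSegment]
    musics: list[AudioSegment]
    babble_voices: list[AudioSegment]
    sample_rate: int


# ---------------------------------------------------------------------------
# voice synthesis
# ---------------------------------------------------------------------------


def _smooth_noise(rng: np.random.Generator, n: int, cutoff_hz: float, sr: int) -> np.ndarray:
    """Unit-variance low-pass noise, used for slow parameter modulation."""
    x = rng.standard_normal(n)
    # 2nd-order Butterworth; normalize variance after filtering
    b, a = signal.butter(2, min(cutoff_hz / (sr / 2), 0.99))
    y = signal.lfilter(b, a, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _formant_filter(x: np.ndarray, formants: Sequence[float], bandwidths: Sequence[float], sr: int) -> np.ndarray:
    y = x
    for f, bw in zip(formants, bandwidths):
        if f >= sr / 2:  # resonance above Nyquist: skip
            continue
        r = math.exp(-math.pi * bw / sr)
        theta = 2 * math.pi * f / sr
        a = [1.0, -2 * r * math.cos(theta), r * r]
        # unit gain at the resonance peak
        y = signal.lfilter([1 - r], a, y)
    return y


def _synth_voice(
    rng: np.random.Generator,
    sr: int,
    duration_s: float,
    f0: float,
    formants: Sequence[float],
    aspiration: float,
    pitch_mod_sd: float,
    frame_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a voiced utterance with pauses.

    Returns (samples, voiced_mask) where voiced_mask marks speech activity at
    sample resolution (ground truth for VAD checks).
    """
    n = int(round(duration_s * sr))
    # slow f0 modulation (prosody proxy)
    f0_track = f0 * np.exp(pitch_mod_sd * _smooth_noise(rng, n, 3.0, sr))
    phase = np.cumsum(f0_track / sr)
    pulses = np.zeros(n)
    pulse_idx = np.nonzero(np.diff(np.floor(phase)) > 0)[0] + 1
    pulses[pulse_idx] = 1.0
    excitation = pulses + aspiration * rng.standard_normal(n)
    # glottal-ish spectral slope
    excitation = signal.lfilter([1.0], [1.0, -0.9], excitation)
    bandwidths = [80.0 + 0.03 * f for f in formants]
    voice = _formant_filter(excitation, formants, bandwidths, sr)
    # slow amplitude modulation (frame-level variability)
    voice *= np.exp(frame_sd * _smooth_noise(rng, n, 8.0, sr))
    # speech bursts separated by pauses
    mask = np.zeros(n, dtype=bool)
    t = 0
    while t < n:
        burst = int(rng.uniform(0.5, 1.2) * sr)
        gap = int(rng.uniform(0.15, 0.35) * sr)
        mask[t : min(t + burst, n)] = True
        t += burst + gap
    edge = int(0.01 * sr)
    env = np.convolve(mask.astype(float), np.ones(2 * edge + 1) / (2 * edge + 1), mode="same")
    voice *= env
    rms = np.sqrt(np.mean(voice[mask] ** 2)) if mask.any() else 1.0
    voice *= 0.1 / max(rms, 1e-12)
    return voice, mask


def _channel_noise(rng: np.random.Generator, n: int, level: float) -> np.ndarray:
    """Stationary colored noise floor (the calibration-silence content)."""
    x = rng.standard_normal(n)
    y = signal.lfilter([1.0], [1.0, -0.7], x)
    return level * y / y.std()


def _apply_channel(
    x: np.ndarray, gain: float, tilt: float, sr_in: int, channel: str, sr_out: int
) -> np.ndarray:
    y = gain * signal.lfilter([1.0, -tilt], [1.0], x)
    if channel == "telephone":
        sos = signal.butter(4, [300.0, 3400.0], btype="band", fs=sr_in, output="sos")
        y = signal.sosfilt(sos, y)
        y = signal.resample_poly(y, sr_out, sr_in)
    elif sr_out != sr_in:
        y = signal.resample_poly(y, sr_out, sr_in)
    peak = np.max(np.abs(y))
    if peak > 0.99:
        y = y * (0.99 / peak)
    return y


def _subject_params(
    rng: np.random.Generator, cfg: SynthCohortConfig, label: str
) -> dict:
    base = _BASE_PARAMS[cfg.gender]
    sd = cfg.subject_sd
    shift = cfg.effect_size * sd if label == "PD" else 0.0
    f0 = base["f0"] * math.exp(sd * rng.standard_normal())
    # per-subject formant dispersion around the gender template; patients get
    # the dispersion compressed (formants pulled toward their mean)
    mean_f = float(np.mean(base["formants"]))
    disp = math.exp(sd * rng.standard_normal() - shift)
    formants = [mean_f + (f - mean_f) * disp for f in base["formants"]]
    # individual formant jitter
    formants = [f * math.exp(0.3 * sd * rng.standard_normal()) for f in formants]
    aspiration = _ASPIRATION_LEVEL * math.exp(sd * rng.standard_normal() + 2.0 * shift)
    pitch_mod = _PITCH_MOD_SD * math.exp(sd * rng.standard_normal() - shift)
    return {
        "f0": f0,
        "formants": formants,
        "aspiration": aspiration,
        "pitch_mod": pitch_mod,
    }


def generate_cohort(
    config: SynthCohortConfig,
) -> tuple[list[SubjectRecord], list[AudioSegment]]:
    """Generate a synthetic cohort: subject records plus audio segments.

    Each subject has ``sessions_per_subject`` sessions; each session carries
    one segment per task plus one 5 s calibration-silence segment.
    Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    synth_sr = 16000 if config.channel == "telephone" else config.sample_rate
    subjects: list[SubjectRecord] = []
    segments: list[AudioSegment] = []
    labels = ["PD"] * config.n_pd + ["HC"] * config.n_hc
    for i, label in enumerate(labels):
        sid = f"{label.lower()}{i:03d}"
        params = _subject_params(rng, config, label)
        session_ids = []
        for s in range(config.sessions_per_subject):
            sess = f"{sid}-s{s}"
            session_ids.append(sess)
            gain = math.exp(config.session_sd * rng.standard_normal())
            tilt = float(np.clip(config.session_sd * rng.standard_normal(), -0.5, 0.5))
            for task in config.tasks:
                voice, _ = _synth_voice(
                    rng,
                    synth_sr,
                    config.task_duration_s,
                    params["f0"],
                    params["formants"],
                    params["aspiration"],
                    params["pitch_mod"],
                    config.frame_sd,
                )
                voice = voice + _channel_noise(rng, len(voice), _NOISE_FLOOR)
                out = _apply_channel(
                    voice, gain, tilt, synth_sr, config.channel, config.sample_rate
                )
                segments.append(
                    AudioSegment(out, config.sample_rate, sid, sess, task)
                )
            sil = _channel_noise(rng, int(_CALIBRATION_S * synth_sr), _NOISE_FLOOR)
            sil = _apply_channel(
                sil, gain, tilt, synth_sr, config.channel, config.sample_rate
            )
            segments.append(
                AudioSegment(
                    sil, config.sample_rate, sid, sess, None, is_calibration_silence=True
                )
            )
        subjects.append(SubjectRecord(sid, label, config.gender, tuple(session_ids)))
    return subjects, segments


# ---------------------------------------------------------------------------
# noise bank
# ---------------------------------------------------------------------------


def generate_noise_bank(sample_rate: int, seed: int = 0) -> NoiseBank:
    """Synthetic surrogate for an augmentation noise corpus.

    Colored-noise bursts, harmonic tone mixtures (music surrogates),
    speech-like babble voices, and exponentially decaying room impulse
    responses. Deterministic in ``seed``.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    rng = np.random.default_rng(seed)
    sr = sample_rate

    noises = []
    for _ in range(8):
        n = int(rng.uniform(1.5, 4.0) * sr)
        x = rng.standard_normal(n)
        # random one-pole coloration
        a = rng.uniform(-0.9, 0.9)
        x = signal.lfilter([1.0], [1.0, a], x)
        x = 0.3 * x / np.max(np.abs(x))
        noises.append(AudioSegment(x, sr))

    musics = []
    for _ in range(4):
        n = int(rng.uniform(3.0, 6.0) * sr)
        t = np.arange(n) / sr
        x = np.zeros(n)
        root = rng.uniform(100, 400)
        for k in (1.0, 1.25, 1.5, 2.0):
            for h in (1, 2, 3):
                x += rng.uniform(0.2, 1.0) * np.sin(
                    2 * np.pi * root * k * h * t + rng.uniform(0, 2 * np.pi)
                )
        # slow tremolo so it is not perfectly stationary
        x *= 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.5, 2.0) * t)
        x = 0.3 * x / np.max(np.abs(x))
        musics.append(AudioSegment(x, sr))

    babble = []
    base_synth_sr = max(sr, 8000)
    for _ in range(8):
        f0 = rng.uniform(90, 250)
        formants = [rng.uniform(300, 800), rng.uniform(900, 2000), rng.uniform(2100, 3400)]
        v, _ = _synth_voice(
            rng, base_synth_sr, rng.uniform(2.0, 4.0), f0, formants,
            aspiration=0.1, pitch_mod_sd=0.08, frame_sd=0.2,
        )
        if base_synth_sr != sr:
            v = signal.resample_poly(v, sr, base_synth_sr)
        peak = np.max(np.abs(v))
        if peak > 0:
            v = 0.3 * v / peak
        babble.append(AudioSegment(v, sr))

    rirs = []
    for _ in range(4):
        t60 = rng.uniform(0.15, 0.6)
        n = int(t60 * 1.5 * sr)
        decay = np.exp(-6.9 * np.arange(n) / (t60 * sr))
        h = rng.standard_normal(n) * decay
        h[0] = 1.0  # direct path
        h /= np.sqrt(np.sum(h**2))
        rirs.append(h)

    return NoiseBank(rirs=rirs, noises=noises, musics=musics, babble_voices=babble, sample_rate=sr)


def resample_bank(bank: NoiseBank, sample_rate: int) -> NoiseBank:
    """Resample every bank entry to a new rate (e.g. 16 kHz -> 8 kHz)."""
    if sample_rate == bank.sample_rate:
        return bank

    def _rs(x: np.ndarray) -> np.ndarray:
        return signal.resample_poly(x, sample_rate, bank.sample_rate)

    return NoiseBank(
        rirs=[_rs(h) for h in bank.rirs],
        noises=[AudioSegment(_rs(s.samples), sample_rate) for s in bank.noises],
        musics=[AudioSegment(_rs(s.samples), sample_rate) for s in bank.musics],
        babble_voices=[AudioSegment(_rs(s.samples), sample_rate) for s in bank.babble_voices],
        sample_rate=sample_rate,
    )


# ---------------------------------------------------------------------------
# PLDA population sampler
# ---------------------------------------------------------------------------


def generate_plda_population(
    n_classes: int,
    per_class: int,
    dim: int,
    F_rank: int,
    G_rank: int,
    seed: int = 0,
    *,
    f_scale: float = 3.0,
    g_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Sample vectors from the PLDA generative model.

    ``x = mu + F h + G w + eps`` with class latent ``h`` (one draw per class),
    sample latent ``w`` and diagonal-Gaussian residual ``eps``.  Returns
    (vectors, integer labels, true parameters).
    """
    if F_rank + G_rank > dim:
        raise ValueError("F_rank + G_rank must not exceed dim")
    rng = np.random.default_rng(seed)
    mu = rng.normal(0, 1, dim)
    F = f_scale * rng.normal(0, 1, (dim, F_rank)) / max(np.sqrt(F_rank), 1)
    G = g_scale * rng.normal(0, 1, (dim, G_rank)) / max(np.sqrt(G_rank), 1)
    sigma = rng.uniform(0.2, 0.8, dim)
    X = np.empty((n_classes * per_class, dim))
    y = np.repeat(np.arange(n_classes), per_class)
    for c in range(n_classes):
        h = rng.standard_normal(F_rank)
        base = mu + F @ h
        for j in range(per_class):
            w = rng.standard_normal(G_rank)
            eps = rng.normal(0, np.sqrt(sigma))
            X[c * per_class + j] = base + G @ w + eps
    params = {"mu": mu, "F": F, "G": G, "Sigma": sigma}
    return X, y, params


# ---------------------------------------------------------------------------
# WAV + manifest export
# ---------------------------------------------------------------------------


def write_cohort(
    subjects: list[SubjectRecord],
    segments: list[AudioSegment],
    out_dir: str | Path,
) -> Path:
    """Write segments as 16-bit PCM WAV plus a TSV manifest; returns manifest path."""
    from scipy.io import wavfile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = {s.subject_id: s.label for s in subjects}
    genders = {s.subject_id: s.gender for s in subjects}
    rows = ["subject_id\tlabel\tgender\tsession\ttask\tpath"]
    for seg in segments:
        task = "calibration" if seg.is_calibration_silence else (seg.task or "unknown")
        name = f"{seg.subject_id}_{seg.session_id}_{task}.wav"
        pcm = np.clip(seg.samples, -1.0, 1.0)
        wavfile.write(out / name, seg.sample_rate, (pcm * 32767).astype(np.int16))
        rows.append(
            "\t".join(
                [
                    str(seg.subject_id),
                    labels.get(seg.subject_id, "?"),
                    genders.get(seg.subject_id, "?"),
                    str(seg.session_id),
                    task,
                    name,
                ]
            )
        )
    manifest = out / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
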