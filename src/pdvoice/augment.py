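"""Training-data augmentation: reverberation, noise, music, babble.

Each training segment gets four corrupted copies (one per kind); two of the
four are picked uniformly at random and appended to the training set,
tripling its size.  Test-side audio is never augmented — the evaluation
pipeline only ever calls this on training subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from pdvoice.cohort import AudioSegment, NoiseBank

KINDS = ("reverb", "noise", "music", "babble")


@dataclass(frozen=True)
class AugmentPolicy:
    snr_ranges: dict = field(
        default_factory=lambda: {
            "noise": (0.0, 15.0),
            "music": (5.0, 15.0),
            "babble": (5.0, 15.0),
        }
    )
    noise_insertion_period_s: float = 1.0
    babble_count_range: tuple[int, int] = (3, 7)
    keep_copies: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.keep_copies <= 4):
            raise ValueError("keep_copies must be within [0, 4]")
        lo, hi = self.babble_count_range
        if not (3 <= lo <= hi <= 7):
            raise ValueError("babble_count_range must lie within [3, 7]")


def _normalize(x: np.ndarray, peak: float) -> np.ndarray:
    m = np.max(np.abs(x))
    if m > 0:
        x = x * (peak / m)
    return np.clip(x, -1.0, 1.0)


def reverberate(segment: AudioSegment, rir: np.ndarray) -> AudioSegment:
    """Convolve with a room impulse response; keep length and input peak."""
    rir = np.asarray(rir, dtype=float)
    wet = fftconvolve(segment.samples, rir)[: len(segment.samples)]
    peak_in = np.max(np.abs(segment.samples))
    return segment.replace_samples(_normalize(wet, peak_in if peak_in > 0 else 1.0))


def _tile_to(x: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Random-offset excerpt of x, tiled if shorter than n."""
    if len(x) >= n:
        start = rng.integers(0, len(x) - n + 1)
        return x[start : start + n]
    reps = int(np.ceil(n / len(x)))
    return np.tile(x, reps)[:n]


def _scale_to_snr(signal_power: float, noise: np.ndarray, snr_db: float) -> np.ndarray:
    p_noise = np.mean(noise**2)
    if p_noise <= 0:
        return noise
    target = signal_power / (10.0 ** (snr_db / 10.0))
    return noise * np.sqrt(target / p_noise)


def add_noise(
    segment: AudioSegment,
    bank: NoiseBank,
    kind: str,
    policy: AugmentPolicy | None = None,
    rng: np.random.Generator | None = None,
) -> AudioSegment:
    """Additive corruption at an SNR drawn from the policy range.

    ``noise`` re-draws a bank excerpt every insertion period (1 s) at one
    per-copy SNR; ``music`` adds a single continuous excerpt; ``babble`` sums
    3-7 bank voices and adds the mixture.
    """
    policy = policy or AugmentPolicy()
    rng = rng if rng is not None else np.random.default_rng(policy.seed)
    if bank.sample_rate != segment.sample_rate:
        raise ValueError("noise bank sample rate does not match the segment")
    x = segment.samples
    n = len(x)
    sr = segment.sample_rate
    p_sig = float(np.mean(x**2))
    snr_lo, snr_hi = policy.snr_ranges[kind if kind in policy.snr_ranges else "noise"]
    snr = float(rng.uniform(snr_lo, snr_hi))

    if kind == "noise":
        if not bank.noises:
            raise ValueError("empty noise bank")
        hop = max(int(policy.noise_insertion_period_s * sr), 1)
        noise = np.zeros(n)
        for start in range(0, n, hop):
            src = bank.noises[rng.integers(0, len(bank.noises))].samples
            stop = min(start + hop, n)
            noise[start:stop] = _tile_to(src, stop - start, rng)
    elif kind == "music":
        if not bank.musics:
            raise ValueError("empty music bank")
        src = bank.musics[rng.integers(0, len(bank.musics))].samples
        noise = _tile_to(src, n, rng)
    elif kind == "babble":
        if not bank.babble_voices:
            raise ValueError("empty babble bank")
        lo, hi = policy.babble_count_range
        k = int(rng.integers(lo, hi + 1))
        noise = np.zeros(n)
        for _ in range(k):
            v = bank.babble_voices[rng.integers(0, len(bank.babble_voices))].samples
            noise += _tile_to(v, n, rng)
    else:
        raise ValueError(f"unknown corruption kind {kind!r}")

    out = x + _scale_to_snr(p_sig, noise, snr)
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out = out / peak
    return segment.replace_samples(out)


def augment_dataset(
    segments: list[AudioSegment],
    bank: NoiseBank,
    policy: AugmentPolicy | None = None,
) -> list[AudioSegment]:
    """Originals plus ``keep_copies`` randomly chosen corrupted copies each.

    With the default ``keep_copies=2`` the output has exactly three times as
    many segments as the input.  Deterministic in ``policy.seed``.
    """
    if not segments:
        raise ValueError("no segments to augment")
    policy = policy or AugmentPolicy()
    rng = np.random.default_rng(policy.seed)
    out: list[AudioSegment] = []
    for seg in segments:
        out.append(seg)
        if policy.keep_copies == 0:
            continue
        copies = {
            "reverb": reverberate(seg, bank.rirs[rng.integers(0, len(bank.rirs))]),
            "noise": add_noise(seg, bank, "noise", policy, rng),
            "music": add_noise(seg, bank, "music", policy, rng),
            "babble": add_noise(seg, bank, "babble", policy, rng),
        }
        picked = rng.choice(len(KINDS), size=policy.keep_copies, replace=False)
        for i in sorted(picked):
            out.append(copies[KINDS[i]])
    return out
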