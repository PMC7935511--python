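"""Shared fixtures: small synthetic cohorts and a trained toy embedding net."""

from __future__ import annotations

import numpy as np
import pytest

from pdvoice.cohort import SynthCohortConfig, generate_cohort, generate_noise_bank
from pdvoice.frontend import MfccConfig, extract_features
from pdvoice.tdnn import TdnnConfig, build_tdnn, make_training_chunks, train_tdnn


@pytest.fixture(scope="session")
def small_cohort():
    """4 + 4 subjects, one 6 s free-speech recording each, clear class effect."""
    cfg = SynthCohortConfig(
        n_pd=4, n_hc=4, tasks=("free_speech",), task_duration_s=6.0,
        effect_size=3.0, seed=7,
    )
    subjects, segments = generate_cohort(cfg)
    return cfg, subjects, segments


@pytest.fixture(scope="session")
def noise_bank_16k():
    return generate_noise_bank(16000, seed=5)


@pytest.fixture(scope="session")
def speaker_setup():
    """8 synthetic speakers with 20 training chunks each, plus one held out."""
    cfg = SynthCohortConfig(
        n_pd=0, n_hc=9, tasks=("free_speech",), task_duration_s=12.0,
        effect_size=0.0, seed=11,
    )
    _, segments = generate_cohort(cfg)
    mfcc = MfccConfig.xvector_high_quality()
    by_speaker: dict[str, list] = {}
    for seg in segments:
        if seg.is_calibration_silence:
            continue
        fm = extract_features(seg, mfcc)
        by_speaker.setdefault(seg.subject_id, []).append(fm)
    speakers = sorted(by_speaker)
    train_speakers, held_out = speakers[:8], speakers[8]
    labeled = [(fm, spk) for spk in train_speakers for fm in by_speaker[spk]]
    chunks = make_training_chunks(labeled, seed=3, chunks_per_segment=20)
    return {
        "mfcc": mfcc,
        "by_speaker": by_speaker,
        "train_speakers": train_speakers,
        "held_out": held_out,
        "chunks": chunks,
    }


@pytest.fixture(scope="session")
def trained_toy_tdnn(speaker_setup):
    """Desk-profile TDNN trained to identify the 8 toy speakers."""
    config = TdnnConfig.desk(input_dim=speaker_setup["mfcc"].dim, n_targets=8)
    model = build_tdnn(config, seed=0)
    return train_tdnn(model, speaker_setup["chunks"], epochs=25, lr=2e-3, seed=0)
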