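"""End-to-end experiment orchestration.

Wires the stages together: synthetic cohort -> frontend features ->
(augmentation) -> branch (MFCC-GMM or TDNN x-vectors) -> back-end scoring ->
repeated random subsampling aggregation -> EER/DET summary.  Everything is
reproducible from the seeds in the configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from pdvoice import augment as aug
from pdvoice import backend as be
from pdvoice import evaluate as ev
from pdvoice import gmm as gb
from pdvoice import tdnn as xn
from pdvoice.cohort import (
    AudioSegment,
    SubjectRecord,
    SynthCohortConfig,
    generate_cohort,
    generate_noise_bank,
)
from pdvoice.frontend import MfccConfig, extract_features, split_segments

_MOD = 2**31


def _derive_seed(seed: int, k: int) -> int:
    return (seed * 9973 + k) % _MOD


@dataclass(frozen=True)
class RunConfig:
    """One experiment of the study grid."""

    cohort: SynthCohortConfig
    branch: str = "gmm"                  # gmm | xvector
    backend: str = "lda_cosine"          # cosine | lda_cosine | plda (xvector)
    segment_mode: str = "matched"        # matched | mismatched test segments
    augment: bool = False
    n_runs: int = ev.N_RUNS_DEFAULT
    n_train_pd: int | None = None        # default: ~2/3 of the class
    n_train_hc: int | None = None
    gmm_components: int | None = None    # default 20 high-quality / 50 telephone
    tdnn_width: int = 48
    tdnn_embedding: int = 48
    tdnn_epochs: int = 12
    tdnn_lr: float = 2e-3
    n_background_speakers: int = 8
    plda_pre_dim: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.branch not in ("gmm", "xvector"):
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.backend not in ("cosine", "lda_cosine", "plda"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.cohort.channel == "telephone" and "reading" in self.cohort.tasks:
            raise ValueError("the telephone protocol has no reading task")

    @property
    def resolved_gmm_components(self) -> int:
        if self.gmm_components is not None:
            return self.gmm_components
        return (
            gb.N_COMPONENTS_TELEPHONE
            if self.cohort.channel == "telephone"
            else gb.N_COMPONENTS_HIGH_QUALITY
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def baseline_mfcc_config(cohort: SynthCohortConfig) -> MfccConfig:
    if cohort.channel == "telephone":
        return MfccConfig.baseline_telephone()
    return MfccConfig.baseline_high_quality(sample_rate=cohort.sample_rate)


def xvector_mfcc_config(cohort: SynthCohortConfig) -> MfccConfig:
    if cohort.channel == "telephone":
        return MfccConfig.xvector_telephone()
    return MfccConfig.xvector_high_quality()


def _calibrations(segments: list[AudioSegment]) -> dict:
    return {
        (s.subject_id, s.session_id): s for s in segments if s.is_calibration_silence
    }


def _speech_segments(segments: list[AudioSegment]) -> list[AudioSegment]:
    return [s for s in segments if not s.is_calibration_silence]


# ---------------------------------------------------------------------------
# GMM branch
# ---------------------------------------------------------------------------


def gmm_features_by_subject(
    segments: list[AudioSegment],
    cohort: SynthCohortConfig,
    mfcc: MfccConfig | None = None,
) -> dict:
    """Pooled kept frames per subject (baseline features, 60-dim by default).

    Spectral subtraction is applied on the high-quality channel using the
    session's calibration silence; the telephone channel skips it.
    """
    mfcc = mfcc or baseline_mfcc_config(cohort)
    cals = _calibrations(segments)
    feats: dict[str, list[np.ndarray]] = {}
    for seg in _speech_segments(segments):
        cal = (
            cals.get((seg.subject_id, seg.session_id))
            if cohort.channel == "high_quality"
            else None
        )
        fm = extract_features(seg, mfcc, calibration=cal)
        if fm.n_frames:
            feats.setdefault(seg.subject_id, []).append(fm.values)
    return {sid: np.vstack(rows) for sid, rows in feats.items()}


def make_gmm_run_pipeline(
    features_by_subject: dict,
    n_components: int,
    seed: int = 0,
    sigmoid_scale: float = 1.0,
):
    """Per-split trainer/scorer for the ensemble driver."""

    def run(split: dict) -> dict:
        pd_frames = np.vstack([features_by_subject[s] for s in split["train_pd"]])
        hc_frames = np.vstack([features_by_subject[s] for s in split["train_hc"]])
        pair = gb.GmmPair(
            pd_model=gb.train_gmm(pd_frames, n_components, seed=seed),
            hc_model=gb.train_gmm(hc_frames, n_components, seed=seed),
        )
        scores = {}
        for sid in split["test"]:
            if sid in features_by_subject:
                scores[sid] = gb.score_subject_gmm(
                    pair, features_by_subject[sid], sigmoid_scale
                )
        return scores

    return run


# ---------------------------------------------------------------------------
# x-vector branch
# ---------------------------------------------------------------------------


def train_background_extractor(
    cohort_template: SynthCohortConfig,
    n_speakers: int = 8,
    width: int = 48,
    embedding: int = 48,
    epochs: int = 12,
    lr: float = 2e-3,
    seed: int = 0,
    chunks_per_segment: int = 6,
) -> xn.TdnnModel:
    """Train a small speaker-identification TDNN on a disjoint synthetic cohort.

    Mirrors the use of an external speaker corpus for embedding training: the
    background speakers never appear in the study cohort, and their class
    labels are irrelevant (the softmax targets are speaker identities).
    """
    bg_cfg = replace(
        cohort_template,
        n_pd=0,
        n_hc=n_speakers,
        effect_size=0.0,
        sessions_per_subject=1,
        task_duration_s=max(cohort_template.task_duration_s, 10.0),
        seed=_derive_seed(seed, 101),
    )
    _, segments = generate_cohort(bg_cfg)
    mfcc = xvector_mfcc_config(bg_cfg)
    labeled = []
    for seg in _speech_segments(segments):
        fm = extract_features(seg, mfcc)
        if fm.n_frames >= 50:
            labeled.append((fm, seg.subject_id))
    chunks = xn.make_training_chunks(
        labeled, seed=_derive_seed(seed, 7), chunks_per_segment=chunks_per_segment
    )
    config = xn.TdnnConfig.desk(
        input_dim=mfcc.dim, n_targets=n_speakers, width=width,
        stats_dim=2 * width, embedding_dim=embedding,
    )
    model = xn.build_tdnn(config, seed=_derive_seed(seed, 11))
    return xn.train_tdnn(model, chunks, epochs=epochs, lr=lr, seed=_derive_seed(seed, 13))


def xvectors_by_subject(
    model: xn.TdnnModel,
    segments: list[AudioSegment],
    cohort: SynthCohortConfig,
    segment_mode: str = "matched",
) -> dict:
    """Per-subject x-vector lists after 1-5 s (or mismatched) segmenting."""
    mfcc = xvector_mfcc_config(cohort)
    cals = _calibrations(segments)
    out: dict[str, list[xn.XVector]] = {}
    for seg in _speech_segments(segments):
        cal = (
            cals.get((seg.subject_id, seg.session_id))
            if cohort.channel == "high_quality"
            else None
        )
        pieces = split_segments(seg, mismatched=(segment_mode == "mismatched"))
        feats = []
        for piece in pieces:
            fm = extract_features(piece, mfcc, calibration=cal)
            fm.provenance["parent_id"] = piece.parent_id
            if fm.n_frames >= model.config.receptive_field:
                feats.append(fm)
        if feats:
            out.setdefault(seg.subject_id, []).extend(xn.extract_for_file(model, feats))
    return out


def make_xvector_run_pipeline(
    xvecs_by_subject: dict,
    backend: str = "lda_cosine",
    aug_xvecs_by_subject: dict | None = None,
    plda_pre_dim: int = 16,
    seed: int = 0,
    sigmoid_scale: float = 1.0,
):
    """Per-split back-end trainer/scorer for the ensemble driver.

    References are the per-class means of the (un-augmented) training
    x-vectors; the LDA / PLDA discriminant fits additionally see the
    augmented copies of training subjects when provided.
    """

    def run(split: dict) -> dict:
        train_x, train_y = [], []
        for label, ids in (("PD", split["train_pd"]), ("HC", split["train_hc"])):
            for sid in ids:
                for xv in xvecs_by_subject.get(sid, []):
                    train_x.append(xv.values)
                    train_y.append(label)
        refs = be.compute_references(train_x, train_y)

        fit_x, fit_y = list(train_x), list(train_y)
        if aug_xvecs_by_subject:
            for label, ids in (("PD", split["train_pd"]), ("HC", split["train_hc"])):
                for sid in ids:
                    for xv in aug_xvecs_by_subject.get(sid, []):
                        fit_x.append(xv.values)
                        fit_y.append(label)

        transforms: dict = {}
        if backend == "lda_cosine":
            transforms["lda"] = be.fit_lda(fit_x, fit_y, dim_out=2)
        elif backend == "plda":
            dim = len(fit_x[0])
            pre_dim = min(plda_pre_dim, dim, max(len(fit_x) - 2, 2))
            pre = be.fit_lda(fit_x, fit_y, dim_out=pre_dim)
            proj = [pre.transform(v) for v in fit_x]
            transforms["plda_lda"] = pre
            transforms["plda"] = be.fit_plda(
                proj, fit_y, rank_F=1, rank_G=max(pre_dim - 1, 1),
                seed=seed, iters=30,
            )

        scores = {}
        for sid in split["test"]:
            xvs = xvecs_by_subject.get(sid, [])
            seg_scores = [
                be.score_xvector(refs, xv, method=backend, transforms=transforms,
                                 sigmoid_scale=sigmoid_scale)
                for xv in xvs
                if not xv.degenerate
            ]
            if seg_scores:
                scores[sid] = be.score_subject(seg_scores)
        return scores

    return run


def augmented_xvectors_by_subject(
    model: xn.TdnnModel,
    segments: list[AudioSegment],
    cohort: SynthCohortConfig,
    seed: int = 0,
) -> dict:
    """X-vectors of two random corrupted copies of every speech segment."""
    bank = generate_noise_bank(cohort.sample_rate, seed=_derive_seed(seed, 17))
    policy = aug.AugmentPolicy(seed=_derive_seed(seed, 19))
    speech = _speech_segments(segments)
    augmented = aug.augment_dataset(speech, bank, policy)
    # augment_dataset interleaves originals and copies; keep the copies only
    originals = {id(s) for s in speech}
    copies = [s for s in augmented if id(s) not in originals]
    keep_cal = [s for s in segments if s.is_calibration_silence]
    return xvectors_by_subject(model, copies + keep_cal, cohort)


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------


def run_experiment(config: RunConfig) -> dict:
    """Execute one configured experiment and return its evaluation summary."""
    subjects, segments = generate_cohort(config.cohort)
    labels = {s.subject_id: s.label for s in subjects}
    n_pd = sum(1 for s in subjects if s.label == "PD")
    n_hc = len(subjects) - n_pd
    n_train_pd = config.n_train_pd or max(1, (2 * n_pd) // 3)
    n_train_hc = config.n_train_hc or max(1, (2 * n_hc) // 3)
    splits = ev.make_splits(
        subjects, n_train_pd, n_train_hc, n_runs=config.n_runs,
        seed=_derive_seed(config.seed, 23),
    )

    if config.branch == "gmm":
        feats = gmm_features_by_subject(segments, config.cohort)
        pipeline = make_gmm_run_pipeline(
            feats, config.resolved_gmm_components, seed=_derive_seed(config.seed, 29)
        )
    else:
        model = train_background_extractor(
            config.cohort,
            n_speakers=config.n_background_speakers,
            width=config.tdnn_width,
            embedding=config.tdnn_embedding,
            epochs=config.tdnn_epochs,
            lr=config.tdnn_lr,
            seed=config.seed,
        )
        xvecs = xvectors_by_subject(model, segments, config.cohort, config.segment_mode)
        aug_xvecs = (
            augmented_xvectors_by_subject(model, segments, config.cohort, config.seed)
            if config.augment
            else None
        )
        pipeline = make_xvector_run_pipeline(
            xvecs, config.backend, aug_xvecs,
            plda_pre_dim=config.plda_pre_dim, seed=_derive_seed(config.seed, 31),
        )

    table = ev.run_ensemble(pipeline, splits, labels)
    avg_curve = ev.average_det(table.run_curves)
    return {
        "config_hash": config.config_hash(),
        "branch": config.branch,
        "backend": config.backend if config.branch == "xvector" else None,
        "effect_size": config.cohort.effect_size,
        "n_runs": config.n_runs,
        "aggregated_eer": table.aggregated_eer(),
        "mean_run_eer": float(np.mean(table.run_eers)),
        "averaged_det_eer": avg_curve.eer,
        "subject_scores": table.aggregated(),
        "expected_test_counts": splits.expected_test_counts(),
    }


# ---------------------------------------------------------------------------
# standard synthetic battery (desk-scale study conditions)
# ---------------------------------------------------------------------------

#: desk-scale study conditions: 16 + 16 male subjects, one free-speech
#: recording each, balanced 10 + 10 training groups and 24 splits so that
#: every subject is tested about nine times (the full design uses 40 splits).
BATTERY_COHORT = SynthCohortConfig(
    n_pd=16,
    n_hc=16,
    gender="M",
    sessions_per_subject=1,
    tasks=("free_speech",),
    task_duration_s=8.0,
    channel="high_quality",
    sample_rate=16000,
    effect_size=1.0,
    seed=0,
)
BATTERY_N_TRAIN = 10
BATTERY_N_RUNS = 24


def standard_battery(
    seed: int,
    branch: str,
    effect_sizes: tuple = (0.0, 1.0, 3.0),
    backend: str = "lda_cosine",
    n_runs: int = BATTERY_N_RUNS,
    gmm_components: int | None = 8,
) -> dict:
    """Run one branch over several class effect sizes at desk scale.

    Returns {effect_size: summary}.  The x-vector extractor is trained once
    (on background speakers) and reused across effect sizes, mirroring the
    reuse of a single pretrained embedding network.  The GMM branch defaults
    to 8 components here: mixture size follows the quantity of training
    speech, which is far smaller than in the full study conditions.
    """
    results: dict = {}
    shared_model = None
    for k, eff in enumerate(effect_sizes):
        cohort = replace(
            BATTERY_COHORT, effect_size=float(eff), seed=_derive_seed(seed, 41 + k)
        )
        cfg = RunConfig(
            cohort=cohort,
            branch=branch,
            backend=backend,
            n_runs=n_runs,
            n_train_pd=BATTERY_N_TRAIN,
            n_train_hc=BATTERY_N_TRAIN,
            gmm_components=gmm_components,
            seed=seed,
        )
        if branch == "gmm":
            results[eff] = run_experiment(cfg)
            continue
        # share the extractor across effect sizes
        if shared_model is None:
            shared_model = train_background_extractor(
                cfg.cohort,
                n_speakers=cfg.n_background_speakers,
                width=cfg.tdnn_width,
                embedding=cfg.tdnn_embedding,
                epochs=cfg.tdnn_epochs,
                lr=cfg.tdnn_lr,
                seed=seed,
            )
        subjects, segments = generate_cohort(cohort)
        labels = {s.subject_id: s.label for s in subjects}
        splits = ev.make_splits(
            subjects, cfg.n_train_pd, cfg.n_train_hc, n_runs=n_runs,
            seed=_derive_seed(seed, 23 + k),
        )
        xvecs = xvectors_by_subject(shared_model, segments, cohort)
        pipeline = make_xvector_run_pipeline(
            xvecs, backend, plda_pre_dim=cfg.plda_pre_dim,
            seed=_derive_seed(seed, 31),
        )
        table = ev.run_ensemble(pipeline, splits, labels)
        avg_curve = ev.average_det(table.run_curves)
        results[eff] = {
            "config_hash": cfg.config_hash(),
            "branch": branch,
            "backend": backend,
            "effect_size": float(eff),
            "n_runs": n_runs,
            "aggregated_eer": table.aggregated_eer(),
            "mean_run_eer": float(np.mean(table.run_eers)),
            "averaged_det_eer": avg_curve.eer,
            "subject_scores": table.aggregated(),
            "expected_test_counts": splits.expected_test_counts(),
        }
    return results
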