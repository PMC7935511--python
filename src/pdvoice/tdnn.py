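"""Time-delay neural network embedding extractor (x-vectors).

Frame-level layers with temporal context splicing feed a statistics-pooling
layer (per-dimension mean and population SD across the segment), followed by
two segment-level layers and a softmax over training targets (speakers, or
the two diagnostic classes).  The x-vector is the pre-activation of the
first segment-level layer.

Implemented directly on numpy with manual backpropagation: the networks
trained here are small, and the full-size architecture is kept only as the
dimension contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pdvoice.frontend import FeatureMatrix, MIN_SEGMENT_S, MAX_SEGMENT_S

#: frame-layer context offsets of the standard architecture; layers 2 and 3
#: use dilated splicing so their input widths are 3x the previous output
FULL_CONTEXTS = ((-2, -1, 0, 1, 2), (-2, 0, 2), (-3, 0, 3), (0,), (0,))
_EPS_STD = 1e-8


@dataclass(frozen=True)
class TdnnConfig:
    input_dim: int
    frame_dims: tuple[int, ...] = (512, 512, 512, 512, 1500)
    contexts: tuple[tuple[int, ...], ...] = FULL_CONTEXTS
    embedding_dim: int = 512
    segment_hidden_dim: int = 512
    n_targets: int = 8

    def __post_init__(self) -> None:
        if len(self.frame_dims) != len(self.contexts):
            raise ValueError("frame_dims and contexts length mismatch")
        if self.input_dim < 1 or self.n_targets < 2:
            raise ValueError("invalid dims")

    @property
    def pooled_dim(self) -> int:
        # mean (+) SD of the last frame layer
        return 2 * self.frame_dims[-1]

    @property
    def receptive_field(self) -> int:
        """Total temporal context in frames (15 for the standard contexts)."""
        return 1 + sum(max(c) - min(c) for c in self.contexts)

    @classmethod
    def full(cls, input_dim: int, n_targets: int) -> "TdnnConfig":
        return cls(input_dim=input_dim, n_targets=n_targets)

    @classmethod
    def desk(cls, input_dim: int, n_targets: int, width: int = 48,
             stats_dim: int = 96, embedding_dim: int = 48) -> "TdnnConfig":
        """Width-divided profile for CPU-scale experiments; same shape contract."""
        return cls(
            input_dim=input_dim,
            frame_dims=(width, width, width, width, stats_dim),
            embedding_dim=embedding_dim,
            segment_hidden_dim=embedding_dim,
            n_targets=n_targets,
        )


@dataclass
class TdnnModel:
    config: TdnnConfig
    params: dict = field(default_factory=dict)
    training_log: list = field(default_factory=list)  # per-epoch chunk accuracy
    label_names: tuple = ()


@dataclass
class XVector:
    values: np.ndarray
    provenance: dict = field(default_factory=dict)
    is_fragment_average: bool = False

    @property
    def degenerate(self) -> bool:
        return bool(np.linalg.norm(self.values) < 1e-9)

    def __len__(self) -> int:
        return len(self.values)


def build_tdnn(config: TdnnConfig, seed: int = 0) -> TdnnModel:
    """He-initialized network, deterministic in ``seed``."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    prev = config.input_dim
    for i, (ctx, out) in enumerate(zip(config.contexts, config.frame_dims)):
        fan_in = prev * len(ctx)
        params[f"W{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, out))
        params[f"b{i}"] = np.zeros(out)
        prev = out
    layers = [
        ("Wseg6", "bseg6", config.pooled_dim, config.embedding_dim),
        ("Wseg7", "bseg7", config.embedding_dim, config.segment_hidden_dim),
        ("Wout", "bout", config.segment_hidden_dim, config.n_targets),
    ]
    for wname, bname, din, dout in layers:
        params[wname] = rng.normal(0, np.sqrt(2.0 / din), (din, dout))
        params[bname] = np.zeros(dout)
    return TdnnModel(config=config, params=params)


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _splice(x: np.ndarray, offsets: tuple[int, ...]) -> np.ndarray:
    """Concatenate context frames: (T, D) -> (T - span, D * len(offsets))."""
    lo, hi = min(offsets), max(offsets)
    t_out = x.shape[0] - (hi - lo)
    if t_out < 1:
        raise ValueError("segment shorter than the receptive field")
    return np.concatenate([x[off - lo : off - lo + t_out] for off in offsets], axis=1)


def _forward(model: TdnnModel, feats: np.ndarray, cache: bool = False):
    cfg = model.config
    p = model.params
    h = feats
    frame_cache = []
    for i, ctx in enumerate(cfg.contexts):
        spliced = _splice(h, ctx)
        z = spliced @ p[f"W{i}"] + p[f"b{i}"]
        a = np.maximum(z, 0.0)
        if cache:
            frame_cache.append((h.shape[0], ctx, spliced, z))
        h = a
    T = h.shape[0]
    m = h.mean(axis=0)
    var = np.maximum(h.var(axis=0), 0.0)  # population variance
    s = np.sqrt(var + _EPS_STD)
    pooled = np.concatenate([m, s])
    z6 = pooled @ p["Wseg6"] + p["bseg6"]  # pre-ReLU: the x-vector
    a6 = np.maximum(z6, 0.0)
    z7 = a6 @ p["Wseg7"] + p["bseg7"]
    a7 = np.maximum(z7, 0.0)
    logits = a7 @ p["Wout"] + p["bout"]
    logits = logits - logits.max()
    probs = np.exp(logits)
    probs /= probs.sum()
    if not cache:
        return z6, probs
    return z6, probs, {
        "frame": frame_cache, "h_last": h, "T": T, "m": m, "s": s,
        "pooled": pooled, "z6": z6, "a6": a6, "z7": z7, "a7": a7,
    }


def _backward(model: TdnnModel, cachain, probs: np.ndarray, target: int) -> dict:
    """Gradients of cross-entropy w.r.t. all parameters for one chunk."""
    cfg = model.config
    p = model.params
    c = cachain
    g: dict[str, np.ndarray] = {}
    dlogits = probs.copy()
    dlogits[target] -= 1.0
    g["Wout"] = np.outer(c["a7"], dlogits)
    g["bout"] = dlogits
    da7 = p["Wout"] @ dlogits
    dz7 = da7 * (c["z7"] > 0)
    g["Wseg7"] = np.outer(c["a6"], dz7)
    g["bseg7"] = dz7
    da6 = p["Wseg7"] @ dz7
    dz6 = da6 * (c["z6"] > 0)
    g["Wseg6"] = np.outer(c["pooled"], dz6)
    g["bseg6"] = dz6
    dpooled = p["Wseg6"] @ dz6
    D = cfg.frame_dims[-1]
    dm, ds = dpooled[:D], dpooled[D:]
    h, T, m, s = c["h_last"], c["T"], c["m"], c["s"]
    # d s_d / d h_td = (h_td - m_d) / (T * s_d)
    dh = dm / T + ds * (h - m) / (T * s)
    for i in range(len(cfg.contexts) - 1, -1, -1):
        t_in, ctx, spliced, z = c["frame"][i]
        dz = dh * (z > 0)
        g[f"W{i}"] = spliced.T @ dz
        g[f"b{i}"] = dz.sum(axis=0)
        dspliced = dz @ p[f"W{i}"].T
        lo = min(ctx)
        d_prev_dim = spliced.shape[1] // len(ctx)
        dprev = np.zeros((t_in, d_prev_dim))
        t_out = dz.shape[0]
        for j, off in enumerate(ctx):
            dprev[off - lo : off - lo + t_out] += dspliced[
                :, j * d_prev_dim : (j + 1) * d_prev_dim
            ]
        dh = dprev
    return g


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def make_training_chunks(
    segments: list[tuple[FeatureMatrix, object]],
    seed: int = 0,
    min_s: float = 2.0,
    max_s: float = 4.0,
    chunks_per_segment: int = 1,
) -> list[tuple[np.ndarray, object]]:
    """Crop labeled feature matrices to 2-4 s training chunks.

    Chunks shorter than ``min_s`` worth of frames are used whole when the
    source segment itself is short (but never below the receptive field —
    the trainer enforces that).
    """
    rng = np.random.default_rng(seed)
    out = []
    for feats, label in segments:
        step_s = feats.config.step_ms / 1000.0
        T = feats.n_frames
        for _ in range(chunks_per_segment):
            want = int(rng.uniform(min_s, max_s) / step_s)
            if T <= want:
                out.append((feats.values, label))
            else:
                start = rng.integers(0, T - want + 1)
                out.append((feats.values[start : start + want], label))
    return out


def train_tdnn(
    model: TdnnModel,
    chunks: list[tuple[np.ndarray, object]],
    epochs: int = 20,
    lr: float = 1e-3,
    seed: int = 0,
) -> TdnnModel:
    """Cross-entropy training with Adam; records per-epoch chunk accuracy.

    ``chunks`` are (frames x input_dim, label) pairs; labels may be any
    hashable values (speaker ids, or the two class names) and are mapped to
    softmax indices sorted by name.  Deterministic in ``seed`` on one thread.
    """
    labels = sorted({lab for _, lab in chunks}, key=str)
    if len(labels) < 2:
        raise ValueError("training requires at least 2 distinct labels")
    if len(labels) != model.config.n_targets:
        raise ValueError(
            f"model has {model.config.n_targets} targets but {len(labels)} labels given"
        )
    index = {lab: i for i, lab in enumerate(labels)}
    rf = model.config.receptive_field
    data = [(np.asarray(x, dtype=float), index[lab]) for x, lab in chunks]
    for x, _ in data:
        if x.shape[0] < rf:
            raise ValueError("chunk shorter than the receptive field")

    rng = np.random.default_rng(seed)
    p = model.params
    mom = {k: np.zeros_like(v) for k, v in p.items()}
    vel = {k: np.zeros_like(v) for k, v in p.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(data))
        correct = 0
        for idx in order:
            x, target = data[idx]
            _, probs, cache = _forward(model, x, cache=True)
            correct += int(np.argmax(probs) == target)
            grads = _backward(model, cache, probs, target)
            step += 1
            for k, gk in grads.items():
                mom[k] = beta1 * mom[k] + (1 - beta1) * gk
                vel[k] = beta2 * vel[k] + (1 - beta2) * gk * gk
                mhat = mom[k] / (1 - beta1**step)
                vhat = vel[k] / (1 - beta2**step)
                p[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        model.training_log.append(correct / len(data))
    model.label_names = tuple(labels)
    return model


def predict_proba(model: TdnnModel, features) -> np.ndarray:
    """Softmax class probabilities for one segment."""
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    _, probs = _forward(model, x)
    return probs


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_xvector(model: TdnnModel, features) -> XVector:
    """Pre-ReLU activation of the first segment-level layer.

    The segment must span at least the receptive field and at most 100 s;
    longer recordings are fragmented by the caller and averaged with
    :func:`extract_for_file`.
    """
    if isinstance(features, FeatureMatrix):
        x = features.values
        prov = dict(features.provenance)
        dur_s = features.n_frames * features.config.step_ms / 1000.0
    else:
        x = np.asarray(features, dtype=float)
        prov = {}
        dur_s = None
    if x.shape[0] < model.config.receptive_field:
        raise ValueError("segment shorter than the receptive field")
    if dur_s is not None and dur_s > MAX_SEGMENT_S:
        raise ValueError("segment longer than 100 s: fragment it first")
    if dur_s is not None and dur_s < MIN_SEGMENT_S:
        raise ValueError("segment shorter than 25 ms")
    z6, _ = _forward(model, x)
    return XVector(values=z6, provenance=prov)


def extract_for_file(
    model: TdnnModel, features_list: list[FeatureMatrix]
) -> list[XVector]:
    """Extract x-vectors, averaging those of fragments sharing a parent."""
    singles: list[XVector] = []
    groups: dict[str, list[XVector]] = {}
    for feats in features_list:
        xv = extract_xvector(model, feats)
        parent = feats.provenance.get("parent_id")
        if parent is None:
            singles.append(xv)
        else:
            groups.setdefault(parent, []).append(xv)
    for parent, xvs in groups.items():
        mean = np.mean([v.values for v in xvs], axis=0)
        prov = dict(xvs[0].provenance)
        prov["parent_id"] = parent
        singles.append(XVector(values=mean, provenance=prov, is_fragment_average=True))
    return singles
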