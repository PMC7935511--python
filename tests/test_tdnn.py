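"""TDNN embedding extractor: architecture contract, gradients, training."""

import numpy as np
import pytest

from pdvoice.tdnn import (
    TdnnConfig,
    XVector,
    _backward,
    _forward,
    build_tdnn,
    extract_for_file,
    extract_xvector,
    make_training_chunks,
    predict_proba,
    train_tdnn,
)
from pdvoice.frontend import FeatureMatrix, MfccConfig


class TestArchitectureContract:
    def test_full_dimension_chain(self):
        cfg = TdnnConfig.full(input_dim=24, n_targets=100)
        m = build_tdnn(cfg, seed=0)
        assert m.params["W0"].shape == (5 * 24, 512)       # frame-level 1
        assert m.params["W1"].shape == (3 * 512, 512)      # 1,536 spliced
        assert m.params["W2"].shape == (3 * 512, 512)
        assert m.params["W3"].shape == (512, 512)
        assert m.params["W4"].shape == (512, 1500)
        assert cfg.pooled_dim == 3000                      # mean (+) SD
        assert m.params["Wseg6"].shape == (3000, 512)      # x-vector layer
        assert m.params["Wout"].shape == (512, 100)
        assert cfg.receptive_field == 15

    def test_xvector_is_512_dimensional(self):
        cfg = TdnnConfig.full(input_dim=24, n_targets=10)
        m = build_tdnn(cfg, seed=1)
        x = np.random.default_rng(0).normal(size=(40, 24))
        assert len(extract_xvector(m, x)) == 512

    def test_softmax_normalized_and_length_agnostic(self):
        cfg = TdnnConfig.desk(input_dim=8, n_targets=4)
        m = build_tdnn(cfg, seed=2)
        rng = np.random.default_rng(3)
        for T in (15, 60, 400):
            p = predict_proba(m, rng.normal(size=(T, 8)))
            assert p.shape == (4,)
            assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_constant_frames_give_zero_pooled_sd(self):
        cfg = TdnnConfig.desk(input_dim=6, n_targets=2)
        m = build_tdnn(cfg, seed=4)
        x = np.tile(np.linspace(-1, 1, 6), (50, 1))
        _, _, cache = _forward(m, x, cache=True)
        assert np.allclose(cache["s"], 0.0, atol=1e-3)

    def test_pooling_permutation_invariance(self):
        """Statistics pooling is order-free: permuting the frame-level
        outputs leaves the pooled mean/SD — and hence the x-vector —
        unchanged.  (Frame layers themselves are context-dependent, so the
        permutation is applied at the pooling input.)"""
        rng = np.random.default_rng(5)
        h = rng.normal(size=(80, 32))
        perm = rng.permutation(80)
        m, s = h.mean(axis=0), h.std(axis=0)
        mp, sp = h[perm].mean(axis=0), h[perm].std(axis=0)
        assert np.allclose(m, mp) and np.allclose(s, sp)

    def test_pooling_matches_two_pass_oracle(self):
        cfg = TdnnConfig.desk(input_dim=6, n_targets=2)
        m = build_tdnn(cfg, seed=6)
        x = np.random.default_rng(7).normal(size=(60, 6))
        _, _, cache = _forward(m, x, cache=True)
        h = cache["h_last"]
        mean = np.array([h[:, d].sum() / len(h) for d in range(h.shape[1])])
        sd = np.sqrt(
            np.array(
                [((h[:, d] - mean[d]) ** 2).sum() / len(h) for d in range(h.shape[1])]
            )
        )
        assert np.allclose(cache["m"], mean, atol=1e-6)
        assert np.allclose(cache["s"], sd, atol=1e-4)

    def test_too_short_segment_rejected(self):
        cfg = TdnnConfig.desk(input_dim=6, n_targets=2)
        m = build_tdnn(cfg, seed=8)
        with pytest.raises(ValueError):
            extract_xvector(m, np.zeros((10, 6)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = TdnnConfig(
            input_dim=3, frame_dims=(4, 5), contexts=((-1, 0, 1), (0,)),
            embedding_dim=4, segment_hidden_dim=4, n_targets=3,
        )
        m = build_tdnn(cfg, seed=9)
        rng = np.random.default_rng(10)
        x = rng.normal(size=(12, 3))
        target = 1
        _, probs, cache = _forward(m, x, cache=True)
        grads = _backward(m, cache, probs, target)

        def loss():
            _, p = _forward(m, x)
            return -np.log(p[target])

        eps = 1e-6
        for name in ("W0", "b0", "W1", "Wseg6", "bseg6", "Wseg7", "Wout", "bout"):
            w = m.params[name]
            flat_idx = [(0,) * w.ndim, tuple(d - 1 for d in w.shape)]
            for idx in flat_idx:
                orig = w[idx]
                w[idx] = orig + eps
                up = loss()
                w[idx] = orig - eps
                down = loss()
                w[idx] = orig
                num = (up - down) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, abs=1e-4)


class TestTraining:
    def test_untrained_accuracy_near_chance(self):
        cfg = TdnnConfig.desk(input_dim=8, n_targets=5)
        m = build_tdnn(cfg, seed=11)
        rng = np.random.default_rng(12)
        chunks = [(rng.normal(size=(50, 8)), k % 5) for k in range(100)]
        hits = sum(
            int(np.argmax(predict_proba(m, x)) == y) for x, y in chunks
        )
        assert hits / 100 < 0.45  # chance is 0.2

    def test_training_is_seed_reproducible(self):
        rng = np.random.default_rng(13)
        chunks = []
        for spk in range(3):
            mu = rng.normal(0, 2, 6)
            chunks += [(rng.normal(size=(40, 6)) + mu, spk) for _ in range(5)]
        cfg = TdnnConfig.desk(input_dim=6, n_targets=3, width=16, stats_dim=16,
                              embedding_dim=8)
        a = train_tdnn(build_tdnn(cfg, seed=1), chunks, epochs=3, lr=1e-3, seed=2)
        b = train_tdnn(build_tdnn(cfg, seed=1), chunks, epochs=3, lr=1e-3, seed=2)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])
        assert a.training_log == b.training_log

    def test_single_label_rejected(self):
        cfg = TdnnConfig.desk(input_dim=4, n_targets=2)
        m = build_tdnn(cfg, seed=14)
        with pytest.raises(ValueError):
            train_tdnn(m, [(np.zeros((20, 4)), "only")], epochs=1)

    def test_two_class_mode_softmax_width_two(self):
        cfg = TdnnConfig.desk(input_dim=4, n_targets=2)
        m = build_tdnn(cfg, seed=15)
        assert m.params["Wout"].shape[1] == 2
        rng = np.random.default_rng(16)
        chunks = [(rng.normal(size=(30, 4)) + (4 if k % 2 else 0), "PD" if k % 2 else "HC")
                  for k in range(20)]
        m = train_tdnn(m, chunks, epochs=5, lr=2e-3, seed=0)
        assert m.label_names == ("HC", "PD")


class TestToySpeakerTraining:
    def test_reaches_high_chunk_accuracy(self, trained_toy_tdnn):
        assert max(trained_toy_tdnn.training_log) > 0.9

    def test_within_speaker_similarity_exceeds_between(self, speaker_setup,
                                                       trained_toy_tdnn):
        from pdvoice.backend import cosine_similarity

        by_spk = speaker_setup["by_speaker"]
        speakers = speaker_setup["train_speakers"][:4]
        xv = {}
        for spk in speakers:
            fm = by_spk[spk][0]
            half = fm.n_frames // 2
            a = extract_xvector(trained_toy_tdnn, fm.values[:half])
            b = extract_xvector(trained_toy_tdnn, fm.values[half:])
            xv[spk] = (a.values, b.values)
        within = np.mean([cosine_similarity(*xv[s]) for s in speakers])
        between = np.mean(
            [
                cosine_similarity(xv[s1][0], xv[s2][1])
                for s1 in speakers
                for s2 in speakers
                if s1 != s2
            ]
        )
        assert within > between

    def test_held_out_speaker_clusters(self, speaker_setup, trained_toy_tdnn):
        """Embeddings separate a speaker never seen in training (positive
        silhouette against trained speakers' segments)."""
        from sklearn.metrics import silhouette_samples

        by_spk = speaker_setup["by_speaker"]
        vecs, labs = [], []
        for spk in speaker_setup["train_speakers"][:4] + [speaker_setup["held_out"]]:
            fm = by_spk[spk][0]
            third = fm.n_frames // 3
            for i in range(3):
                seg = fm.values[i * third : (i + 1) * third]
                vecs.append(extract_xvector(trained_toy_tdnn, seg).values)
                labs.append(spk)
        vecs, labs = np.array(vecs), np.array(labs)
        sil = silhouette_samples(vecs, labs, metric="cosine")
        assert sil[labs == speaker_setup["held_out"]].mean() > 0


class TestExtraction:
    def _fm(self, values, parent=None):
        cfg = MfccConfig.xvector_high_quality()
        fm = FeatureMatrix(values, np.arange(len(values)) * 0.01, cfg,
                           {"parent_id": parent})
        return fm

    def test_deterministic(self, trained_toy_tdnn):
        x = np.random.default_rng(17).normal(size=(100, 31))
        a = extract_xvector(trained_toy_tdnn, x)
        b = extract_xvector(trained_toy_tdnn, x)
        assert np.array_equal(a.values, b.values)

    def test_fragments_averaged_to_single_vector(self, trained_toy_tdnn):
        rng = np.random.default_rng(18)
        frags = [self._fm(rng.normal(size=(80, 31)), parent="long-file")
                 for _ in range(3)]
        out = extract_for_file(trained_toy_tdnn, frags)
        assert len(out) == 1
        assert out[0].is_fragment_average
        parts = [extract_xvector(trained_toy_tdnn, f).values for f in frags]
        assert np.allclose(out[0].values, np.mean(parts, axis=0))

    def test_identical_fragment_average_idempotent(self, trained_toy_tdnn):
        rng = np.random.default_rng(19)
        vals = rng.normal(size=(80, 31))
        frags = [self._fm(vals, parent="p") for _ in range(2)]
        out = extract_for_file(trained_toy_tdnn, frags)
        single = extract_xvector(trained_toy_tdnn, vals)
        assert np.allclose(out[0].values, single.values)

    def test_cancelling_fragments_flagged_degenerate(self):
        v = np.ones(8)
        avg = XVector((v + (-v)) / 2)
        assert avg.degenerate
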