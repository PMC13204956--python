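"""The normalizer-free classifier: layers, AGC, training, attention."""

import numpy as np
import pytest

from mscascade.nn import (
    AttentionMap,
    ModelConfig,
    TrainConfig,
    agc_clip,
    attention_allocation,
    build_model,
    class_weights,
    extract_attention,
    predict_epochs,
    train_model,
    weighted_cross_entropy,
)
from mscascade.nn.layers import BatchNorm1d

TINY = ModelConfig(in_channels=3, stem_width=4, block_widths=(4,), attn_heads=2, attn_embed=8)
SMALL = ModelConfig(stem_width=8, block_widths=(8,), attn_embed=16, attn_heads=4)


class TestArchitecture:
    def test_logit_shape_contract(self):
        m = build_model(ModelConfig(), seed=42)
        x = np.random.default_rng(0).normal(size=(5, 8, 2560)).astype(np.float32)
        assert m.forward(x).shape == (5, 2)

    def test_proposed_variant_has_no_normalization_layers(self):
        m = build_model(ModelConfig(), seed=42)
        assert not any(isinstance(l, BatchNorm1d) for l in m.iter_layers())

    def test_conv_bn_variant_has_normalization(self):
        m = build_model(ModelConfig(variant="conv_bn"), seed=42)
        assert any(isinstance(l, BatchNorm1d) for l in m.iter_layers())

    def test_temporal_length_after_stem_and_pool(self):
        m = build_model(ModelConfig(), seed=42)
        assert m.token_length(2560) == 320

    def test_single_sample_equals_batched_inference(self):
        m = build_model(SMALL, seed=1)
        x = np.random.default_rng(2).normal(size=(4, 8, 320)).astype(np.float32)
        batched = m.forward(x, training=False)
        single = np.vstack([m.forward(x[i : i + 1], training=False) for i in range(4)])
        assert np.allclose(batched, single, atol=1e-5)

    def test_conv_bn_variant_violates_batch_independence_in_training_mode(self):
        m = build_model(ModelConfig(variant="conv_bn", stem_width=8, block_widths=(8,), attn_embed=16), seed=1)
        x = np.random.default_rng(3).normal(size=(4, 8, 320)).astype(np.float32)
        batched = m.forward(x, training=True)
        single = np.vstack([m.forward(x[i : i + 1], training=True) for i in range(4)])
        assert not np.allclose(batched, single, atol=1e-5)

    def test_invalid_embed_head_combo_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(attn_embed=10, attn_heads=4)

    def test_gradients_match_finite_differences(self):
        m = build_model(TINY, seed=0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 3, 64)).astype(np.float32)
        y = np.array([0, 1, 0])
        m.zero_grad()
        loss, grad = weighted_cross_entropy(m.forward(x), y)
        m.backward(grad.astype(np.float32))
        checked = 0
        for p in m.params():
            flat, gflat = p.value.reshape(-1), p.grad.reshape(-1)
            for i in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + 1e-3
                up = weighted_cross_entropy(m.forward(x), y)[0]
                flat[i] = old - 1e-3
                dn = weighted_cross_entropy(m.forward(x), y)[0]
                flat[i] = old
                numeric = (up - dn) / 2e-3
                assert gflat[i] == pytest.approx(numeric, abs=1e-3, rel=0.05)
                checked += 1
        assert checked > 30


class TestAgc:
    def test_zero_gradient_unchanged(self):
        w = np.ones((4, 3))
        g = np.zeros_like(w)
        assert np.array_equal(agc_clip(g, w), g)

    def test_unit_norm_hand_case(self):
        w = np.array([[1.0]])
        g = np.array([[1.0]])
        out = agc_clip(g, w, lam=0.04)
        assert np.linalg.norm(out) == pytest.approx(0.04)

    def test_zero_weight_eps_branch(self):
        w = np.array([[0.0]])
        g = np.array([[1.0]])
        out = agc_clip(g, w, lam=0.04, eps=1e-3)
        assert np.linalg.norm(out) == pytest.approx(4e-5)

    def test_norm_bound_and_direction_preserved(self, rng):
        for _ in range(25):
            w = rng.normal(size=(6, 5)) * rng.choice([0.01, 1.0])
            g = rng.normal(size=(6, 5)) * rng.choice([0.1, 10.0])
            out = agc_clip(g, w)
            for i in range(6):
                gn = np.linalg.norm(g[i])
                on = np.linalg.norm(out[i])
                bound = max(gn, 0.04 * max(np.linalg.norm(w[i]), 1e-3))
                assert on <= bound + 1e-12
                if gn > 0:
                    cos = out[i] @ g[i] / (on * gn)
                    assert cos == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agc_clip(np.zeros((2, 2)), np.zeros((3, 2)))


class TestLossAndWeights:
    def test_inverse_frequency_hand_case(self):
        w = class_weights({"dementia": 59, "HC": 29})
        assert w == pytest.approx([0.7458, 1.5172], abs=1e-4)

    def test_balanced_counts_give_unit_weights(self):
        assert np.allclose(class_weights([10, 10, 10]), 1.0)

    def test_scale_invariance(self):
        assert np.allclose(class_weights([5, 9]), class_weights([50, 90]))

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            class_weights([3, 0])

    def test_weighted_equals_unweighted_on_balanced_set(self, rng):
        logits = rng.normal(size=(8, 2))
        y = np.array([0, 1] * 4)
        lw, _ = weighted_cross_entropy(logits, y, class_weights(np.bincount(y)))
        lu, _ = weighted_cross_entropy(logits, y, None)
        assert lw == pytest.approx(lu)


class TestTraining:
    def _separable(self, n=24, t=320, seed=0):
        rng = np.random.default_rng(seed)
        x0 = rng.random((n, 8, t)).astype(np.float32) * 0.2
        x0[:, :4] += 0.6
        x1 = rng.random((n, 8, t)).astype(np.float32) * 0.2
        x1[:, 4:] += 0.6
        x = np.vstack([x0, x1])
        y = np.array([0] * n + [1] * n)
        return x, y

    def test_early_stopping_on_constant_validation_loss(self):
        x, y = self._separable(n=8)
        # constant zero validation inputs -> validation loss cannot improve
        vx = np.zeros((4, 8, 320), dtype=np.float32)
        vy = np.array([0, 1, 0, 1])
        m = build_model(SMALL, seed=0)
        cfg = TrainConfig(lr=0.0, max_epochs=50, patience=4, seed=0)
        hist = train_model(m, x, y, vx, vy, cfg)
        assert hist["n_epochs"] == cfg.patience + 1

    def test_separable_inputs_learned(self):
        x, y = self._separable()
        m = build_model(SMALL, seed=42)
        cfg = TrainConfig(lr=3e-3, max_epochs=50, patience=10, seed=42)
        train_model(m, x[::2], y[::2], x[1::2], y[1::2], cfg)
        probs = predict_epochs(m, x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs.argmax(axis=1) == y).mean() >= 0.95

    def test_duplicated_epoch_gets_identical_probabilities(self):
        m = build_model(SMALL, seed=3)
        x = np.random.default_rng(1).random((1, 8, 320)).astype(np.float32)
        probs = predict_epochs(m, np.vstack([x, x]))
        assert np.allclose(probs[0], probs[1])

    def test_seeded_training_is_deterministic(self):
        x, y = self._separable(n=6, t=128)
        cfg = TrainConfig(lr=1e-3, max_epochs=5, patience=3, seed=7)
        hists = []
        for _ in range(2):
            m = build_model(ModelConfig(stem_width=4, block_widths=(4,), attn_embed=8, attn_heads=2), seed=7)
            hists.append(train_model(m, x, y, x[:4], y[:4], cfg))
        assert hists[0]["train_loss"] == hists[1]["train_loss"]
        assert hists[0]["val_loss"] == hists[1]["val_loss"]

    def test_subject_overlap_between_train_and_val_rejected(self):
        x, y = self._separable(n=4, t=64)
        m = build_model(ModelConfig(stem_width=4, block_widths=(4,), attn_embed=8, attn_heads=2), seed=0)
        with pytest.raises(ValueError, match="leakage"):
            train_model(m, x, y, x, y, TrainConfig(max_epochs=1),
                        train_subjects=["s1"] * len(y), val_subjects=["s1"] * len(y))


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path):
        from mscascade.nn import load_checkpoint, save_checkpoint

        m = build_model(SMALL, seed=11)
        x = np.random.default_rng(0).normal(size=(2, 8, 320)).astype(np.float32)
        path = tmp_path / "model.npz"
        save_checkpoint(m, path)
        back = load_checkpoint(path)
        assert back.config == m.config
        assert np.allclose(back.forward(x), m.forward(x))

    def test_history_tsv(self, tmp_path):
        from mscascade.nn import save_history_tsv

        hist = {"train_loss": [0.9, 0.5], "val_loss": [0.8, 0.6]}
        path = tmp_path / "history.tsv"
        save_history_tsv(hist, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0].split("\t") == ["epoch", "train_loss", "val_loss"]
        assert len(lines) == 3


class TestAttention:
    def test_distribution_properties_and_upsampling(self):
        m = build_model(SMALL, seed=5)
        x = np.random.default_rng(4).random((8, 2560)).astype(np.float32)
        att = extract_attention(m, x)
        assert att.weights.min() >= 0
        assert att.weights.sum() == pytest.approx(1.0, abs=1e-6)
        assert att.weights.size == 320
        assert att.upsampled(2560).size == 2560

    def test_variant_without_attention_rejected(self):
        m = build_model(ModelConfig(variant="nfnet_no_attn", stem_width=8, block_widths=(8,)), seed=0)
        with pytest.raises(ValueError):
            extract_attention(m, np.zeros((8, 2560), dtype=np.float32))

    def test_allocation_hand_cases(self):
        t = 64
        uniform = AttentionMap(np.full(t, 1.0 / t))
        all_target = np.zeros((8, t))
        all_target[4:] = 0.5
        assert attention_allocation(uniform, all_target, range(4, 8)) == pytest.approx(1.0)
        assert attention_allocation(uniform, all_target, range(0, 4)) == pytest.approx(0.0)
        equal = np.full((8, t), 0.3)
        assert attention_allocation(uniform, equal, range(4, 8)) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            attention_allocation(uniform, equal, [])

    def test_trained_model_prefers_delta_rows_for_burst_class(self):
        """Attention allocation separates a bursty class from a quiet class.

        Mirrors the group-level interpretability check: subjects whose
        delta rows carry transient high-correlation bursts should receive
        significantly more delta-row attention than subjects without them.
        """
        from mscascade.stats import mann_whitney_u

        rng = np.random.default_rng(42)
        t = 320
        n_subj, n_ep = 6, 6

        def subject_epochs(bursty):
            eps = rng.random((n_ep, 8, t)).astype(np.float32) * 0.25
            eps[:, :4] += 0.35  # alpha-like baseline
            if bursty:
                for e in eps:
                    for _ in range(4):
                        s = rng.integers(0, t - 20)
                        e[4:, s : s + 20] += 0.6
            return np.clip(eps, 0, 1)

        groups = [subject_epochs(True) for _ in range(n_subj)] + [
            subject_epochs(False) for _ in range(n_subj)
        ]
        x = np.concatenate(groups)
        y = np.array([1] * (n_subj * n_ep) + [0] * (n_subj * n_ep))
        m = build_model(SMALL, seed=42)
        train_model(m, x, y, x[:: 3], y[:: 3], TrainConfig(lr=3e-3, max_epochs=12, patience=12, seed=42),
                    train_subjects=None, val_subjects=None)
        scores = []
        for subj in groups:
            per_ep = [
                attention_allocation(extract_attention(m, e), e, range(4, 8)) for e in subj
            ]
            scores.append(float(np.mean(per_ep)))
        bursty, quiet = scores[:n_subj], scores[n_subj:]
        _, p = mann_whitney_u(bursty, quiet)
        assert np.mean(bursty) > np.mean(quiet)
        assert p < 0.05
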