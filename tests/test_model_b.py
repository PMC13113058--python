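"""Fusion-model tests: brute-force oracles for attention, BCE, and the
classification head, plus architectural contracts."""

import numpy as np
import pytest

from pvlkit.model_b import (ClinicalMLP, CrossAttentionFusion, EncoderConfig,
                            FusionConfig, FusionModel, ResNet3dEncoder,
                            bce_loss, class_balanced_weights,
                            load_checkpoint, save_checkpoint)
from pvlkit.nnx import Tensor


def brute_force_attention(Q, K, V, d):
    """Independent scalar-loop softmax(QK^T/sqrt(d))V."""
    T, m = Q.shape[0], K.shape[0]
    out = np.zeros((T, V.shape[1]))
    for t in range(T):
        scores = np.array([np.dot(Q[t], K[j]) / np.sqrt(d) for j in range(m)])
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        for j in range(m):
            out[t] += w[j] * V[j]
    return out


class TestCrossAttention:
    def _identity_fusion(self, n_tokens, token_dim, d):
        """Fusion module with identity projections for oracle comparison."""
        cfg = FusionConfig(n_clinical_features=5, clinical_embed_dim=token_dim * n_tokens,
                           n_clinical_tokens=n_tokens, attention_dim=d)
        fus = CrossAttentionFusion(d_model=d, cfg=cfg,
                                   rng=np.random.default_rng(0))
        return fus

    def test_matches_loop_oracle_many_instances(self, rng):
        for _ in range(100):
            T, m, d = int(rng.integers(1, 6)), int(rng.integers(1, 5)), 4
            Q = rng.normal(size=(T, d)).astype(np.float32)
            K = rng.normal(size=(m, d)).astype(np.float32)
            V = rng.normal(size=(m, d)).astype(np.float32)
            # route through the module with identity projections
            fus = self._identity_fusion(m, d, d)
            for w in (fus.w_q, fus.w_k, fus.w_v):
                w.weight.data = np.eye(d, dtype=np.float32)
                w.bias.data = np.zeros(d, dtype=np.float32)
            out = fus(Tensor(Q[None]), Tensor(K[None])).data[0]
            # oracle fuses then mean-pools; V projection is identity but the
            # module reads V from the same clinical tokens as K
            ref = brute_force_attention(Q, K, K, d).mean(axis=0)
            np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_single_clinical_token_degenerates(self, rng):
        # m=1: softmax over a singleton is exactly 1, fused token = V row
        d = 8
        fus = self._identity_fusion(1, d, d)
        for w in (fus.w_q, fus.w_k, fus.w_v):
            w.weight.data = np.eye(d, dtype=np.float32)
            w.bias.data = np.zeros(d, dtype=np.float32)
        Q = rng.normal(size=(1, 3, d)).astype(np.float32)
        KV = rng.normal(size=(1, 1, d)).astype(np.float32)
        fus(Tensor(Q), Tensor(KV))
        np.testing.assert_allclose(fus.last_weights, 1.0, atol=1e-7)

    def test_identical_keys_give_uniform_weights(self, rng):
        d = 4
        fus = self._identity_fusion(2, d, d)
        Q = rng.normal(size=(1, 5, d)).astype(np.float32)
        key = rng.normal(size=d).astype(np.float32)
        KV = np.stack([key, key])[None]
        fus(Tensor(Q), Tensor(KV.astype(np.float32)))
        np.testing.assert_allclose(fus.last_weights, 0.5, atol=1e-6)

    def test_row_stochastic(self, rng):
        cfg = FusionConfig(n_clinical_features=7)
        fus = CrossAttentionFusion(16, cfg, rng=rng)
        fus(Tensor(rng.normal(size=(2, 8, 16)).astype(np.float32)),
            Tensor(rng.normal(size=(2, 8, 8)).astype(np.float32)))
        np.testing.assert_allclose(fus.last_weights.sum(axis=-1), 1.0,
                                   atol=1e-6)

    def test_clinical_token_permutation_invariance(self, rng):
        """Permuting clinical tokens together with their K/V rows leaves the
        fused output unchanged (weights share the projection)."""
        cfg = FusionConfig(n_clinical_features=7)
        fus = CrossAttentionFusion(16, cfg, rng=rng)
        img = Tensor(rng.normal(size=(1, 4, 16)).astype(np.float32))
        clin = rng.normal(size=(1, 8, 8)).astype(np.float32)
        perm = rng.permutation(8)
        out1 = fus(img, Tensor(clin)).data
        out2 = fus(img, Tensor(clin[:, perm])).data
        np.testing.assert_allclose(out1, out2, atol=1e-5)


class TestClassifyHead:
    def test_zero_weights_give_half(self, rng):
        from pvlkit import nnx
        head = nnx.Linear(6, 1, rng=rng)
        head.weight.data[:] = 0
        head.bias.data[:] = 0
        p = head(Tensor(np.ones((1, 6), dtype=np.float32))).sigmoid()
        assert p.data[0, 0] == pytest.approx(0.5)

    def test_saturation(self, rng):
        from pvlkit import nnx
        head = nnx.Linear(3, 1, rng=rng)
        head.weight.data[:] = 0
        head.bias.data[:] = 20.0
        p = head(Tensor(np.zeros((1, 3), dtype=np.float32))).sigmoid()
        assert p.data[0, 0] > 0.999999

    def test_matches_scalar_formula(self, rng):
        from pvlkit import nnx
        head = nnx.Linear(5, 1, rng=rng)
        f = rng.normal(size=(1, 5)).astype(np.float32)
        p = float(head(Tensor(f)).sigmoid().data[0, 0])
        z = (f @ head.weight.data + head.bias.data).item()
        assert p == pytest.approx(1 / (1 + np.exp(-z)), abs=1e-7)


class TestBCE:
    def test_ln2_at_half(self):
        p = Tensor(np.array([0.5], dtype=np.float32))
        assert float(bce_loss(p, np.array([1.0])).data) == \
            pytest.approx(np.log(2), rel=1e-6)

    def test_perfect_fit_limit(self):
        p = Tensor(np.array([1e-7, 1 - 1e-7], dtype=np.float32))
        loss = float(bce_loss(p, np.array([0.0, 1.0])).data)
        assert loss < 1e-4

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            n = 16
            probs = rng.uniform(0.01, 0.99, size=n).astype(np.float32)
            y = (rng.uniform(size=n) < 0.5).astype(float)
            w = rng.uniform(0.5, 2.0, size=n)
            ref = -np.mean([wi * (yi * np.log(pi) + (1 - yi) * np.log(1 - pi))
                            for pi, yi, wi in zip(probs, y, w)])
            out = float(bce_loss(Tensor(probs), y, w).data)
            assert out == pytest.approx(ref, rel=1e-5)

    def test_clamps_instead_of_nan(self):
        p = Tensor(np.array([0.0, 1.0], dtype=np.float32))
        loss = float(bce_loss(p, np.array([1.0, 0.0])).data)
        assert np.isfinite(loss)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(Tensor(np.array([0.5])), np.array([1.0, 0.0]))

    def test_class_balanced_weights_sum(self):
        y = np.array([0, 0, 0, 0, 1])
        w = class_balanced_weights(y)
        assert w[y == 1].sum() == pytest.approx(w[y == 0].sum())


class TestEncoder:
    def test_token_count_64_cube(self, rng):
        enc = ResNet3dEncoder(EncoderConfig.tiny(), rng=rng)
        fmap = enc(Tensor(rng.normal(size=(1, 3, 64, 64, 64))
                          .astype(np.float32)))
        assert fmap.shape[2:] == (2, 2, 2)
        assert enc.tokens(fmap).shape == (1, 8, enc.cfg.feature_dim)

    def test_all_zero_input_finite(self, rng):
        enc = ResNet3dEncoder(EncoderConfig.tiny(), rng=rng)
        fmap = enc(Tensor(np.zeros((1, 3, 32, 32, 32), dtype=np.float32)))
        assert np.all(np.isfinite(fmap.data))

    def test_tiny_param_count_ratio(self):
        full = FusionModel(EncoderConfig(), FusionConfig(), seed=0)
        tiny = FusionModel(EncoderConfig.tiny(), FusionConfig(), seed=0)
        n_full = sum(p.data.size for p in full.encoder.parameters())
        n_tiny = sum(p.data.size for p in tiny.encoder.parameters())
        assert n_tiny * 50 < n_full

    def test_channel_mismatch_rejected(self, rng):
        enc = ResNet3dEncoder(EncoderConfig.tiny(), rng=rng)
        with pytest.raises(ValueError, match="channels"):
            enc(Tensor(np.zeros((1, 2, 32, 32, 32), dtype=np.float32)))

    def test_batch_order_equivariance(self, rng):
        enc = ResNet3dEncoder(EncoderConfig.tiny(), rng=rng)
        enc.eval()
        x = rng.normal(size=(3, 3, 16, 16, 16)).astype(np.float32)
        out = enc(Tensor(x)).data
        out_rev = enc(Tensor(x[::-1].copy())).data
        np.testing.assert_allclose(out_rev, out[::-1], atol=1e-5)


class TestClinicalMLP:
    def test_embedding_is_64_dim(self, rng):
        mlp = ClinicalMLP(FusionConfig(n_clinical_features=35), rng=rng)
        out = mlp(Tensor(rng.normal(size=(2, 35)).astype(np.float32)))
        assert out.shape == (2, 64)

    def test_deterministic(self, rng):
        mlp = ClinicalMLP(FusionConfig(n_clinical_features=10), rng=rng)
        x = Tensor(rng.normal(size=(1, 10)).astype(np.float32))
        np.testing.assert_array_equal(mlp(x).data, mlp(x).data)

    def test_extreme_inputs_finite(self, rng):
        mlp = ClinicalMLP(FusionConfig(n_clinical_features=10), rng=rng)
        out = mlp(Tensor(np.full((1, 10), 10.0, dtype=np.float32)))
        assert np.all(np.isfinite(out.data))

    def test_wrong_width_rejected(self, rng):
        mlp = ClinicalMLP(FusionConfig(n_clinical_features=10), rng=rng)
        with pytest.raises(ValueError, match="covariates"):
            mlp(Tensor(np.zeros((1, 7), dtype=np.float32)))


class TestFullForward:
    @pytest.fixture(scope="class")
    def model(self):
        return FusionModel(EncoderConfig.tiny(),
                           FusionConfig(n_clinical_features=12), seed=3)

    def test_untrained_mean_probability_near_half(self, model, rng):
        x = rng.normal(size=(6, 3, 16, 16, 16)).astype(np.float32)
        c = rng.normal(size=(6, 12)).astype(np.float32)
        p = model(Tensor(x), Tensor(c)).data
        assert 0.2 < p.mean() < 0.8

    def test_gradient_reaches_every_parameter_group(self, model, rng):
        x = rng.normal(size=(2, 3, 16, 16, 16)).astype(np.float32)
        c = rng.normal(size=(2, 12)).astype(np.float32)
        model.zero_grad()
        p = model(Tensor(x), Tensor(c))
        bce_loss(p, np.array([0.0, 1.0])).backward()
        for name, param in model.named_parameters().items():
            assert param.grad is not None, f"no gradient for {name}"
            assert np.any(param.grad != 0) or param.data.size == 1 or \
                "bn" in name or "beta" in name or "bias" in name, \
                f"all-zero gradient for {name}"

    def test_clinical_branch_is_active(self, model, rng):
        x = rng.normal(size=(1, 3, 16, 16, 16)).astype(np.float32)
        c1 = rng.normal(size=(1, 12)).astype(np.float32)
        c2 = c1 + 3.0
        model.eval()
        p1 = float(model(Tensor(x), Tensor(c1)).data[0])
        p2 = float(model(Tensor(x), Tensor(c2)).data[0])
        assert p1 != pytest.approx(p2, abs=1e-9)

    def test_checkpoint_roundtrip(self, model, tmp_path, rng):
        save_checkpoint(model, tmp_path / "ckpt.npz")
        clone = load_checkpoint(tmp_path / "ckpt.npz")
        model.eval()
        clone.eval()
        x = rng.normal(size=(1, 3, 16, 16, 16)).astype(np.float32)
        c = rng.normal(size=(1, 12)).astype(np.float32)
        np.testing.assert_allclose(model(Tensor(x), Tensor(c)).data,
                                   clone(Tensor(x), Tensor(c)).data,
                                   atol=1e-7)


def test_fusion_config_validation():
    with pytest.raises(ValueError, match="divisible"):
        FusionConfig(n_clinical_tokens=7)
    with pytest.raises(ValueError, match="positive"):
        FusionConfig(attention_dim=0)
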