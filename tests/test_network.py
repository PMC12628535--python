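"""Shape, determinism and closed-form contracts of the dual-branch network."""

import numpy as np
import pytest

from methylcl.autodiff import Tensor
from methylcl.network import (
    Model,
    ModelConfig,
    attention_pool,
    attention_pool_scores,
    variant_config,
    uses_contrastive,
)


@pytest.fixture
def model():
    return Model(ModelConfig(embed_dim=8, conv_filters=16, hidden=64, seed=0))


def fake_inputs(rng, batch=3, tokens=38, dim=8, L0=41):
    return Tensor(rng.normal(size=(batch, tokens, dim))), Tensor(
        rng.normal(size=(batch, L0, 1))
    )


class TestAttentionPool:
    def test_single_timestep_gets_weight_one(self):
        H = Tensor(np.array([[[2.0, 3.0]]]))
        e = Tensor(np.array([[1.7]]))
        a, c = attention_pool_scores(H, e)
        assert np.allclose(a.data, [[1.0]])
        assert np.allclose(c.data, [[2.0, 3.0]])

    def test_identical_timesteps_get_equal_weights(self):
        H = Tensor(np.tile([[1.0, 2.0]], (1, 2, 1)).reshape(1, 2, 2))
        e = Tensor(np.array([[0.3, 0.3]]))
        a, _ = attention_pool_scores(H, e)
        assert np.allclose(a.data, [[0.5, 0.5]])

    def test_ln3_scores_give_three_quarter_weight(self):
        H = Tensor(np.array([[[1.0, 0.0], [0.0, 1.0]]]))
        e = Tensor(np.array([[np.log(3.0), 0.0]]))
        a, c = attention_pool_scores(H, e)
        assert np.allclose(a.data, [[0.75, 0.25]])
        assert np.allclose(c.data, [[0.75, 0.25]])

    def test_zero_parameters_give_unweighted_mean(self):
        rng = np.random.default_rng(0)
        H = Tensor(rng.normal(size=(2, 5, 4)))
        W = Tensor(np.zeros((4, 4)))
        b = Tensor(np.zeros(4))
        v = Tensor(np.zeros((4, 1)))
        a, c = attention_pool(H, W, b, v)
        assert np.allclose(a.data, 0.2)
        assert np.allclose(c.data, H.data.mean(axis=1))

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            attention_pool_scores(Tensor(np.empty((1, 0, 3))), Tensor(np.empty((1, 0))))

    def test_weights_are_probability_vectors(self):
        rng = np.random.default_rng(1)
        H = Tensor(rng.normal(size=(4, 7, 6)))
        W = Tensor(rng.normal(size=(6, 6)))
        b = Tensor(rng.normal(size=6))
        v = Tensor(rng.normal(size=(6, 1)))
        a, _ = attention_pool(H, W, b, v)
        assert np.all(a.data >= 0)
        assert np.allclose(a.data.sum(axis=1), 1.0)


class TestBranches:
    def test_branch1_context_dimension_is_128(self, model):
        rng = np.random.default_rng(0)
        X, _ = fake_inputs(rng)
        _, ctx, attn = model.branch1_forward(X, train_mode=False)
        assert ctx.shape == (3, 128)
        assert np.allclose(attn.data.sum(axis=1), 1.0)

    def test_branch1_eval_mode_deterministic(self, model):
        rng = np.random.default_rng(0)
        X, _ = fake_inputs(rng)
        _, c1, _ = model.branch1_forward(X, train_mode=False)
        _, c2, _ = model.branch1_forward(X, train_mode=False)
        assert np.array_equal(c1.data, c2.data)

    def test_branch1_wrong_rank_raises(self, model):
        with pytest.raises(ValueError):
            model.branch1_forward(Tensor(np.zeros((3, 8))), train_mode=False)

    def test_branch2_summary_dimension_is_128(self, model):
        rng = np.random.default_rng(0)
        _, Xe = fake_inputs(rng)
        out = model.branch2_forward(Xe, train_mode=False)
        assert out.shape == (3, 128)

    def test_branch2_wrong_shape_raises(self, model):
        with pytest.raises(ValueError):
            model.branch2_forward(Tensor(np.zeros((3, 41, 2))), train_mode=False)

    def test_branch2_repeatable(self, model):
        rng = np.random.default_rng(0)
        _, Xe = fake_inputs(rng)
        a = model.branch2_forward(Xe, train_mode=False)
        b = model.branch2_forward(Xe, train_mode=False)
        assert np.array_equal(a.data, b.data)


class TestEncodeAndHeads:
    def test_fused_dimension_is_256(self, model):
        rng = np.random.default_rng(0)
        enc = model.encode(fake_inputs(rng), train_mode=False)
        assert enc.h.shape == (3, 256)

    def test_branch_ablations_reduce_h(self):
        rng = np.random.default_rng(0)
        b1 = Model(ModelConfig(embed_dim=8, use_branch2=False, seed=0))
        b2 = Model(ModelConfig(embed_dim=8, use_branch1=False, seed=0))
        assert b1.encode(fake_inputs(rng), False).h.shape == (3, 128)
        assert b2.encode(fake_inputs(rng), False).h.shape == (3, 128)

    def test_projection_maps_to_p_dims(self, model):
        rng = np.random.default_rng(0)
        enc = model.encode(fake_inputs(rng), train_mode=False)
        z = model.project(enc.h).z
        assert z.shape == (3, 64)

    def test_large_p_warns(self):
        with pytest.warns(UserWarning, match="projection"):
            Model(ModelConfig(embed_dim=8, proj_dim=512, seed=0))

    def test_classifier_rows_sum_to_one(self, model):
        rng = np.random.default_rng(0)
        enc = model.encode(fake_inputs(rng), train_mode=False)
        probs = model.classify(enc.h).probs
        assert np.allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs.data >= 0)

    def test_zero_final_layer_gives_uniform_probs(self, model):
        model.cls_out.W.data[:] = 0.0
        model.cls_out.b.data[:] = 0.0
        rng = np.random.default_rng(0)
        enc = model.encode(fake_inputs(rng), train_mode=False)
        assert np.allclose(model.classify(enc.h).probs.data, 0.5)

    def test_eval_mode_argmax_stable(self, model):
        rng = np.random.default_rng(0)
        sample = fake_inputs(rng)
        p1 = model.forward_probs(sample, train_mode=False).data
        p2 = model.forward_probs(sample, train_mode=False).data
        assert np.array_equal(p1.argmax(axis=1), p2.argmax(axis=1))


class TestProjectionComplexity:
    def test_projected_similarity_needs_fewer_operations(self):
        # similarity on z costs O(B^2 P) + O(B D P) vs O(B^2 D) on h
        B, D, P = 256, 256, 64
        with_head = B * B * P + B * D * P
        without = B * B * D
        assert with_head < without


class TestVariants:
    @pytest.mark.parametrize(
        "name,b1,b2", [("cnn", True, False), ("cba_bil", True, True), ("s_bil", False, True)]
    )
    def test_variant_flags(self, name, b1, b2):
        cfg = variant_config(name, embed_dim=8)
        assert cfg.use_branch1 is b1
        assert cfg.use_branch2 is b2

    def test_contrastive_flag_follows_s_prefix(self):
        assert uses_contrastive("s_cba_bil")
        assert not uses_contrastive("cba_bil")

    def test_unknown_variant_raises(self):
        with pytest.raises(ValueError):
            variant_config("transformer")

    def test_cnn_variant_runs_without_lstm(self):
        m = Model(variant_config("cnn", embed_dim=8, seed=0))
        rng = np.random.default_rng(0)
        enc = m.encode(fake_inputs(rng), train_mode=False)
        assert enc.h.shape == (3, 64)  # conv filters


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, model):
        rng = np.random.default_rng(0)
        sample = fake_inputs(rng)
        before = model.forward_probs(sample, train_mode=False).data
        model.save(tmp_path / "ckpt.npz")
        other = Model(ModelConfig(embed_dim=8, conv_filters=16, hidden=64, seed=99))
        other.load_weights(tmp_path / "ckpt.npz")
        after = other.forward_probs(sample, train_mode=False).data
        assert np.allclose(before, after)

    def test_architecture_mismatch_raises(self, tmp_path, model):
        model.save(tmp_path / "ckpt.npz")
        other = Model(ModelConfig(embed_dim=16, conv_filters=16, hidden=64, seed=0))
        with pytest.raises(ValueError, match="mismatch"):
            other.load_weights(tmp_path / "ckpt.npz")
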