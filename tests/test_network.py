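"""Architecture contracts: shapes, sharing, boundedness, determinism."""

import numpy as np
import pytest

from cirf import losses as L
from cirf import network as N
from cirf._autodiff import Tensor, manual_seed
from cirf._autodiff.optim import Adam


def _rand_batch(rng, n, size):
    return rng.random((n, 1, size, size)).astype(np.float32)


@pytest.fixture
def rng32():
    return np.random.default_rng(32)


class TestEncoder:
    def test_base_and_detail_shapes(self, small_model, rng32):
        x = _rand_batch(rng32, 2, 64)
        out = small_model.encoder(x)
        assert out.base.shape == (2, 64, 64, 64)
        assert out.detail.shape == (2, 64, 64, 64)

    def test_rejects_indivisible_sizes(self, small_model, rng32):
        with pytest.raises(ValueError, match="32"):
            small_model.encoder(rng32.random((1, 1, 48, 48)).astype(np.float32))

    def test_eval_forward_deterministic(self, small_model, rng32):
        x = _rand_batch(rng32, 1, 64)
        a = small_model.encoder(x)
        b = small_model.encoder(x)
        assert np.array_equal(a.base.data, b.base.data)
        assert np.array_equal(a.detail.data, b.detail.data)

    def test_train_mode_dropout_reproducible_under_seed(self, rng32):
        manual_seed(5)
        model = N.FusionModel(N.ModelConfig.small(image_size=64))
        model.train()
        x = _rand_batch(rng32, 1, 64)
        manual_seed(99)
        a = model.encoder(x).base.data.copy()
        manual_seed(99)
        b = model.encoder(x).base.data.copy()
        assert np.array_equal(a, b)
        manual_seed(100)
        c = model.encoder(x).base.data
        assert not np.array_equal(a, c)

    def test_interact_detail_to_base_token_contract(self, small_model, rng32):
        enc = small_model.encoder
        detail = Tensor(rng32.random((1, 64, 32, 32)).astype(np.float32))
        tok = enc.interact_detail_to_base(detail)
        # token count matches the ViT grid of a 64x64 input (stem /2, patch 8)
        assert tok.shape == (1, 16, enc.cfg.vit_dim)

    def test_interaction_layernorm_statistics(self, small_model, rng32):
        enc = small_model.encoder
        tokens = Tensor(rng32.random((1, 16, 64)).astype(np.float32))
        normed = enc.d2b_norm[0](tokens)
        # gamma=1, beta=0 at init: per-token mean ~0, variance ~1
        assert np.abs(normed.data.mean(-1)).max() < 1e-4
        assert np.abs(normed.data.var(-1) - 1).max() < 1e-2

    def test_constant_map_layernorms_to_zero(self, small_model):
        enc = small_model.encoder
        const = Tensor(np.full((1, 64, 32, 32), 0.7, dtype=np.float32))
        tok = enc.interact_detail_to_base(const)
        # zero-variance tokens collapse to the (zero-init) bias after norm
        assert np.abs(tok.data).max() < 1e-2

    def test_interact_base_to_detail_shape_and_constants(self, small_model, rng32):
        enc = small_model.encoder
        enc.eval()
        tokens = Tensor(np.full((1, 16, enc.cfg.vit_dim), 0.5, dtype=np.float32))
        out = enc.interact_base_to_detail(tokens, (4, 4))
        assert out.shape == (1, 64, 32, 32)
        # constant tokens -> constant map before normalisation: bilinear
        # interpolation preserves constants, so spatial variance ~ 0
        spatial_std = out.data.std(axis=(2, 3))
        assert spatial_std.max() < 1e-5

    def test_batchnorm_train_vs_eval_differ(self, rng32):
        manual_seed(3)
        model = N.FusionModel(N.ModelConfig.small(image_size=64))
        enc = model.encoder
        tokens = Tensor(rng32.random((2, 16, enc.cfg.vit_dim)).astype(np.float32))
        model.train()
        a = enc.interact_base_to_detail(tokens, (4, 4)).data.copy()
        model.eval()
        b = enc.interact_base_to_detail(tokens, (4, 4)).data
        assert not np.allclose(a, b)


class TestFusionBlocks:
    def test_bfb_shape_preserving_and_deterministic(self, small_model, rng32):
        x = Tensor(rng32.random((1, 64, 32, 32)).astype(np.float32))
        out1 = small_model.bfb(x)
        out2 = small_model.bfb(x)
        assert out1.shape == (1, 64, 32, 32)
        assert np.array_equal(out1.data, out2.data)
        zero = Tensor(np.zeros((1, 64, 32, 32), dtype=np.float32))
        z1 = small_model.bfb(zero).data
        z2 = small_model.bfb(zero).data
        assert np.array_equal(z1, z2)

    def test_bfb_attention_rows_sum_to_one(self, small_model, rng32):
        x = Tensor(rng32.random((1, 64, 32, 32)).astype(np.float32))
        small_model.bfb(x)
        attn = small_model.bfb.attn.last_attn
        assert np.abs(attn.sum(-1) - 1.0).max() < 1e-6

    def test_dfb_output_bounded_even_for_scaled_inputs(self, rng32):
        manual_seed(11)
        dfb = N.DetailFusionBlock(N.ModelConfig.small())
        for seed in range(5):
            g = np.random.default_rng(seed)
            x = g.standard_normal((2, 64, 32, 32)).astype(np.float32)
            for scale in (1.0, 100.0):
                out = dfb(Tensor(x * scale)).data
                assert out.max() <= 6.0
                assert out.min() >= 0.0

    def test_dfb_residual_line_is_live(self, rng32):
        manual_seed(12)
        dfb = N.DetailFusionBlock(N.ModelConfig.small())
        x = Tensor(rng32.random((1, 64, 32, 32)).astype(np.float32))
        with_res = dfb(x).data.copy()
        dfb.use_residual = False
        without = dfb(x).data
        assert not np.allclose(with_res, without)
        dfb.use_residual = True
        # gradient flows through the residual convolution
        xt = Tensor(rng32.random((1, 64, 32, 32)).astype(np.float32),
                    requires_grad=True)
        dfb(xt).sum().backward()
        assert dfb.residual.layers[0].weight.grad is not None
        assert np.abs(dfb.residual.layers[0].weight.grad).max() > 0


class TestDecoders:
    def test_decoder_shape_range_determinism(self, small_model, rng32):
        feats = Tensor(rng32.standard_normal((2, 128, 32, 32)).astype(np.float32))
        out1 = small_model.dfd(feats)
        out2 = small_model.dfd(feats)
        assert out1.shape == (2, 1, 32, 32)
        assert out1.data.min() >= 0.0 and out1.data.max() <= 1.0
        assert np.array_equal(out1.data, out2.data)

    def test_wrong_channel_count_rejected(self, small_model, rng32):
        with pytest.raises(ValueError):
            small_model.dfd(Tensor(rng32.random((1, 64, 16, 16)).astype(np.float32)))

    def test_fusion_and_reconstruction_decoders_are_disjoint(self, small_model):
        dfd_ids = {id(p) for p in small_model.dfd.parameters()}
        drd_ids = {id(p) for p in small_model.drd.parameters()}
        assert dfd_ids.isdisjoint(drd_ids)


class TestFullModel:
    @pytest.mark.parametrize("n,size", [(1, 32), (2, 64), (4, 96)])
    def test_fusion_shape_contract(self, n, size, rng32):
        manual_seed(21)
        model = N.FusionModel(N.ModelConfig.small(image_size=96))
        t1 = _rand_batch(rng32, n, size)
        t2 = _rand_batch(rng32, n, size)
        out = model.fuse(t1, t2)
        assert out.shape == (n, 1, size, size)
        assert np.isfinite(out).all() and out.min() >= 0 and out.max() <= 1

    def test_fuse_swap_symmetric_exactly(self, small_model, rng32):
        t1 = _rand_batch(rng32, 2, 64)
        t2 = _rand_batch(rng32, 2, 64)
        assert np.array_equal(small_model.fuse(t1, t2), small_model.fuse(t2, t1))

    def test_reconstruction_branch_cut_at_inference(self, small_model, rng32):
        small_model.drd.n_calls = 0
        small_model.fuse(_rand_batch(rng32, 1, 64), _rand_batch(rng32, 1, 64))
        assert small_model.drd.n_calls == 0

    def test_encoder_is_shared_between_branches(self, small_model, rng32):
        t = Tensor(_rand_batch(rng32, 1, 64))
        enc_params = {id(p) for p in small_model.encoder.parameters()}
        all_named = dict(small_model.named_parameters())
        reachable = {id(p) for n, p in all_named.items() if n.startswith("encoder.")}
        assert enc_params == reachable
        # the registry holds the encoder exactly once
        names = [n for n in all_named if n.startswith("encoder.")]
        assert len(names) == len(set(names))

    def test_masked_reconstruction_uses_masked_input(self, small_model, rng32):
        t = _rand_batch(rng32, 1, 64)
        r0 = small_model.reconstruct(t, mask_ratio=0.0).data
        r1 = small_model.reconstruct(t, mask_ratio=0.5, seed=1).data
        assert not np.allclose(r0, r1)
        assert r0.shape == (1, 1, 64, 64)

    def test_gradient_liveness_all_parameters(self, rng32):
        """Every registered parameter gets a nonzero gradient from the
        combined loss at sigma=0.5 (dead-path detector)."""
        manual_seed(17)
        model = N.FusionModel(N.ModelConfig.small(image_size=32))
        model.train()
        w = L.LossWeights(sigma=0.5, mask_ratio=0.0)
        t1 = Tensor(_rand_batch(rng32, 2, 32))
        t2 = Tensor(_rand_batch(rng32, 2, 32))
        fused = model.forward_fusion(t1, t2)
        r1 = model.reconstruct(t1)
        r2 = model.reconstruct(t2)
        loss1 = L.total_rec_loss(L.rec_loss(r1, t1, w), L.rec_loss(r2, t2, w), w)
        loss2, _ = L.fusion_loss(t1, t2, fused, w)
        L.total_loss(loss1, loss2, w).backward()
        dead = [name for name, p in model.named_parameters()
                if p.grad is None or not np.abs(p.grad).max() > 0]
        assert dead == []

    def test_checkpoint_round_trip(self, tmp_path, small_model, rng32):
        path = tmp_path / "model.npz"
        N.save_model(small_model, path)
        loaded = N.load_model(path)
        loaded.eval()
        t1 = _rand_batch(rng32, 1, 64)
        t2 = _rand_batch(rng32, 1, 64)
        assert np.array_equal(small_model.fuse(t1, t2), loaded.fuse(t1, t2))
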