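import math

import numpy as np
import pytest

from mufrf._autodiff import Tensor
from mufrf.fusion import (AttentionParams, AutoencoderParams, ConvParams,
                          FusionParams, adaptive_avg_pool_matrix,
                          ae_reconstruction_loss, attention_weights, concat_level,
                          fuse_latents, fusion_forward_t, multi_head_attention,
                          scalar_level)


@pytest.fixture
def views(rng):
    return rng.normal(size=(7, 100)), rng.normal(size=(7, 100))


@pytest.fixture
def conv_row(rng):
    return ConvParams.init("row_stack", rng)


@pytest.fixture
def conv_col(rng):
    return ConvParams.init("col_stack", rng)


@pytest.fixture
def ae(rng):
    return AutoencoderParams.init(rng)


class TestConcatLevel:
    @pytest.mark.parametrize("n", [1, 7, 64])
    @pytest.mark.parametrize("mode", ["row_stack", "col_stack"])
    def test_output_width_twenty(self, rng, n, mode):
        params = ConvParams.init(mode, rng)
        hg, eh = rng.normal(size=(n, 100)), rng.normal(size=(n, 100))
        lf = concat_level(hg, eh, mode, params)
        assert lf.matrix.shape == (n, 20)
        assert lf.branch_tag == ("LF1" if mode == "row_stack" else "LF2")

    def test_zero_weights_zero_latent(self, views, conv_row):
        for t in conv_row.tensors():
            t.data[...] = 0.0
        lf = concat_level(*views, "row_stack", conv_row)
        assert np.all(lf.matrix == 0.0)

    def test_per_drug_independence(self, rng, conv_row):
        # changing drug 0's views must not change drug 1's latent
        hg, eh = rng.normal(size=(2, 100)), rng.normal(size=(2, 100))
        base = concat_level(hg, eh, "row_stack", conv_row).matrix
        hg2 = hg.copy()
        hg2[0] += 5.0
        pert = concat_level(hg2, eh, "row_stack", conv_row).matrix
        assert np.allclose(base[1], pert[1])
        assert not np.allclose(base[0], pert[0])

    def test_wrong_width_rejected(self, rng, conv_row):
        with pytest.raises(ValueError, match="n×100"):
            concat_level(rng.normal(size=(3, 50)), rng.normal(size=(3, 50)),
                         "row_stack", conv_row)

    def test_mode_params_mismatch_rejected(self, views, conv_col):
        with pytest.raises(ValueError, match="initialized for mode"):
            concat_level(*views, "row_stack", conv_col)

    def test_adaptive_pool_matrix_averages(self):
        m = adaptive_avg_pool_matrix(6, 3)
        x = np.arange(6.0)
        assert np.allclose(x @ m, [0.5, 2.5, 4.5])
        assert np.allclose(m.sum(axis=0), 1.0)


class TestScalarLevel:
    def test_add_with_zero_kg_equals_encoder_of_structure(self, rng, ae):
        hg = rng.normal(size=(5, 100))
        lf = scalar_level(hg, np.zeros_like(hg), "add", ae)
        direct = scalar_level(hg, np.zeros_like(hg), "add", ae)
        assert np.array_equal(lf.matrix, direct.matrix)
        assert lf.branch_tag == "LF3"
        # additive identity: same as encoding hg + 0
        both = scalar_level(hg / 2, hg / 2, "add", ae)
        assert np.allclose(lf.matrix, both.matrix)

    def test_product_with_ones_equals_encoder_of_structure(self, rng, ae):
        hg = rng.normal(size=(4, 100))
        via_product = scalar_level(hg, np.ones_like(hg), "product", ae)
        via_add = scalar_level(hg, np.zeros_like(hg), "add", ae)
        assert np.allclose(via_product.matrix, via_add.matrix)
        assert via_product.branch_tag == "LF4"

    @pytest.mark.parametrize("n", [1, 7, 64])
    def test_latent_dimension(self, rng, ae, n):
        lf = scalar_level(rng.normal(size=(n, 100)), rng.normal(size=(n, 100)),
                          "add", ae)
        assert lf.matrix.shape == (n, 20)

    def test_widths_contract(self, ae):
        assert ae.widths == (100, 60, 20, 60, 100)

    def test_reconstruction_loss_nonnegative_and_hand_case(self, rng, ae):
        x = rng.normal(size=(3, 100))
        assert ae_reconstruction_loss(x, ae) > 0.0
        # hand-computable: all-zero autoencoder reconstructs 0, so the loss
        # is mean(x²)
        for t in ae.tensors():
            t.data[...] = 0.0
        assert ae_reconstruction_loss(x, ae) == pytest.approx(np.mean(x ** 2), rel=1e-12)


class TestFuseLatents:
    def test_lf5_is_sum_and_blocks_recover_inputs(self, rng, conv_row, conv_col, ae):
        hg, eh = rng.normal(size=(6, 100)), rng.normal(size=(6, 100))
        lf1 = concat_level(hg, eh, "row_stack", conv_row)
        lf2 = concat_level(hg, eh, "col_stack", conv_col)
        lf3 = scalar_level(hg, eh, "add", ae)
        lf4 = scalar_level(hg, eh, "product", ae)
        fused = fuse_latents(lf1, lf2, lf3, lf4)
        assert fused.X.shape == (6, 100)
        assert np.array_equal(fused.X[:, :20], lf1.matrix)
        assert np.array_equal(fused.X[:, 60:80], lf4.matrix)
        assert np.allclose(fused.X[:, 80:],
                           lf1.matrix + lf2.matrix + lf3.matrix + lf4.matrix)

    def test_equal_inputs_quadruple(self, rng, ae):
        hg = rng.normal(size=(3, 100))
        lf = scalar_level(hg, np.zeros_like(hg), "add", ae)
        lf_copies = [type(lf)(lf.matrix, tag) for tag in ("LF1", "LF2", "LF3", "LF4")]
        fused = fuse_latents(*lf_copies)
        assert np.allclose(fused.X[:, 80:], 4 * lf.matrix)


class TestMultiHeadAttention:
    def test_four_heads_width_25(self, rng):
        params = AttentionParams.init(4, rng)
        assert params.d_k == 25
        assert params.wq[0].shape == (100, 25)

    def test_two_heads_width_50(self, rng):
        assert AttentionParams.init(2, rng).d_k == 50

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            AttentionParams.init(3, rng)

    @pytest.mark.parametrize("n", [1, 7, 64])
    def test_shape_preserved(self, rng, n):
        params = AttentionParams.init(4, rng)
        x = rng.normal(size=(n, 100))
        assert multi_head_attention(x, params).shape == (n, 100)

    def test_single_token_attention_is_one(self, rng):
        params = AttentionParams.init(2, rng)
        weights = attention_weights(rng.normal(size=(1, 100)), params)
        for w in weights:
            assert np.allclose(w, [[1.0]])

    def test_rows_sum_to_one(self, rng):
        params = AttentionParams.init(4, rng)
        for w in attention_weights(rng.normal(size=(9, 100)), params):
            assert np.allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_two_token_scalar_softmax_oracle(self, rng):
        # brute-force scalar arithmetic, independent of the tensor path
        params = AttentionParams.init(2, rng)
        x = rng.normal(size=(2, 100))
        for i in range(params.n_heads):
            q = x @ params.wq[i].data
            k = x @ params.wk[i].data
            expected = np.empty((2, 2))
            for a in range(2):
                logits = [sum(q[a, d] * k[b, d] for d in range(q.shape[1]))
                          / math.sqrt(params.d_k) for b in range(2)]
                z = max(logits)
                exps = [math.exp(l - z) for l in logits]
                expected[a] = np.array(exps) / sum(exps)
            assert np.allclose(attention_weights(x, params)[i], expected, atol=1e-12)


class TestFusionPipeline:
    @pytest.mark.parametrize("n", [1, 7, 64])
    def test_shape_conservation_end_to_end(self, rng, n):
        params = FusionParams.init(2, rng)
        hg = Tensor(rng.normal(size=(n, 100)))
        eh = Tensor(rng.normal(size=(n, 100)))
        x_att, recon = fusion_forward_t(hg, eh, params)
        assert x_att.shape == (n, 100)
        assert float(recon.data) >= 0.0

    @pytest.mark.parametrize("tag", ["c0", "c1", "add", "product", "attn"])
    def test_single_branch_ablation_still_runs(self, rng, tag):
        params = FusionParams.init(2, rng, disabled=(tag,))
        hg = Tensor(rng.normal(size=(5, 100)))
        eh = Tensor(rng.normal(size=(5, 100)))
        x_att, _ = fusion_forward_t(hg, eh, params)
        assert x_att.shape == (5, 100)
        assert np.all(np.isfinite(x_att.data))

    def test_unknown_ablation_tag_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown ablation"):
            FusionParams.init(2, rng, disabled=("bogus",))
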