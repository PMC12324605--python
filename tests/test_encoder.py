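"""Token construction, masking rules, encoding symmetries, batch-token
integration, and the masked-reconstruction objective."""

import numpy as np
import pytest

import protomap as pm
from protomap.encoder import (EncoderModel, build_tokens, encode,
                              integrate_batch_token, mask_tokens,
                              masked_reconstruction_loss)
from protomap.nn.autograd import Tensor


@pytest.fixture()
def plain_model():
    cfg = pm.EncoderConfig(d=16, n_layers=1, n_heads=2, use_ppi=False, seed=0)
    return EncoderModel([f"g{i}" for i in range(12)], cfg, n_datasets=2)


class TestBuildTokens:
    def test_without_ppi_token_is_expression_projection_alone(self, plain_model):
        x = np.linspace(0, 1, 12)[None, :]
        batch = build_tokens(x, plain_model.feature_ids, plain_model)
        expected = plain_model.expr_projection(Tensor(x[..., None])).data
        assert np.allclose(batch.G.data[:, 1:, :], expected)

    def test_zero_value_zero_bias_gives_zero_token(self, plain_model):
        plain_model.expr_projection.bias.data[:] = 0
        batch = build_tokens(np.zeros((1, 12)), plain_model.feature_ids,
                             plain_model)
        assert np.allclose(batch.G.data[:, 1:, :], 0)

    def test_equal_values_give_identical_token_rows(self, plain_model):
        x = np.full((1, 12), 0.5)
        batch = build_tokens(x, plain_model.feature_ids, plain_model)
        rows = batch.G.data[0, 1:, :]
        assert np.allclose(rows, rows[0])

    def test_ppi_adds_adapted_identity(self, tiny_encoder):
        model, table, _ = tiny_encoder
        x = np.full((1, len(model.feature_ids)), 0.3)
        batch = build_tokens(x, model.feature_ids, model)
        rows = batch.G.data[0, 1:, :]
        assert not np.allclose(rows, rows[0])  # PPI vectors distinguish tokens

    def test_non_finite_input_rejected(self, plain_model):
        x = np.zeros((1, 12))
        x[0, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            build_tokens(x, plain_model.feature_ids, plain_model)

    def test_truncation_keeps_highest_variance_features(self):
        cfg = pm.EncoderConfig(d=16, n_layers=0, n_heads=2, use_ppi=False,
                               max_tokens=3, seed=0)
        model = EncoderModel([f"g{i}" for i in range(6)], cfg)
        rng = np.random.default_rng(0)
        X = np.zeros((10, 6))
        X[:, [1, 4, 5]] = rng.uniform(size=(10, 3))  # only these vary
        batch = build_tokens(X, model.feature_ids, model)
        assert list(batch.feature_positions) == [1, 4, 5]


class TestMasking:
    def test_thirty_percent_of_ten_masks_three(self, plain_model):
        x = np.random.default_rng(0).uniform(size=(4, 10))
        batch = build_tokens(x, plain_model.feature_ids[:10], plain_model)
        masked = mask_tokens(batch, 0.3, 0, plain_model)
        assert masked.mask_indices.shape == (4, 3)

    def test_same_seed_same_mask(self, plain_model):
        x = np.random.default_rng(0).uniform(size=(4, 12))
        batch = build_tokens(x, plain_model.feature_ids, plain_model)
        m1 = mask_tokens(batch, 0.3, 5, plain_model)
        m2 = mask_tokens(batch, 0.3, 5, plain_model)
        assert np.array_equal(m1.mask_indices, m2.mask_indices)

    def test_cls_and_pad_positions_never_masked(self, plain_model):
        x = np.random.default_rng(0).uniform(size=(8, 12))
        batch = build_tokens(x, plain_model.feature_ids, plain_model, n_pad=4)
        masked = mask_tokens(batch, 0.4, 1, plain_model)
        assert masked.mask_indices.min() >= 1
        assert masked.mask_indices.max() <= 12  # never into the pad block

    def test_masked_rows_carry_mask_token(self, plain_model):
        x = np.random.default_rng(0).uniform(size=(2, 12))
        batch = build_tokens(x, plain_model.feature_ids, plain_model)
        masked = mask_tokens(batch, 0.25, 2, plain_model)
        for b in range(2):
            for col in masked.mask_indices[b]:
                assert np.allclose(masked.G.data[b, col],
                                   plain_model.mask_token.data, atol=1e-6)

    def test_zero_mask_count_rejected(self, plain_model):
        x = np.random.default_rng(0).uniform(size=(1, 12))
        batch = build_tokens(x, plain_model.feature_ids, plain_model)
        with pytest.raises(ValueError, match="zero"):
            mask_tokens(batch, 0.01, 0, plain_model)


class TestEncode:
    def test_zero_layer_transformer_is_identity(self):
        cfg = pm.EncoderConfig(d=16, n_layers=0, n_heads=2, use_ppi=False,
                               seed=0)
        model = EncoderModel([f"g{i}" for i in range(5)], cfg)
        x = np.random.default_rng(1).uniform(size=(3, 5))
        batch = build_tokens(x, model.feature_ids, model)
        H, _ = encode(batch, model)
        assert np.allclose(H.data, batch.G.data)

    def test_permutation_equivariance_without_positional_encodings(self, plain_model):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=(2, 12))
        perm = rng.permutation(12)
        b1 = build_tokens(x, plain_model.feature_ids, plain_model)
        b2 = build_tokens(x[:, perm],
                          [plain_model.feature_ids[j] for j in perm], plain_model)
        H1, c1 = encode(b1, plain_model)
        H2, c2 = encode(b2, plain_model)
        assert np.allclose(H1.data[:, 1:, :][:, perm, :], H2.data[:, 1:, :],
                           atol=1e-5)
        assert np.allclose(c1.data, c2.data, atol=1e-5)

    def test_pad_tokens_do_not_influence_pooled_embedding(self, plain_model):
        x = np.random.default_rng(3).uniform(size=(2, 12))
        c_plain = encode(build_tokens(x, plain_model.feature_ids, plain_model),
                         plain_model)[1]
        c_padded = encode(build_tokens(x, plain_model.feature_ids, plain_model,
                                       n_pad=7), plain_model)[1]
        assert np.allclose(c_plain.data, c_padded.data, atol=1e-6)

    def test_exact_and_linear_attention_agree_on_pooled_embedding(self):
        ids = [f"g{i}" for i in range(10)]
        x = np.random.default_rng(4).uniform(size=(3, 10))
        pooled = {}
        for kind in ("exact", "linear_favor"):
            cfg = pm.EncoderConfig(d=16, n_layers=1, n_heads=2, use_ppi=False,
                                   attention_kind=kind, seed=0)
            model = EncoderModel(ids, cfg)
            _, c = encode(build_tokens(x, ids, model), model)
            pooled[kind] = c.data
        for a, b in zip(pooled["exact"], pooled["linear_favor"]):
            cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            assert 1 - cos < 1e-2

    def test_dimension_mismatch_rejected(self, plain_model):
        other = EncoderModel(["g0"], pm.EncoderConfig(d=32, n_layers=0,
                                                      n_heads=2, use_ppi=False))
        x = np.random.default_rng(0).uniform(size=(1, 12))
        batch = build_tokens(x, plain_model.feature_ids, plain_model)
        with pytest.raises(ValueError, match="dimension"):
            encode(batch, other)


class TestBatchToken:
    def test_hand_arithmetic(self, plain_model):
        plain_model.alpha.data = np.array(2.0)
        plain_model.batch_token_table.data[1, :2] = [0.5, 1.0]
        plain_model.batch_token_table.data[1, 2:] = 0
        c = Tensor(np.array([[1.0, 0.0] + [0.0] * 14]))
        z = integrate_batch_token(c, np.array([1]), plain_model)
        assert np.allclose(z.data[0, :2], [2.0, 2.0])

    def test_zero_alpha_or_zero_token_is_identity(self, plain_model):
        c = Tensor(np.random.default_rng(0).standard_normal((2, 16)))
        plain_model.alpha.data = np.array(0.0)
        z = integrate_batch_token(c, np.array([0, 1]), plain_model)
        assert np.allclose(z.data, c.data)
        plain_model.alpha.data = np.array(1.0)
        plain_model.batch_token_table.data[:] = 0
        z = integrate_batch_token(c, np.array([0, 1]), plain_model)
        assert np.allclose(z.data, c.data)

    def test_unknown_dataset_strict_raises_lenient_warns(self, plain_model):
        c = Tensor(np.ones((1, 16)))
        with pytest.raises(KeyError, match="unknown dataset"):
            integrate_batch_token(c, np.array([5]), plain_model)
        with pytest.warns(UserWarning, match="unseen dataset"):
            z = integrate_batch_token(c, np.array([5]), plain_model,
                                      strict=False)
        assert np.allclose(z.data, c.data)  # zero batch vector

    def test_disabled_batch_token_is_identity(self):
        cfg = pm.EncoderConfig(d=16, n_layers=0, n_heads=2, use_ppi=False,
                               use_batch_token=False, seed=0)
        model = EncoderModel(["g0"], cfg)
        c = Tensor(np.ones((1, 16)))
        z = integrate_batch_token(c, np.array([3]), model)
        assert z is c


class TestPretraining:
    def test_loss_uses_masked_positions_only(self, plain_model):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=(6, 12))
        batch = build_tokens(x, plain_model.feature_ids, plain_model)
        masked = mask_tokens(batch, 0.25, 3, plain_model)
        base = masked_reconstruction_loss(plain_model, masked,
                                          np.zeros(6, int)).item()
        # perturb original values at every UNmasked position
        perturbed = masked.original_values.copy()
        mask = np.zeros_like(perturbed, dtype=bool)
        np.put_along_axis(mask, masked.mask_indices - 1, True, axis=1)
        perturbed[~mask] += 123.0
        masked.original_values = perturbed
        after = masked_reconstruction_loss(plain_model, masked,
                                           np.zeros(6, int)).item()
        assert after == pytest.approx(base, abs=1e-12)

    def test_toggles_change_parameter_count_by_component_sizes(self, small_normalized):
        cfg, rnan, _, _ = small_normalized
        edges = pm.simulate_ppi(cfg.n_genes, 3, 0.4, 0.02, seed=3)
        table, _ = pm.embed_graph(edges, d_ppi=16, seed=3, n_epochs=2)
        base = pm.EncoderConfig(d=16, n_layers=1, n_heads=2, seed=0)
        vocab = rnan.feature_ids
        full = EncoderModel(vocab, base, n_datasets=2, ppi_table=table)
        no_ppi = EncoderModel(vocab, pm.EncoderConfig(**{**base.__dict__,
                                                         "use_ppi": False}),
                              n_datasets=2, ppi_table=table)
        no_batch = EncoderModel(vocab, pm.EncoderConfig(**{**base.__dict__,
                                                           "use_batch_token": False}),
                                n_datasets=2, ppi_table=table)
        adapter_size = 16 * 16 + 16       # weight + bias
        table_size = 2 * 16               # one row per dataset
        assert full.n_parameters() - no_ppi.n_parameters() == adapter_size
        assert full.n_parameters() - no_batch.n_parameters() == table_size

    def test_unnormalized_data_rejected(self, small_sim):
        _, rna, _, _ = small_sim
        with pytest.raises(ValueError, match="normalized"):
            pm.pretrain([rna], pm.EncoderConfig(d=16, n_heads=2, n_epochs=1))

    def test_short_pretraining_reduces_loss(self, tiny_encoder):
        _, _, trace = tiny_encoder
        assert trace[-1] < trace[0]

    def test_checkpoint_round_trip_preserves_embeddings(self, tiny_encoder,
                                                        small_normalized,
                                                        tmp_path):
        model, _, _ = tiny_encoder
        _, rnan, _, _ = small_normalized
        model.save(tmp_path / "enc.h5")
        back = EncoderModel.load(tmp_path / "enc.h5")
        e1 = pm.encode_cells(model, rnan).Z
        e2 = pm.encode_cells(back, rnan).Z
        assert np.allclose(e1, e2, atol=1e-6)
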