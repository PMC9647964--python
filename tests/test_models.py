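"""Attention mechanisms and the assembled architecture variants."""

import numpy as np
import pytest

from peptox.autodiff import Tensor, no_grad
from peptox.blosum import encode_batch
from peptox.models import (
    ConfigError,
    EncoderConfig,
    EvolutionaryEncoder,
    MultiHeadAttention,
    channel_attention_cnn,
    channel_attention_gru,
    cnn_bigru_forward,
    self_attention,
)
from peptox.nn import MLP, BiGRU, masked_mean_pool
from peptox.pipeline import assemble_variant
from peptox.sequence_io import STANDARD_AA, SequenceRecord, SyntheticDatasetSpec, generate_synthetic_dataset


def np_softmax(x, axis=-1):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def zero_mlp(mlp: MLP) -> MLP:
    for p in mlp.parameters():
        p.data[...] = 0.0
    return mlp


class TestSelfAttention:
    def test_single_key_value_returns_value(self, rng):
        q = Tensor(rng.normal(size=(3, 4)))
        k = Tensor(rng.normal(size=(1, 4)))
        v = Tensor(rng.normal(size=(1, 6)))
        out, w = self_attention(q, k, v)
        np.testing.assert_allclose(out.data, np.repeat(v.data, 3, axis=0))
        np.testing.assert_allclose(w.data, 1.0)

    def test_identical_keys_give_uniform_mean(self, rng):
        q = Tensor(rng.normal(size=(2, 4)))
        k = Tensor(np.tile(rng.normal(size=(1, 4)), (5, 1)))
        v = Tensor(rng.normal(size=(5, 3)))
        out, w = self_attention(q, k, v)
        np.testing.assert_allclose(w.data, 0.2)
        np.testing.assert_allclose(out.data, np.tile(v.data.mean(axis=0), (2, 1)))

    def test_two_token_hand_computation(self):
        Q = np.array([[1.0, 0.0], [0.0, 2.0]])
        K = np.array([[1.0, 1.0], [2.0, 0.0]])
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        scale = 1.0 / np.sqrt(2.0)
        expected = np_softmax(Q @ K.T * scale) @ V
        out, w = self_attention(Tensor(Q), Tensor(K), Tensor(V))
        np.testing.assert_allclose(out.data, expected, rtol=1e-12)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            self_attention(
                Tensor(rng.normal(size=(2, 3))),
                Tensor(rng.normal(size=(2, 4))),
                Tensor(rng.normal(size=(2, 4))),
            )

    def test_masked_keys_get_zero_weight(self, rng):
        q = Tensor(rng.normal(size=(1, 2, 4)))
        kv = Tensor(rng.normal(size=(1, 3, 4)))
        mask = np.array([[1.0, 1.0, 0.0]])
        _, w = self_attention(q, kv, kv, key_mask=mask[:, None, :])
        assert np.all(w.data[..., 2] < 1e-12)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)


class TestMultiHeadAttention:
    def test_matches_explicit_per_head_decomposition(self, rng):
        d, h, L = 12, 3, 5
        mha = MultiHeadAttention(rng, d, h)
        x = rng.normal(size=(2, L, d))
        with no_grad():
            out, _ = mha(Tensor(x))
        dk = d // h
        q_all = x @ mha.Wq.W.data
        k_all = x @ mha.Wk.W.data
        v_all = x @ mha.Wv.W.data
        heads = []
        for i in range(h):
            sl = slice(i * dk, (i + 1) * dk)
            q, k, v = q_all[..., sl], k_all[..., sl], v_all[..., sl]
            scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(dk)
            heads.append(np_softmax(scores) @ v)
        expected = np.concatenate(heads, axis=-1) @ mha.Wo.W.data
        np.testing.assert_allclose(out.data, expected, rtol=1e-10)

    def test_single_head_reduces_to_self_attention(self, rng):
        d = 6
        mha = MultiHeadAttention(rng, d, 1)
        x = Tensor(rng.normal(size=(1, 4, d)))
        with no_grad():
            out, _ = mha(x)
            q, k, v = mha.Wq(x), mha.Wk(x), mha.Wv(x)
            ref, _ = self_attention(q, k, v, scale=1.0 / np.sqrt(d))
            ref = mha.Wo(ref)
        np.testing.assert_allclose(out.data, ref.data, rtol=1e-12)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ConfigError):
            MultiHeadAttention(rng, 10, 3)
        with pytest.raises(ConfigError):
            EncoderConfig(d_model=10, n_heads=3)


class TestChannelAttention:
    def test_zero_mlp_gives_half_gates(self, rng):
        maps = Tensor(rng.normal(size=(2, 6, 4)))
        mlp = zero_mlp(MLP(rng, [4, 2, 4]))
        gated, gates = channel_attention_cnn(maps, mlp)
        np.testing.assert_allclose(gates.data, 0.5)
        np.testing.assert_allclose(gated.data, 0.5 * maps.data)

    def test_gates_strictly_in_unit_interval(self, rng):
        maps = Tensor(rng.normal(size=(3, 5, 8)) * 10)
        _, gates = channel_attention_cnn(maps, MLP(rng, [8, 4, 8]))
        assert np.all(gates.data > 0) and np.all(gates.data < 1)

    def test_two_channel_hand_computation(self, rng):
        maps_data = rng.normal(size=(1, 4, 2))
        mlp = MLP(rng, [2, 2])  # single affine layer
        W, b = mlp.layers[0].W.data, mlp.layers[0].b.data
        gated, gates = channel_attention_cnn(Tensor(maps_data), mlp)
        pooled = maps_data.mean(axis=1)  # (1, 2)
        expected_gates = 1.0 / (1.0 + np.exp(-(pooled @ W + b)))
        np.testing.assert_allclose(gates.data, expected_gates, rtol=1e-12)
        np.testing.assert_allclose(
            gated.data, maps_data * expected_gates[:, None, :], rtol=1e-12
        )

    def test_gru_gate_selection(self, rng):
        # an MLP pushed to saturation selects a single hidden layer
        hidden = [Tensor(rng.normal(size=(2, 4))) for _ in range(4)]
        mlp = MLP(rng, [4, 1])
        mlp.layers[0].W.data[...] = 0.0
        mlp.layers[0].b.data[...] = -60.0
        out0, gates0 = channel_attention_gru(hidden, mlp)
        np.testing.assert_allclose(out0.data, 0.0, atol=1e-20)
        assert np.all(gates0.data < 1e-20)

    def test_gru_weighted_sum_assembly(self, rng):
        hidden = [Tensor(rng.normal(size=(3, 5))) for _ in range(4)]
        mlp = MLP(rng, [5, 3, 1])
        out, gates = channel_attention_gru(hidden, mlp)
        manual = sum(
            gates.data[:, l : l + 1] * hidden[l].data for l in range(4)
        )
        np.testing.assert_allclose(out.data, manual, rtol=1e-12)
        assert np.all((gates.data > 0) & (gates.data < 1))

    def test_toy_two_dim_hand_computation(self):
        h1 = Tensor(np.array([[1.0, 2.0]]))
        h2 = Tensor(np.array([[3.0, -1.0]]))
        rng = np.random.default_rng(0)
        mlp = MLP(rng, [2, 1])
        mlp.layers[0].W.data[:] = np.array([[1.0], [0.5]])
        mlp.layers[0].b.data[:] = 0.0
        out, gates = channel_attention_gru([h1, h2], mlp)
        g1 = 1 / (1 + np.exp(-(1.0 + 1.0)))  # w.h1 = 1*1 + 0.5*2
        g2 = 1 / (1 + np.exp(-(3.0 - 0.5)))
        np.testing.assert_allclose(gates.data, [[g1, g2]], rtol=1e-12)
        np.testing.assert_allclose(
            out.data, g1 * h1.data + g2 * h2.data, rtol=1e-12
        )


def _records(n, seed=0, lengths=(8, 20)):
    spec = SyntheticDatasetSpec(n, n, lengths, "KWK", 1.0, seed=seed)
    return generate_synthetic_dataset(spec)


class TestEncoderVariants:
    def test_default_dimensions(self):
        assert EncoderConfig().evolutionary_dim == 2048
        assert EncoderConfig(variant="channel_attention").evolutionary_dim == 512
        cfg = EncoderConfig(variant="transformer")
        assert (cfg.n_heads, cfg.head_dim, cfg.n_encoder_layers, cfg.ffn_dim) == (8, 64, 6, 2048)

    def test_dimension_formula_follows_config(self, rng, tiny_config):
        # bidirectional concat of final states: 2 directions x layers x hidden
        enc = EvolutionaryEncoder(tiny_config, rng)
        recs = _records(2)
        blosum, mask = encode_batch(recs, max_len=tiny_config.max_len)
        with no_grad():
            feat, _ = enc(blosum, mask)
        assert feat.shape == (4, 2 * tiny_config.gru_layers * tiny_config.gru_hidden)

    def test_cnn_bigru_forward_helper(self, tiny_config):
        recs = _records(1)[:1]
        blosum, mask = encode_batch(recs, max_len=tiny_config.max_len)
        with no_grad():
            feat = cnn_bigru_forward(blosum, mask, config=tiny_config)
        assert feat.shape == (1, tiny_config.evolutionary_dim)

    def test_batch_item_independence_in_eval(self, rng, tiny_config):
        enc = EvolutionaryEncoder(tiny_config, rng)
        recs = _records(3)
        blosum, mask = encode_batch(recs, max_len=tiny_config.max_len)
        with no_grad():
            batched, _ = enc(blosum, mask)
            single, _ = enc(blosum[1:2], mask[1:2])
        np.testing.assert_allclose(batched.data[1], single.data[0], rtol=1e-10)

    def test_forward_deterministic_under_fixed_weights(self, tiny_config):
        enc = EvolutionaryEncoder(tiny_config, np.random.default_rng(7))
        recs = _records(2)
        blosum, mask = encode_batch(recs, max_len=tiny_config.max_len)
        with no_grad():
            a, _ = enc(blosum, mask)
            b, _ = enc(blosum, mask)
        np.testing.assert_array_equal(a.data, b.data)

    def test_transformer_positional_permutation_sensitivity(self, rng, tiny_config):
        import dataclasses

        cfg = dataclasses.replace(tiny_config, variant="transformer")
        enc = EvolutionaryEncoder(cfg, rng)
        seq = "".join(np.random.default_rng(0).choice(list(STANDARD_AA), size=cfg.max_len))
        rec = SequenceRecord("x", seq)
        blosum, mask = encode_batch([rec], max_len=cfg.max_len)
        perm = np.random.default_rng(1).permutation(cfg.max_len)
        with no_grad():
            orig, _ = enc(blosum, mask)
            shuffled, _ = enc(blosum[:, perm], mask[:, perm])
        assert not np.allclose(orig.data, shuffled.data)

    def test_shape_mismatch_raises(self, rng, tiny_config):
        enc = EvolutionaryEncoder(tiny_config, rng)
        with pytest.raises(ConfigError):
            enc(np.zeros((1, tiny_config.max_len + 1, 20)), np.ones((1, tiny_config.max_len + 1)))


class TestAssembledVariants:
    def test_design2_has_no_recurrence_and_exposes_positional_encoding(self, tiny_config):
        model = assemble_variant("design2", encoder=tiny_config)
        assert not hasattr(model.encoder, "bigru")
        assert isinstance(model.encoder.positional_encoding, np.ndarray)

    def test_design3_reduces_to_hidden_width(self, tiny_config):
        model = assemble_variant("design3", encoder=tiny_config)
        assert model.config.encoder.evolutionary_dim == tiny_config.gru_hidden
        baseline = assemble_variant("baseline", encoder=tiny_config)
        assert baseline.config.encoder.evolutionary_dim == 4 * tiny_config.gru_hidden

    @pytest.mark.parametrize(
        "variant", ["baseline", "design1", "design2", "design3", "design4", "design5"]
    )
    def test_every_variant_emits_probability(self, variant, tiny_config, small_fegs):
        model = assemble_variant(
            variant, encoder=tiny_config, fegs_encoder=small_fegs, seed=3,
            latent_dim=8, mlp_hidden=16,
        )
        recs = _records(2, seed=variant.__hash__() % 100)
        probs = model.predict_proba(recs)
        assert probs.shape == (4,)
        assert np.all(np.isfinite(probs))
        assert np.all((probs >= 0) & (probs <= 1))

    def test_unknown_variant_rejected(self, tiny_config):
        with pytest.raises(ConfigError):
            assemble_variant("design9", encoder=tiny_config)

    def test_attention_rows_sum_to_one_in_design1(self, tiny_config, small_fegs):
        model = assemble_variant("design1", encoder=tiny_config, fegs_encoder=small_fegs)
        recs = _records(2)
        blosum, mask, fegs = model.encode_records(recs)
        with no_grad():
            _, _, extras = model.forward(blosum, mask, fegs)
        weights = extras["attention"].data
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_channel_gates_in_unit_interval_in_design3(self, tiny_config, small_fegs):
        model = assemble_variant("design3", encoder=tiny_config, fegs_encoder=small_fegs)
        recs = _records(2)
        blosum, mask, fegs = model.encode_records(recs)
        with no_grad():
            _, _, extras = model.forward(blosum, mask, fegs)
        for key in ("cnn_gates", "gru_gates"):
            g = extras[key].data
            assert np.all((g > 0) & (g < 1))


class TestMaskedPooling:
    def test_padding_excluded_from_mean(self, rng):
        x = Tensor(rng.normal(size=(1, 4, 3)))
        mask = np.array([[1.0, 1.0, 0.0, 0.0]])
        pooled = masked_mean_pool(x, mask)
        np.testing.assert_allclose(pooled.data[0], x.data[0, :2].mean(axis=0))

    def test_bigru_final_state_ignores_padding(self, rng):
        gru = BiGRU(rng, in_dim=3, hidden=4, layers=1)
        x_real = rng.normal(size=(1, 2, 3))
        x_padded = np.concatenate([x_real, rng.normal(size=(1, 3, 3))], axis=1)
        with no_grad():
            _, finals_short = gru(Tensor(x_real), np.ones((1, 2)))
            _, finals_padded = gru(
                Tensor(x_padded), np.array([[1.0, 1.0, 0.0, 0.0, 0.0]])
            )
        # forward-direction final state must equal the state at the last real step
        np.testing.assert_allclose(
            finals_short[0].data, finals_padded[0].data, rtol=1e-12
        )
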