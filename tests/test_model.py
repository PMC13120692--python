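"""Encoder–decoder transformer: projections, masks, causality, invariants."""

import numpy as np
import pytest

from hiergo.model import (
    FunctionTransformer,
    ModelConfig,
    ResidueEmbeddings,
    build_causal_mask,
    load_model,
    pad_batch,
    save_model,
)
from hiergo.nn import Tensor


def small_model(rng=None, **overrides):
    rng = rng or np.random.default_rng(0)
    defaults = dict(d_seq=16, d_go=8, d=32, n_heads=2, n_enc=2, n_dec=2, d_ff=48, head_hidden=24)
    defaults.update(overrides)
    return FunctionTransformer(ModelConfig(**defaults), rng)


class TestProjection:
    def test_identity_weights_pass_through(self):
        model = small_model(d_seq=32, d=32)
        model.w_seq.weight.data = np.eye(32)
        model.w_seq.bias.data = np.zeros(32)
        X = np.random.default_rng(1).standard_normal((1, 5, 32))
        assert np.allclose(model.project_residues(Tensor(X)).data, X, atol=1e-6)

    def test_zero_input_yields_bias(self):
        model = small_model()
        out = model.project_residues(Tensor(np.zeros((1, 4, 16))))
        assert np.allclose(out.data, model.w_seq.bias.data, atol=1e-6)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        model = small_model(rng)
        X = rng.standard_normal((1, 3, 16)).astype(np.float32)
        out = model.project_residues(Tensor(X)).data[0]
        W, b = model.w_seq.weight.data, model.w_seq.bias.data
        for i in range(3):
            oracle = np.array([sum(X[0, i, k] * W[k, j] for k in range(16)) + b[j] for j in range(32)])
            assert np.allclose(out[i], oracle, atol=1e-4)


class TestCausalMask:
    def test_t3_allowed_pairs(self):
        mask = build_causal_mask(3)
        allowed = {(i, j) for i in range(3) for j in range(3) if mask[i, j]}
        assert allowed == {(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)}

    def test_t1_single_entry(self):
        assert build_causal_mask(1).tolist() == [[True]]

    def test_row_sums_count_up(self):
        mask = build_causal_mask(7)
        assert mask.sum(axis=1).tolist() == list(range(1, 8))


class TestEncoder:
    @pytest.mark.parametrize("L", [1, 10, 200])
    def test_output_shape(self, L):
        model = small_model()
        X = np.random.default_rng(0).standard_normal((2, L, 16))
        mask = np.ones((2, L), dtype=bool)
        h = model.encode_protein(model.project_residues(Tensor(X)), mask)
        assert h.shape == (2, L, 32)

    def test_padding_extension_leaves_real_rows_unchanged(self):
        rng = np.random.default_rng(3)
        model = small_model(rng)
        X = rng.standard_normal((1, 6, 16))
        mask = np.ones((1, 6), dtype=bool)
        h = model.encode_protein(model.project_residues(Tensor(X)), mask).data
        X_pad = np.concatenate([X, np.zeros((1, 4, 16))], axis=1)
        mask_pad = np.concatenate([mask, np.zeros((1, 4), dtype=bool)], axis=1)
        h_pad = model.encode_protein(model.project_residues(Tensor(X_pad)), mask_pad).data
        assert np.allclose(h[0], h_pad[0, :6], atol=1e-5)

    def test_permutation_equivariance_without_positional_encoding(self):
        rng = np.random.default_rng(4)
        model = small_model(rng)
        X = rng.standard_normal((1, 8, 16))
        mask = np.ones((1, 8), dtype=bool)
        h = model.encode_protein(model.project_residues(Tensor(X)), mask).data
        perm = rng.permutation(8)
        h_perm = model.encode_protein(
            model.project_residues(Tensor(X[:, perm])), mask
        ).data
        assert np.allclose(h[0, perm], h_perm[0], atol=1e-5)

    def test_all_masked_input_rejected(self):
        model = small_model()
        with pytest.raises(ValueError, match="masked"):
            model.encode_protein(Tensor(np.zeros((1, 3, 32))), np.zeros((1, 3), dtype=bool))


class TestDecoder:
    def test_causality_later_rows_cannot_leak_backward(self):
        """Perturbing GO latents at rank k leaves outputs at ranks < k unchanged."""
        rng = np.random.default_rng(5)
        model = small_model(rng)
        X = rng.standard_normal((1, 10, 16))
        mask = np.ones((1, 10), dtype=bool)
        E = rng.standard_normal((6, 8))
        base, _ = model.forward(X, mask, E)
        for trial in range(5):
            k = int(rng.integers(1, 6))
            E2 = E.copy()
            E2[k:] += rng.standard_normal(E2[k:].shape)
            out, _ = model.forward(X, mask, E2)
            assert np.max(np.abs(out.data[0, :k] - base.data[0, :k])) < 1e-5

    def test_attention_rows_are_distributions(self):
        rng = np.random.default_rng(6)
        model = small_model(rng)
        X = rng.standard_normal((2, 9, 16))
        mask = np.ones((2, 9), dtype=bool)
        mask[1, 5:] = False
        E = rng.standard_normal((4, 8))
        _, record = model.forward(X, mask, E)
        for probs in record.layers:
            sums = probs.sum(axis=-1)
            assert np.allclose(sums, 1.0, atol=1e-6)
            # padded residues receive zero attention
            assert np.allclose(probs[1, :, :, 5:], 0.0, atol=1e-8)

    def test_mask_shape_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        model = small_model(rng)
        h = Tensor(np.zeros((1, 4, 32)))
        memory = Tensor(np.zeros((1, 5, 32)))
        with pytest.raises(ValueError, match="causal mask"):
            model.decode_terms(h, memory, build_causal_mask(3), np.ones((1, 5), dtype=bool))


class TestPredictionHead:
    def test_zero_weights_give_half_probability(self):
        model = small_model()
        for lin in (model.head1, model.head2):
            lin.weight.data[:] = 0
            lin.bias.data[:] = 0
        logits = model.predict_head(Tensor(np.random.default_rng(0).standard_normal((1, 4, 32))))
        probs = 1 / (1 + np.exp(-logits.data))
        assert np.allclose(probs, 0.5)

    def test_probabilities_in_open_interval(self):
        rng = np.random.default_rng(8)
        model = small_model(rng)
        X = rng.standard_normal((2, 7, 16))
        probs, _ = model.predict(X, np.ones((2, 7), dtype=bool), rng.standard_normal((5, 8)))
        assert probs.shape == (2, 5)
        assert (probs > 0).all() and (probs < 1).all()

    def test_matches_composed_closed_form_on_toy(self):
        rng = np.random.default_rng(9)
        model = small_model(rng)
        h = rng.standard_normal((1, 2, 32)).astype(np.float32)
        logits = model.predict_head(Tensor(h)).data
        W1, b1 = model.head1.weight.data, model.head1.bias.data
        W2, b2 = model.head2.weight.data, model.head2.bias.data
        c = np.sqrt(2 / np.pi)
        pre = h @ W1 + b1
        act = 0.5 * pre * (1 + np.tanh(c * (pre + 0.044715 * pre**3)))
        oracle = (act @ W2 + b2)[..., 0]
        assert np.allclose(logits, oracle, atol=1e-5)


class TestForward:
    def test_shapes_and_attention_maps(self):
        rng = np.random.default_rng(10)
        model = small_model(rng)
        X = rng.standard_normal((1, 50, 16))
        mask = np.ones((1, 50), dtype=bool)
        E = rng.standard_normal((20, 8))
        probs, record = model.predict(X, mask, E)
        assert probs.shape == (1, 20)
        assert record.n_layers == 2 and record.n_heads == 2
        assert all(layer.shape == (1, 2, 20, 50) for layer in record.layers)

    def test_deterministic_given_same_inputs(self):
        rng = np.random.default_rng(11)
        model = small_model(rng)
        X = rng.standard_normal((1, 12, 16))
        mask = np.ones((1, 12), dtype=bool)
        E = rng.standard_normal((4, 8))
        a, _ = model.predict(X, mask, E)
        b, _ = model.predict(X, mask, E)
        assert np.array_equal(a, b)

    def test_encoder_variant_is_order_insensitive_where_decoder_is_not(self):
        """Bidirectional term attention sees all ranks; causal decoding does not."""
        rng = np.random.default_rng(12)
        X = rng.standard_normal((1, 8, 16))
        mask = np.ones((1, 8), dtype=bool)
        E = rng.standard_normal((5, 8))
        dec = small_model(np.random.default_rng(40))
        out_dec, _ = dec.forward(X, mask, E)
        E2 = E.copy()
        E2[-1] += 1.0  # change the last-ranked term only
        out_dec2, _ = dec.forward(X, mask, E2)
        # causal: earlier ranks untouched
        assert np.allclose(out_dec.data[0, :-1], out_dec2.data[0, :-1], atol=1e-5)
        enc = small_model(np.random.default_rng(40), architecture="encoder")
        out_enc, _ = enc.forward(X, mask, E)
        out_enc2, _ = enc.forward(X, mask, E2)
        # bidirectional: the perturbation reaches earlier ranks
        assert np.max(np.abs(out_enc.data[0, :-1] - out_enc2.data[0, :-1])) > 1e-4

    def test_mlp_variant_shape_and_determinism(self):
        rng = np.random.default_rng(13)
        model = small_model(rng, architecture="mlp")
        X = rng.standard_normal((2, 6, 16))
        mask = np.ones((2, 6), dtype=bool)
        E = rng.standard_normal((7, 8))
        probs, record = model.predict(X, mask, E)
        assert probs.shape == (2, 7)
        assert record is None
        again, _ = model.predict(X, mask, E)
        assert np.array_equal(probs, again)

    def test_frozen_inputs_never_receive_gradients(self):
        rng = np.random.default_rng(14)
        model = small_model(rng)
        X = Tensor(rng.standard_normal((1, 5, 16)))  # requires_grad False
        E = rng.standard_normal((3, 8))
        logits, _ = model.forward(X, np.ones((1, 5), dtype=bool), E)
        logits.sum().backward()
        assert X.grad is None
        # every trainable parameter belongs to projections/blocks/head
        assert all(p.grad is not None for p in model.parameters())


class TestPadBatchAndCheckpoint:
    def test_pad_batch_masks_padding(self):
        rng = np.random.default_rng(15)
        proteins = [ResidueEmbeddings(rng.standard_normal((n, 4))) for n in (3, 6)]
        X, mask = pad_batch(proteins)
        assert X.shape == (2, 6, 4)
        assert mask[0].tolist() == [True] * 3 + [False] * 3

    def test_checkpoint_roundtrip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(16)
        model = small_model(rng)
        X = rng.standard_normal((1, 9, 16))
        mask = np.ones((1, 9), dtype=bool)
        E = rng.standard_normal((4, 8))
        before, _ = model.predict(X, mask, E)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        after, _ = loaded.predict(X, mask, E)
        assert np.array_equal(before, after)
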