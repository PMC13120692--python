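"""Multi-task GO autoencoder: projection, heads, loss, fitting, zero-shot path."""

import numpy as np
import pytest

from hiergo.autoencoder import (
    AutoencoderConfig,
    AutoencoderParams,
    LossWeights,
    autoencoder_loss,
    ancestor_retrieval_auc,
    build_targets,
    decode_heads,
    embed_unseen_term,
    encode_term,
    fit_autoencoder,
    subontology_accuracy,
)
from hiergo.ontology import ancestor_index, parse_obo
from hiergo.synthetic import SyntheticConfig, generate_ontology
from hiergo.text_embedding import TermEmbeddingMatrix, TextEncoderSpec, embed_definitions

from conftest import make_obo, term_stanza


@pytest.fixture(scope="module")
def tiny_setup():
    """10-term, 3-aspect ontology with templated definitions."""
    config = SyntheticConfig(
        leaves_per_aspect=2, internal_per_aspect=1, max_depth=2, d_seq=8, d_t=64, seed=5
    )
    _, graph = generate_ontology(config)
    emb = embed_definitions(
        [graph.terms[t] for t in graph.active_terms()], TextEncoderSpec(d_t=64)
    )
    index = ancestor_index(graph, include_self=True)
    return graph, emb, index


class TestEncodeDecode:
    def test_identity_projection_passes_through(self):
        rng = np.random.default_rng(0)
        params = AutoencoderParams(d_t=6, d_z=6, n_terms=4, rng=rng)
        params.w_emb.weight.data = np.eye(6)
        x = rng.standard_normal(6)
        assert np.allclose(encode_term(x, params), x)
        assert np.allclose(encode_term(np.zeros(6), params), 0.0)

    def test_matches_matvec_oracle(self):
        rng = np.random.default_rng(1)
        params = AutoencoderParams(d_t=5, d_z=3, n_terms=4, rng=rng)
        x = rng.standard_normal(5)
        W = params.w_emb.weight.data
        oracle = np.array([sum(W[j, i] * x[j] for j in range(5)) for i in range(3)])
        assert np.allclose(encode_term(x, params), oracle, atol=1e-6)

    def test_heads_are_distributions(self):
        rng = np.random.default_rng(2)
        params = AutoencoderParams(d_t=4, d_z=4, n_terms=7, rng=rng)
        y_anc, y_sub, y_id = decode_heads(rng.standard_normal(4), params)
        for head in (y_anc, y_sub, y_id):
            assert head.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_latent_zero_bias_uniform(self):
        rng = np.random.default_rng(3)
        params = AutoencoderParams(d_t=4, d_z=4, n_terms=10, rng=rng)
        y_anc, y_sub, y_id = decode_heads(np.zeros(4), params)
        assert np.allclose(y_sub, 1 / 3, atol=1e-6)
        assert np.allclose(y_id, 1 / 10, atol=1e-6)

    def test_sigmoid_mode_is_elementwise(self):
        rng = np.random.default_rng(4)
        params = AutoencoderParams(d_t=4, d_z=4, n_terms=10, rng=rng)
        y_anc, _, _ = decode_heads(np.zeros(4), params, ancestor_mode="sigmoid")
        assert np.allclose(y_anc, 0.5, atol=1e-6)  # sigmoid(0), not normalized


class TestLoss:
    def test_perfect_predictions_zero_loss(self):
        preds = (np.array([0.0, 1.0, 1.0]), np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
        targets = (np.array([0, 1, 1]), np.array([1, 0, 0]), np.array([0, 1, 0]))
        assert autoencoder_loss(preds, targets) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_gives_log_n(self):
        n = 8
        preds = (np.full(n, 1 / n), np.full(3, 1 / 3), np.full(n, 1 / n))
        targets = (np.eye(n)[0], np.eye(3)[0], np.eye(n)[0])
        expected = np.log(n) + np.log(3) + np.log(n)
        assert autoencoder_loss(preds, targets) == pytest.approx(expected, rel=1e-9)

    def test_alpha_weights_match_hand_summed_oracle(self):
        rng = np.random.default_rng(5)
        p = tuple(rng.uniform(0.1, 0.9, size=s) for s in (4, 3, 4))
        y = (np.array([1, 0, 1, 0]), np.array([0, 1, 0]), np.array([0, 0, 0, 1]))
        w = LossWeights(2.0, 1.0, 1.0)
        oracle = (
            -2.0 * (np.log(p[0][0]) + np.log(p[0][2]))
            - np.log(p[1][1])
            - np.log(p[2][3])
        )
        assert autoencoder_loss(p, y, w) == pytest.approx(oracle, rel=1e-9)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0, 0, 0)


class TestFit:
    def test_tiny_ontology_overfits(self, tiny_setup):
        """Multi-label (sigmoid) mode drives the loss to ≈0 on a 12-term ontology.

        The softmax ancestor head keeps an intrinsic floor on multi-positive
        targets (mass must split across ancestors), so the overfit check uses
        the sigmoid mode whose optimum is exactly zero.
        """
        graph, emb, index = tiny_setup
        result = fit_autoencoder(
            emb, index, graph.aspect_of,
            config=AutoencoderConfig(d_z=16, epochs=2000, lr=3e-3, seed=0, ancestor_head="sigmoid"),
        )
        assert result.loss_trace[-1] < 0.01 * result.loss_trace[0]

    def test_same_seed_identical_parameters(self, tiny_setup):
        graph, emb, index = tiny_setup
        cfg = AutoencoderConfig(d_z=8, epochs=50, seed=9)
        a = fit_autoencoder(emb, index, graph.aspect_of, config=cfg)
        b = fit_autoencoder(emb, index, graph.aspect_of, config=cfg)
        for pa, pb in zip(a.params.parameters(), b.params.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_input_matrix_frozen(self, tiny_setup):
        graph, emb, index = tiny_setup
        before = emb.checksum()
        fit_autoencoder(emb, index, graph.aspect_of, config=AutoencoderConfig(epochs=20, d_z=8))
        assert emb.checksum() == before

    def test_latent_semantic_proximity(self, tiny_setup):
        """Definition pairs with high text cosine stay close in latent space."""
        graph, emb, index = tiny_setup
        result = fit_autoencoder(
            emb, index, graph.aspect_of, config=AutoencoderConfig(d_z=8, epochs=500, seed=1)
        )
        Z = result.latents().matrix
        X = emb.rows(result.term_ids)

        def cos_matrix(M):
            U = M / np.linalg.norm(M, axis=1, keepdims=True)
            return U @ U.T

        cx, cz = cos_matrix(X), cos_matrix(Z)
        iu = np.triu_indices(len(Z), k=1)
        top_text = np.argsort(cx[iu])[-5:]  # most similar definition pairs
        assert cz[iu][top_text].mean() > np.median(cz[iu])


class TestUnseenTerm:
    def test_known_definition_reproduces_latent(self, tiny_setup):
        graph, emb, index = tiny_setup
        spec = TextEncoderSpec(d_t=64)
        result = fit_autoencoder(emb, index, graph.aspect_of, config=AutoencoderConfig(epochs=20, d_z=8))
        term = result.term_ids[3]
        z_new = embed_unseen_term(graph.definition(term), spec, result.params)
        z_known = encode_term(emb.row(term), result.params)
        assert np.allclose(z_new, z_known, atol=1e-6)

    def test_params_untouched_by_inference(self, tiny_setup):
        graph, emb, index = tiny_setup
        result = fit_autoencoder(emb, index, graph.aspect_of, config=AutoencoderConfig(epochs=10, d_z=8))
        before = [p.data.copy() for p in result.params.parameters()]
        embed_unseen_term("a brand new definition", TextEncoderSpec(d_t=64), result.params)
        for prev, p in zip(before, result.params.parameters()):
            assert np.array_equal(prev, p.data)

    def test_mixed_definition_lands_between_sources(self):
        config = SyntheticConfig(
            leaves_per_aspect=5, internal_per_aspect=2, max_depth=2, d_seq=8, d_t=64, seed=5
        )
        _, graph = generate_ontology(config)
        emb = embed_definitions(
            [graph.terms[t] for t in graph.active_terms()], TextEncoderSpec(d_t=64)
        )
        index = ancestor_index(graph, include_self=True)
        result = fit_autoencoder(
            emb, index, graph.aspect_of, config=AutoencoderConfig(d_z=8, epochs=500, seed=2)
        )
        ids = result.term_ids
        leaves = graph.leaves("MF")
        a, b = leaves[0], leaves[3]
        mixed = graph.definition(a) + " " + graph.definition(b)
        z = embed_unseen_term(mixed, TextEncoderSpec(d_t=64), result.params)
        Z = result.latents().matrix

        def cos(u, v):
            return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))

        sims = {t: cos(z, Z[i]) for i, t in enumerate(ids)}
        source_sim = min(sims[a], sims[b])
        others = [s for t, s in sims.items() if t not in (a, b)]
        assert source_sim > np.quantile(others, 0.9)

    def test_empty_definition_rejected(self, tiny_setup):
        graph, emb, index = tiny_setup
        result = fit_autoencoder(emb, index, graph.aspect_of, config=AutoencoderConfig(epochs=5, d_z=8))
        with pytest.raises(ValueError):
            embed_unseen_term("", TextEncoderSpec(d_t=64), result.params)
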