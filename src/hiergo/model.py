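"""Hierarchical encoder–decoder transformer for protein function prediction.

Residue embeddings X ∈ R^{L×d_seq} from a (pluggable) protein language model
are projected into the model width (H_enc(0) = X W_seq + 1 b_seq^T) and
contextualized by N_enc self-attention layers.  GO term latents E ∈ R^{T×d_go}
— arranged in topological order π from the ontology root toward the leaves —
are projected (H_dec(0) = E W_go + 1 b_go^T) and decoded by N_dec layers of
causal self-attention (lower-triangular mask over π, diagonal included),
cross-attention to the encoded residues, and a feed-forward sub-layer.  A
two-layer GELU head with a sigmoid emits the probability that the protein
carries each term.  The frozen GO latents and residue embeddings are inputs,
never parameters; cross-attention probabilities are recorded per layer and
head for rollout attribution.

Two ablation architectures are provided: a bidirectional "encoder" variant
(no causal mask over terms) and an "MLP" variant pairing the mean-pooled
protein embedding with each GO latent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    NEG_INF,
    Adam,
    DecoderLayer,
    EncoderLayer,
    Linear,
    Module,
    Tensor,
    concat,
    gelu,
)

ARCHITECTURES = ("decoder", "encoder", "mlp")


@dataclass
class ResidueEmbeddings:
    """Per-residue embedding matrix for one protein plus a validity mask."""

    X: np.ndarray  # (L, d_seq)
    mask: np.ndarray | None = None  # True where a real residue sits

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[0] < 1:
            raise ValueError("residue embeddings must be a non-empty (L, d_seq) matrix")
        if self.mask is None:
            self.mask = np.ones(self.X.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.X.shape[0],):
            raise ValueError("mask length must equal residue count")


@dataclass
class ModelConfig:
    d_seq: int = 64
    d_go: int = 64
    d: int = 128
    n_heads: int = 4
    n_enc: int = 2
    n_dec: int = 2
    d_ff: int = 256
    head_hidden: int = 128
    architecture: str = "decoder"
    ordering: str = "hierarchical"
    pre_norm: bool = False
    positional_encoding: bool = False
    max_len: int = 1000
    n_terms: int | None = None  # required for the trainable-embedding ablation
    trainable_term_embeddings: bool = False  # "none" GO-embedding ablation

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")


@dataclass
class AttentionRecord:
    """Cross-attention probabilities per decoder layer: each (B, H, T, L)."""

    layers: list[np.ndarray]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_heads(self) -> int:
        return self.layers[0].shape[1]


def build_causal_mask(T: int) -> np.ndarray:
    """Boolean (T, T) lower-triangular mask, diagonal included: allowed(i,j) ⇔ j ≤ i."""
    if T < 1:
        raise ValueError("need at least one term")
    return np.tril(np.ones((T, T), dtype=bool))


def _additive(mask_bool: np.ndarray) -> np.ndarray:
    return np.where(mask_bool, 0.0, NEG_INF)


def sinusoidal_encoding(length: int, d: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.zeros((length, d))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


class FunctionTransformer(Module):
    """The trainable part of the pipeline: projections, blocks, prediction head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        c = config
        self.config = c
        self.w_seq = Linear(c.d_seq, c.d, rng)
        self.enc_layers = [
            EncoderLayer(c.d, c.n_heads, c.d_ff, rng, c.pre_norm) for _ in range(c.n_enc)
        ]
        if c.architecture == "mlp":
            self.w_go = Linear(c.d_go, c.d, rng)
            self.head1 = Linear(2 * c.d, c.head_hidden, rng)
            self.head2 = Linear(c.head_hidden, 1, rng)
            self.dec_layers: list[DecoderLayer] = []
        else:
            self.w_go = Linear(c.d_go, c.d, rng)
            self.dec_layers = [
                DecoderLayer(c.d, c.n_heads, c.d_ff, rng, c.pre_norm) for _ in range(c.n_dec)
            ]
            self.head1 = Linear(c.d, c.head_hidden, rng)
            self.head2 = Linear(c.head_hidden, 1, rng)
        if c.trainable_term_embeddings:
            if c.n_terms is None:
                raise ValueError("n_terms required when term embeddings are trainable")
            self.term_embeddings = Tensor(
                rng.standard_normal((c.n_terms, c.d_go)) / np.sqrt(c.d_go),
                requires_grad=True,
            )
        else:
            self.term_embeddings = None

    # -- spec operations -------------------------------------------------------
    def project_residues(self, X: Tensor) -> Tensor:
        """H_enc(0) = X W_seq + 1 b_seq^T."""
        h = self.w_seq(X)
        if self.config.positional_encoding:
            h = h + Tensor(sinusoidal_encoding(X.shape[-2], self.config.d))
        return h

    def encode_protein(self, h: Tensor, pad_mask: np.ndarray) -> Tensor:
        """Run the N_enc self-attention stack; padded keys are never attended."""
        if not pad_mask.any(axis=-1).all():
            raise ValueError("a protein with every residue masked cannot be encoded")
        additive = _additive(pad_mask)[:, None, None, :]  # (B,1,1,L)
        for layer in self.enc_layers:
            h = layer(h, additive)
        return h

    def decode_terms(
        self,
        h_dec: Tensor,
        memory: Tensor,
        causal_mask: np.ndarray | None,
        pad_mask: np.ndarray,
    ) -> tuple[Tensor, AttentionRecord]:
        """Causal self-attention over terms + cross-attention to residues."""
        T = h_dec.shape[-2]
        if causal_mask is not None and causal_mask.shape != (T, T):
            raise ValueError(f"causal mask shape {causal_mask.shape} does not match T={T}")
        self_mask = None if causal_mask is None else _additive(causal_mask)[None, None, :, :]
        cross_mask = _additive(pad_mask)[:, None, None, :]
        record: list[np.ndarray] = []
        for layer in self.dec_layers:
            h_dec, probs = layer(h_dec, memory, self_mask, cross_mask)
            record.append(probs)
        return h_dec, AttentionRecord(record)

    def predict_head(self, h: Tensor) -> Tensor:
        """Per-term logit: W2 · gelu(W1 h + b1) + b2 (sigmoid applied by callers)."""
        return self.head2(gelu(self.head1(h))).reshape(*h.shape[:-1])

    # -- full forward ----------------------------------------------------------
    def forward(
        self,
        X: np.ndarray | Tensor,
        pad_mask: np.ndarray,
        E: np.ndarray | None,
        return_probs: bool = True,
    ) -> tuple[Tensor, AttentionRecord | None]:
        """Batch forward pass.

        X: (B, L, d_seq) padded residue embeddings, pad_mask (B, L) boolean.
        E: (T, d_go) frozen GO latents in decoder order (ignored when the
        model owns trainable term embeddings).  Returns per-term logits
        (B, T) and the captured cross-attention record.
        """
        x_in = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=np.float64))
        if self.term_embeddings is not None:
            e_in: Tensor = self.term_embeddings
        else:
            if E is None:
                raise ValueError("frozen GO latents E are required")
            e_in = Tensor(np.asarray(E, dtype=np.float64))
        B = x_in.shape[0]
        h_enc = self.encode_protein(self.project_residues(x_in), pad_mask)
        if self.config.architecture == "mlp":
            counts = pad_mask.sum(axis=1, keepdims=True)
            pooled = (h_enc * Tensor(pad_mask[:, :, None].astype(float))).sum(axis=1) / Tensor(
                counts.astype(float)
            )  # (B, d)
            g = self.w_go(e_in)  # (T, d)
            T = g.shape[0]
            pooled_b = pooled.reshape(B, 1, self.config.d) + Tensor(np.zeros((B, T, 1)))
            g_b = g.reshape(1, T, self.config.d) + Tensor(np.zeros((B, 1, 1)))
            h = concat([pooled_b, g_b], axis=-1)
            logits = self.predict_head(h)
            return logits, None
        h_dec0 = self.w_go(e_in)  # (T, d)
        T = h_dec0.shape[0]
        h_dec0 = h_dec0.reshape(1, T, self.config.d) + Tensor(np.zeros((B, 1, 1)))
        causal = build_causal_mask(T) if self.config.architecture == "decoder" else None
        h_dec, record = self.decode_terms(h_dec0, h_enc, causal, pad_mask)
        logits = self.predict_head(h_dec)
        return logits, record

    def predict(
        self, X: np.ndarray, pad_mask: np.ndarray, E: np.ndarray | None
    ) -> tuple[np.ndarray, AttentionRecord | None]:
        """Probabilities in [0,1] per (protein, term), plus attention record."""
        logits, record = self.forward(X, pad_mask, E)
        return 1.0 / (1.0 + np.exp(-logits.data)), record


def pad_batch(
    proteins: list[ResidueEmbeddings],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length proteins into (B, L_max, d_seq) + boolean mask."""
    if not proteins:
        raise ValueError("empty batch")
    L = max(p.X.shape[0] for p in proteins)
    d = proteins[0].X.shape[1]
    X = np.zeros((len(proteins), L, d))
    mask = np.zeros((len(proteins), L), dtype=bool)
    for i, p in enumerate(proteins):
        n = p.X.shape[0]
        X[i, :n] = p.X
        mask[i, :n] = p.mask
    return X, mask


def save_model(model: FunctionTransformer, path, meta: dict | None = None) -> None:
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    arrays["_config"] = np.frombuffer(
        json.dumps(vars(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)
    if meta is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def load_model(path) -> FunctionTransformer:
    data = np.load(path, allow_pickle=False)
    config = ModelConfig(**json.loads(bytes(data["_config"]).decode()))
    model = FunctionTransformer(config, np.random.default_rng(0))
    for i, p in enumerate(model.parameters()):
        p.data = data[f"param_{i}"]
    return model
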