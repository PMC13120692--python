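"""Structure-recovering GO term autoencoder.

Frozen definition-text embeddings x_t are mapped by a single linear
projection z_t = W_emb x_t into a latent space; three decoding heads are
trained to recover (i) the term's ancestor set, (ii) its subontology and
(iii) its identity.  The combined objective is the weighted sum of
positive-class cross-entropies

    L = − α_anc Σ_i y_anc,i log ŷ_anc,i
        − α_sub Σ_i y_sub,i log ŷ_sub,i
        − α_id  Σ_i y_id,i  log ŷ_id,i

with softmax heads by default.  Because a softmax over a multi-positive
ancestor target is unusual, a sigmoid multi-label mode for the ancestor head
is available (trained with full binary cross-entropy in that mode).

Because the encoder consumes only definition text, latents for terms that
never appeared in training — newly introduced ontology releases — come from
the same frozen projection, which is what enables zero-shot prediction
downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Linear, Module, Tensor, softmax
from .ontology import ASPECTS, AncestorIndex
from .text_embedding import TermEmbeddingMatrix, TextEncoderSpec

EPS = 1e-12


@dataclass
class LossWeights:
    """α weights balancing the ancestor, subontology and identity terms."""

    alpha_anc: float = 1.0
    alpha_sub: float = 1.0
    alpha_id: float = 1.0

    def __post_init__(self):
        if self.alpha_anc < 0 or self.alpha_sub < 0 or self.alpha_id < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha_anc == self.alpha_sub == self.alpha_id == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class AutoencoderConfig:
    d_z: int = 64
    lr: float = 1e-3
    epochs: int = 200
    seed: int = 0
    ancestor_head: str = "softmax"  # or "sigmoid" (multi-label variant)


class AutoencoderParams(Module):
    """Projection W_emb plus the three decoding heads."""

    def __init__(self, d_t: int, d_z: int, n_terms: int, rng: np.random.Generator):
        self.d_t, self.d_z, self.n_terms = d_t, d_z, n_terms
        self.w_emb = Linear(d_t, d_z, rng, bias=False)
        self.head_anc = Linear(d_z, n_terms, rng)
        self.head_sub = Linear(d_z, 3, rng)
        self.head_id = Linear(d_z, n_terms, rng)

    def checksum(self) -> int:
        return hash(tuple(float(a.sum()) for a in self.state_arrays()))


def encode_term(x_t: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """z_t = W_emb x_t — a bias-free, nonlinearity-free projection."""
    x = np.atleast_2d(np.asarray(x_t, dtype=np.float64))
    if x.shape[1] != params.d_t:
        raise ValueError(f"expected input dimension {params.d_t}, got {x.shape[1]}")
    z = x @ params.w_emb.weight.data
    return z[0] if np.ndim(x_t) == 1 else z


def decode_heads(
    z_t: np.ndarray, params: AutoencoderParams, ancestor_mode: str = "softmax"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recover (ancestor set, subontology, identity) distributions from a latent."""
    z = Tensor(np.atleast_2d(np.asarray(z_t, dtype=np.float64)))
    if z.shape[1] != params.d_z:
        raise ValueError(f"expected latent dimension {params.d_z}, got {z.shape[1]}")
    anc_logits = params.head_anc(z)
    y_anc = anc_logits.sigmoid() if ancestor_mode == "sigmoid" else softmax(anc_logits)
    y_sub = softmax(params.head_sub(z))
    y_id = softmax(params.head_id(z))
    out = (y_anc.data, y_sub.data, y_id.data)
    if np.ndim(z_t) == 1:
        return tuple(o[0] for o in out)
    return out


def autoencoder_loss(
    preds: tuple[np.ndarray, np.ndarray, np.ndarray],
    targets: tuple[np.ndarray, np.ndarray, np.ndarray],
    weights: LossWeights = LossWeights(),
    eps: float = EPS,
) -> float:
    """The weighted positive-class cross-entropy objective (scalar, ≥ 0 for probs ≤ 1)."""
    total = 0.0
    alphas = (weights.alpha_anc, weights.alpha_sub, weights.alpha_id)
    for alpha, p, y in zip(alphas, preds, targets):
        p = np.clip(np.asarray(p, dtype=np.float64), eps, None)
        total -= alpha * float(np.sum(np.asarray(y) * np.log(p)))
    return total


def build_targets(
    term_ids: list[str], index: AncestorIndex, aspect_of: dict[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(y_anc, y_sub, y_id) matrices aligned with ``term_ids`` row order."""
    n = len(term_ids)
    pos = {t: i for i, t in enumerate(term_ids)}
    y_anc = np.zeros((n, n))
    y_sub = np.zeros((n, 3))
    y_id = np.eye(n)
    for i, t in enumerate(term_ids):
        for a in index[t]:
            y_anc[i, pos[a]] = 1.0
        y_sub[i, ASPECTS.index(aspect_of[t])] = 1.0
    return y_anc, y_sub, y_id


@dataclass
class FitResult:
    params: AutoencoderParams
    loss_trace: list[float]
    term_ids: list[str]
    config: AutoencoderConfig
    weights: LossWeights

    def latents(self) -> TermEmbeddingMatrix:
        raise NotImplementedError  # bound in fit_autoencoder


def fit_autoencoder(
    embeddings: TermEmbeddingMatrix,
    index: AncestorIndex,
    aspect_of: dict[str, str],
    weights: LossWeights = LossWeights(),
    config: AutoencoderConfig = AutoencoderConfig(),
) -> FitResult:
    """Train the projection + heads on every non-obsolete term (full batch).

    The input matrix stays frozen — only W_emb and the heads receive
    gradients.  Optimization is Adam; training aborts on a non-finite loss.
    """
    term_ids = [t for t in embeddings.term_ids if t in index]
    X = embeddings.rows(term_ids)
    y_anc, y_sub, y_id = build_targets(term_ids, index, aspect_of)
    rng = np.random.default_rng(config.seed)
    params = AutoencoderParams(embeddings.d_t, config.d_z, len(term_ids), rng)
    opt = Adam(params.parameters(), lr=config.lr)
    x_in = Tensor(X)  # constant: requires_grad stays False
    t_anc, t_sub, t_id = Tensor(y_anc), Tensor(y_sub), Tensor(y_id)
    sigmoid_mode = config.ancestor_head == "sigmoid"
    trace: list[float] = []
    before = embeddings.checksum()
    for _ in range(config.epochs):
        z = params.w_emb(x_in)
        anc_logits = params.head_anc(z)
        if sigmoid_mode:
            p_anc = anc_logits.sigmoid()
            loss_anc = -(
                t_anc * p_anc.clip_min(EPS).log()
                + (1.0 - t_anc) * (1.0 - p_anc).clip_min(EPS).log()
            ).sum()
        else:
            p_anc = softmax(anc_logits)
            loss_anc = -(t_anc * p_anc.clip_min(EPS).log()).sum()
        p_sub = softmax(params.head_sub(z))
        p_id = softmax(params.head_id(z))
        loss = (
            loss_anc * weights.alpha_anc
            + -(t_sub * p_sub.clip_min(EPS).log()).sum() * weights.alpha_sub
            + -(t_id * p_id.clip_min(EPS).log()).sum() * weights.alpha_id
        )
        value = float(loss.data)
        if not np.isfinite(value):
            raise FloatingPointError(f"autoencoder loss diverged at epoch {len(trace)}")
        trace.append(value)
        opt.zero_grad()
        loss.backward()
        opt.step()
    if embeddings.checksum() != before:
        raise RuntimeError("frozen input embeddings were mutated during training")
    result = FitResult(params, trace, term_ids, config, weights)
    result.latents = lambda: TermEmbeddingMatrix(  # type: ignore[method-assign]
        term_ids=list(term_ids), matrix=encode_term(embeddings.rows(term_ids), params)
    )
    return result


def embed_unseen_term(
    definition: str, encoder: TextEncoderSpec, params: AutoencoderParams
) -> np.ndarray:
    """Latent for a term never seen in training, straight from its definition.

    No parameter is updated: the text encoder and the projection are both
    frozen, so novel ontology releases can be embedded without retraining.
    """
    if not definition or not definition.strip():
        raise ValueError("empty definition")
    x = encoder.encode(definition)
    return encode_term(x, params)


def ancestor_retrieval_auc(
    params: AutoencoderParams,
    embeddings: TermEmbeddingMatrix,
    term_ids: list[str],
    index: AncestorIndex,
    ancestor_mode: str = "softmax",
) -> float:
    """Mean per-term ROC AUC of the ancestor head against the true closure."""
    from sklearn.metrics import roc_auc_score

    z = encode_term(embeddings.rows(term_ids), params)
    p_anc, _, _ = decode_heads(z, params, ancestor_mode)
    pos = {t: i for i, t in enumerate(term_ids)}
    aucs = []
    for i, t in enumerate(term_ids):
        truth = np.zeros(len(term_ids))
        for a in index[t]:
            truth[pos[a]] = 1.0
        if 0 < truth.sum() < len(truth):
            aucs.append(roc_auc_score(truth, p_anc[i]))
    return float(np.mean(aucs))


def subontology_accuracy(
    params: AutoencoderParams,
    embeddings: TermEmbeddingMatrix,
    term_ids: list[str],
    aspect_of: dict[str, str],
) -> float:
    z = encode_term(embeddings.rows(term_ids), params)
    _, p_sub, _ = decode_heads(z, params)
    pred = np.argmax(p_sub, axis=1)
    truth = np.array([ASPECTS.index(aspect_of[t]) for t in term_ids])
    return float(np.mean(pred == truth))


def save_params(params: AutoencoderParams, path, meta: dict | None = None) -> None:
    arrays = {
        "w_emb": params.w_emb.weight.data,
        "w_anc": params.head_anc.weight.data,
        "b_anc": params.head_anc.bias.data,
        "w_sub": params.head_sub.weight.data,
        "b_sub": params.head_sub.bias.data,
        "w_id": params.head_id.weight.data,
        "b_id": params.head_id.bias.data,
    }
    np.savez(path, **arrays)
    if meta is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def load_params(path) -> AutoencoderParams:
    data = np.load(path, allow_pickle=False)
    d_t, d_z = data["w_emb"].shape
    n_terms = data["w_anc"].shape[1]
    params = AutoencoderParams(d_t, d_z, n_terms, np.random.default_rng(0))
    params.w_emb.weight.data = data["w_emb"]
    params.head_anc.weight.data = data["w_anc"]
    params.head_anc.bias.data = data["b_anc"]
    params.head_sub.weight.data = data["w_sub"]
    params.head_sub.bias.data = data["b_sub"]
    params.head_id.weight.data = data["w_id"]
    params.head_id.bias.data = data["b_id"]
    return params
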