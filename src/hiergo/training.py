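"""Supervised multi-label training of the function transformer.

Binary cross-entropy over per-term probabilities, with the residue
embeddings and GO latents held frozen — only the projections, transformer
blocks and prediction head receive gradients.  Runs are seeded and the loss
trace (train and validation) is returned alongside the fitted model;
early stopping watches validation BCE.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .model import (
    AttentionRecord,
    FunctionTransformer,
    ModelConfig,
    ResidueEmbeddings,
    pad_batch,
)
from .nn import Adam, Tensor

EPS = 1e-12


@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 40
    batch_size: int = 16
    seed: int = 0
    val_fraction: float = 0.1
    patience: int = 10
    aspect: str = "MF"
    ordering: str = "hierarchical"
    deterministic: bool = True

    def __post_init__(self):
        if self.lr <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate, epochs and batch size must be positive")


@dataclass
class ProteinDataset:
    """Aligned proteins, residue embeddings and binary target matrix.

    ``targets[i, j]`` says whether protein i carries the term at decoder rank
    j; rows must already be true-path-propagated (upward-closed).
    """

    protein_ids: list[str]
    proteins: list[ResidueEmbeddings]
    targets: np.ndarray  # (N, T)
    term_ids: list[str]

    def __post_init__(self):
        if len(self.protein_ids) != len(self.proteins) or self.targets.shape != (
            len(self.proteins),
            len(self.term_ids),
        ):
            raise ValueError("dataset pieces are misaligned")

    def __len__(self) -> int:
        return len(self.proteins)

    def subset(self, idx) -> "ProteinDataset":
        idx = list(idx)
        return ProteinDataset(
            [self.protein_ids[i] for i in idx],
            [self.proteins[i] for i in idx],
            self.targets[idx],
            self.term_ids,
        )

    def checksum(self) -> str:
        h = hashlib.blake2b(digest_size=16)
        for p in self.proteins:
            h.update(np.ascontiguousarray(p.X).tobytes())
        h.update(np.ascontiguousarray(self.targets).tobytes())
        return h.hexdigest()


def build_target_matrix(annotations, protein_ids: list[str], term_ids: list[str]) -> np.ndarray:
    """Binary matrix of propagated annotations aligned to decoder term order."""
    pos = {t: j for j, t in enumerate(term_ids)}
    mat = np.zeros((len(protein_ids), len(term_ids)))
    by_protein: dict[str, set[str]] = {}
    for protein, term in annotations.records.itertuples(index=False):
        by_protein.setdefault(protein, set()).add(term)
    for i, pid in enumerate(protein_ids):
        for t in by_protein.get(pid, ()):
            if t in pos:
                mat[i, pos[t]] = 1.0
    return mat


def bce_objective(predictions: np.ndarray, targets: np.ndarray, eps: float = EPS) -> float:
    """Mean binary cross-entropy over proteins × terms, ε-clamped."""
    p = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {y.shape}")
    if np.isnan(p).any() or np.isnan(y).any():
        raise FloatingPointError("NaN in BCE inputs")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _bce_loss_tensor(
    logits: Tensor, targets: np.ndarray, term_weights: np.ndarray | None = None
) -> Tensor:
    y = Tensor(targets)
    p = logits.sigmoid()
    pos = p.clip_min(EPS).log() * y
    neg = (1.0 - p).clip_min(EPS).log() * (1.0 - y)
    if term_weights is None:
        return -(pos + neg).mean()
    # zero-weight columns (e.g. zero-shot terms with all associations removed)
    # contribute no gradient at all — they are unsupervised, not negative
    w = np.broadcast_to(term_weights, targets.shape)
    denom = float(w.sum()) or 1.0
    return -((pos + neg) * Tensor(w)).sum() / denom


@dataclass
class TrainResult:
    model: FunctionTransformer
    train_trace: list[float]
    val_trace: list[float]
    config: TrainConfig
    best_epoch: int


def predict_matrix(
    model: FunctionTransformer,
    dataset: ProteinDataset,
    E: np.ndarray | None,
    batch_size: int = 32,
    capture_attention: bool = False,
) -> tuple[np.ndarray, list[AttentionRecord] | None]:
    """Probability matrix (N, T) for the whole dataset, batched."""
    rows, records = [], []
    for start in range(0, len(dataset), batch_size):
        batch = dataset.proteins[start : start + batch_size]
        X, mask = pad_batch(batch)
        probs, record = model.predict(X, mask, E)
        rows.append(probs)
        if capture_attention:
            records.append(record)
    return np.vstack(rows), (records if capture_attention else None)


def train_model(
    dataset: ProteinDataset,
    go_latents: np.ndarray | None,
    model_config: ModelConfig,
    config: TrainConfig = TrainConfig(),
    term_weights: np.ndarray | None = None,
) -> TrainResult:
    """Fit the transformer on propagated annotations with frozen embeddings.

    The validation split is carved from the dataset by a seeded permutation;
    early stopping restores the parameters of the best validation epoch.
    ``term_weights`` (length T) down- or zero-weights term columns in the
    objective; zero-shot protocols pass 0 for held-out terms, whose
    associations were removed and which therefore carry no supervision.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    E = None if go_latents is None else np.asarray(go_latents, dtype=np.float64)
    e_before = None if E is None else E.copy()
    x_before = dataset.checksum()
    rng = np.random.default_rng(config.seed)
    model = FunctionTransformer(model_config, rng)
    opt = Adam(model.parameters(), lr=config.lr)

    n_val = max(1, int(round(config.val_fraction * len(dataset)))) if len(dataset) > 4 else 0
    perm = rng.permutation(len(dataset))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    train_set = dataset.subset(train_idx)
    val_set = dataset.subset(val_idx) if n_val else None

    train_trace: list[float] = []
    val_trace: list[float] = []
    best_val = np.inf
    best_epoch = -1
    best_state: list[np.ndarray] | None = None
    waited = 0
    # batch proteins of similar length together to minimise padding work;
    # batch order is reshuffled every epoch
    by_length = np.argsort([p.X.shape[0] for p in train_set.proteins], kind="stable")
    batches = [
        by_length[s : s + config.batch_size]
        for s in range(0, len(by_length), config.batch_size)
    ]
    for epoch in range(config.epochs):
        epoch_losses = []
        for b in rng.permutation(len(batches)):
            idx = batches[b]
            X, mask = pad_batch([train_set.proteins[i] for i in idx])
            logits, _ = model.forward(X, mask, E)
            loss = _bce_loss_tensor(logits, train_set.targets[idx], term_weights)
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}; trace so far: {train_trace[-5:]}"
                )
            epoch_losses.append(value)
            opt.zero_grad()
            loss.backward()
            opt.step()
        train_trace.append(float(np.mean(epoch_losses)))
        if val_set is not None:
            probs, _ = predict_matrix(model, val_set, E)
            if term_weights is None:
                val_loss = bce_objective(probs, val_set.targets)
            else:
                keep = np.asarray(term_weights) > 0
                val_loss = bce_objective(probs[:, keep], val_set.targets[:, keep])
            val_trace.append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val, best_epoch, waited = val_loss, epoch, 0
                best_state = [p.data.copy() for p in model.parameters()]
            else:
                waited += 1
                if waited >= config.patience:
                    break
    if best_state is not None:
        for p, saved in zip(model.parameters(), best_state):
            p.data = saved
    else:
        best_epoch = len(train_trace) - 1
    if E is not None and not np.array_equal(E, e_before):
        raise RuntimeError("frozen GO latents were mutated during training")
    if dataset.checksum() != x_before:
        raise RuntimeError("frozen residue embeddings were mutated during training")
    return TrainResult(model, train_trace, val_trace, config, best_epoch)
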