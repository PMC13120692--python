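"""Frozen sentence embeddings of GO term definitions.

The real system plugs in a biomedical sentence encoder (e.g. a
SBERT-flavoured BioBERT with mean pooling over last-layer token vectors)
through :class:`TextEncoderSpec`'s adapter hook.  The package ships a
deterministic *hash encoder* which maps each token to a pseudo-random vector
seeded from a stable digest of the token text, then mean-pools — it needs no
downloads, is bit-stable across platforms, and makes cosine similarity grow
with token overlap, which is the one property the downstream models rely on.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

_TOKEN_RE = re.compile(r"[A-Za-z0-9_:.\-]+")


def _tokenize(text: str) -> list[str]:
    return [t.lower() for t in _TOKEN_RE.findall(text)]


def _token_vector(token: str, d: int, seed: int) -> np.ndarray:
    digest = hashlib.blake2b(f"{seed}\x00{token}".encode(), digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "big"))
    return rng.standard_normal(d) / np.sqrt(d)


def hash_test_encoder(definition: str, d_t: int = 256, seed: int = 0) -> np.ndarray:
    """Deterministic mean-pooled token-hash embedding of ``definition``."""
    if d_t < 8:
        raise ValueError("embedding dimension must be at least 8")
    tokens = _tokenize(definition)
    if not tokens:
        raise ValueError("cannot embed empty text")
    vecs = np.stack([_token_vector(t, d_t, seed) for t in tokens])
    return vecs.mean(axis=0)


@dataclass
class TextEncoderSpec:
    """Description of a sentence encoder producing per-definition vectors.

    ``encode_fn`` maps text → vector of dimension ``d_t``.  The built-in hash
    encoder is deterministic; external adapters (any model that yields token
    vectors mean-pooled to a sentence vector) can be wired in without adding
    the model as a package dependency.
    """

    name: str = "hash"
    d_t: int = 256
    pooling: str = "mean"
    deterministic: bool = True
    seed: int = 0
    encode_fn: Callable[[str], np.ndarray] | None = None

    def encode(self, text: str) -> np.ndarray:
        if self.encode_fn is not None:
            vec = np.asarray(self.encode_fn(text), dtype=np.float64)
        else:
            vec = hash_test_encoder(text, self.d_t, self.seed)
        if vec.shape != (self.d_t,):
            raise ValueError(
                f"encoder {self.name!r} returned dimension {vec.shape}, expected ({self.d_t},)"
            )
        return vec


@dataclass
class TermEmbeddingMatrix:
    """Frozen per-term embedding rows, indexed by sorted term id."""

    term_ids: list[str]
    matrix: np.ndarray
    frozen: bool = True

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.term_ids):
            raise ValueError("matrix rows must match term ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite entries in embedding matrix")
        self._row = {t: i for i, t in enumerate(self.term_ids)}

    @property
    def d_t(self) -> int:
        return self.matrix.shape[1]

    def row(self, term: str) -> np.ndarray:
        return self.matrix[self._row[term]]

    def rows(self, terms: Iterable[str]) -> np.ndarray:
        return self.matrix[[self._row[t] for t in terms]]

    def checksum(self) -> str:
        h = hashlib.blake2b(digest_size=16)
        h.update("\x00".join(self.term_ids).encode())
        h.update(np.ascontiguousarray(self.matrix).tobytes())
        return h.hexdigest()

    # -- persistence (npz + sidecar TSV index) --------------------------------
    def save(self, path) -> None:
        np.savez(path, matrix=self.matrix, term_ids=np.array(self.term_ids))

    @classmethod
    def load(cls, path) -> "TermEmbeddingMatrix":
        data = np.load(path, allow_pickle=False)
        return cls(term_ids=[str(t) for t in data["term_ids"]], matrix=data["matrix"])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("term_id\t" + "\t".join(f"d{i}" for i in range(self.d_t)) + "\n")
            for t in self.term_ids:
                fh.write(t + "\t" + "\t".join(f"{v:.10g}" for v in self.row(t)) + "\n")


def embed_definitions(
    terms,  # iterable of GoTerm or (id, definition) pairs
    encoder: TextEncoderSpec,
) -> TermEmbeddingMatrix:
    """Embed every term's definition (falling back to its name) into a frozen matrix.

    Row order follows the lexicographic sort of term ids.
    """
    items: list[tuple[str, str]] = []
    for t in terms:
        if hasattr(t, "id"):
            text = t.definition or t.name
            items.append((t.id, text))
        else:
            items.append((t[0], t[1]))
    items.sort(key=lambda x: x[0])
    rows = []
    for tid, text in items:
        if not text or not text.strip():
            raise ValueError(f"term {tid!r} has neither definition nor name text")
        rows.append(encoder.encode(text))
    return TermEmbeddingMatrix(
        term_ids=[tid for tid, _ in items], matrix=np.stack(rows), frozen=True
    )
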