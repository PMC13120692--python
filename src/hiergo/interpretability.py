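"""Attention-rollout attribution of predictions to residues.

Cross-attention matrices are head-averaged per decoder layer,
A̅(l) = (1/H) Σ_h A_h(l), and aggregated recursively

    R(1) = A̅(1),    R(l) = ½ (A̅(l) + R(l−1))   for l = 2…N_dec,

equally weighting the current layer and the accumulated score.  Row t of the
final R is the per-residue relevance profile r_t for the GO term at decoder
rank t.  Because each recursion step is a convex combination, every R row
remains a distribution over unmasked residues.  Profiles are scored against
binary binding-site masks by ROC AUC.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

from .model import AttentionRecord
from .ontology import TopologicalOrder


def head_average(record: AttentionRecord, layer: int) -> np.ndarray:
    """A̅(l): mean over heads of the cross-attention at decoder layer ``layer`` (0-based)."""
    if layer < 0 or layer >= record.n_layers:
        raise ValueError(f"layer {layer} out of range (model has {record.n_layers})")
    return record.layers[layer].mean(axis=1)  # (B, T, L)


def attention_rollout(layer_averages: list[np.ndarray]) -> np.ndarray:
    """Apply the recursive averaging over layers 1…N_dec; returns R(N_dec)."""
    if not layer_averages:
        raise ValueError("need at least one layer")
    shapes = {a.shape for a in layer_averages}
    if len(shapes) != 1:
        raise ValueError(f"layer shapes differ: {shapes}")
    R = np.asarray(layer_averages[0], dtype=np.float64)
    for A in layer_averages[1:]:
        R = 0.5 * (np.asarray(A, dtype=np.float64) + R)
    return R


def rollout_from_record(record: AttentionRecord) -> np.ndarray:
    """R for every protein in the batch: (B, T, L)."""
    return attention_rollout([head_average(record, l) for l in range(record.n_layers)])


def residue_profile(
    R: np.ndarray,
    term: str,
    order: TopologicalOrder,
    pad_mask: np.ndarray | None = None,
) -> np.ndarray:
    """r_t: the rollout row for ``term``, with padding positions dropped."""
    if term not in order.rank:
        raise KeyError(f"term {term!r} not in decoding order")
    profile = np.asarray(R)[order.rank[term]]
    if pad_mask is not None:
        profile = profile[np.asarray(pad_mask, dtype=bool)]
    return profile


def rollout_auroc(profile: np.ndarray, mask: np.ndarray) -> float:
    """ROC AUC of the residue profile against a binary binding mask."""
    mask = np.asarray(mask, dtype=int)
    if mask.shape != np.asarray(profile).shape:
        raise ValueError("profile and mask lengths differ")
    if mask.min() == mask.max():
        raise ValueError("binding mask needs both a positive and a negative residue")
    return float(roc_auc_score(mask, profile))


def read_binding_masks(path) -> dict[str, list[tuple[int, int]]]:
    """BED-like TSV of binding intervals: protein_id, start, end (0-based, half-open).

    Files carrying an extra ``term_id`` column (as the synthetic fixture
    writes) are accepted; intervals are pooled per protein.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        start_col = header.index("start") if "start" in header else 1
        end_col = header.index("end") if "end" in header else 2
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            intervals.setdefault(cols[0], []).append((int(cols[start_col]), int(cols[end_col])))
    return intervals


def intervals_to_mask(intervals: list[tuple[int, int]], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for start, end in intervals:
        mask[start:end] = True
    return mask


def write_binding_masks(masks: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\n")
        for pid in sorted(masks):
            for start, end in masks[pid]:
                fh.write(f"{pid}\t{start}\t{end}\n")
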