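"""CAFA-style evaluation of protein→term probability matrices.

Protein-centric Fmax follows the CAFA convention: thresholds τ sweep
0.01…1.00 in steps of 0.01; precision at τ averages over proteins with at
least one prediction ≥ τ, recall averages over proteins with at least one
true term, and Fmax is the maximum harmonic mean (smallest τ on ties).
Term-centric metrics are macro/micro area under precision–recall and
per-term ROC AUC (Mann–Whitney, ties get half credit); the headline
"term-centric AUC" is the unweighted mean of per-term AUCs over scorable
terms (≥1 positive and ≥1 negative).  Aspect roots — always true after
propagation — are excluded by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

THRESHOLDS = np.round(np.arange(0.01, 1.001, 0.01), 2)


@dataclass
class PredictionMatrix:
    """Probabilities (proteins × terms) with aligned indices."""

    protein_ids: list[str]
    term_ids: list[str]
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (len(self.protein_ids), len(self.term_ids)):
            raise ValueError("probability matrix misaligned with indices")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")

    def drop_terms(self, terms: set[str]) -> "PredictionMatrix":
        keep = [j for j, t in enumerate(self.term_ids) if t not in terms]
        return PredictionMatrix(
            self.protein_ids, [self.term_ids[j] for j in keep], self.probs[:, keep]
        )


def fmax(preds: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """CAFA Fmax and its argmax threshold (smallest τ on ties)."""
    preds = np.asarray(preds, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    has_truth = truth.sum(axis=1) > 0
    if not has_truth.any():
        raise ValueError("no protein has a true term; Fmax undefined")
    n_with_truth = has_truth.sum()
    best_f, best_tau = 0.0, float(THRESHOLDS[0])
    for tau in THRESHOLDS:
        called = preds >= tau
        n_called = called.sum(axis=1)
        covered = n_called > 0
        if covered.any():
            tp = (called & (truth > 0)).sum(axis=1)
            prec = float(np.mean(tp[covered] / n_called[covered]))
        else:
            continue  # precision undefined at this τ
        rec = float(np.mean((called & (truth > 0)).sum(axis=1)[has_truth] / truth.sum(axis=1)[has_truth]))
        if prec + rec > 0:
            f = 2 * prec * rec / (prec + rec)
            if f > best_f + 1e-12:
                best_f, best_tau = f, float(tau)
    return best_f, best_tau


def _term_columns_with_positives(truth: np.ndarray) -> np.ndarray:
    return np.nonzero(truth.sum(axis=0) > 0)[0]


def macro_aupr(preds: np.ndarray, truth: np.ndarray) -> float:
    """Mean per-term area under precision–recall; 0-positive terms excluded."""
    cols = _term_columns_with_positives(truth)
    if len(cols) == 0:
        raise ValueError("no term has a positive example")
    return float(
        np.mean([average_precision_score(truth[:, j], preds[:, j]) for j in cols])
    )


def micro_aupr(preds: np.ndarray, truth: np.ndarray) -> float:
    """AUPR over flattened (protein, term) pairs."""
    y = np.asarray(truth).ravel()
    if y.sum() == 0:
        raise ValueError("no positives anywhere")
    return float(average_precision_score(y, np.asarray(preds).ravel()))


def per_term_auc(
    preds: np.ndarray, truth: np.ndarray, term_ids: list[str]
) -> dict[str, float]:
    """ROC AUC per term; terms lacking a positive or a negative are skipped."""
    out: dict[str, float] = {}
    for j, t in enumerate(term_ids):
        col = truth[:, j]
        if 0 < col.sum() < len(col):
            out[t] = float(roc_auc_score(col, preds[:, j]))
    return out


def term_centric_auc(preds: np.ndarray, truth: np.ndarray) -> float:
    """Unweighted mean of per-term ROC AUCs over scorable terms."""
    ids = [str(j) for j in range(truth.shape[1])]
    table = per_term_auc(preds, truth, ids)
    if not table:
        raise ValueError("no term is scorable (needs ≥1 positive and ≥1 negative)")
    return float(np.mean(list(table.values())))


@dataclass
class EvalReport:
    fmax: float
    fmax_threshold: float
    macro_aupr: float
    micro_aupr: float
    term_centric_auc: float
    per_term_auc: dict[str, float]
    n_proteins: int
    n_terms: int

    def to_dict(self) -> dict:
        return {
            "fmax": self.fmax,
            "fmax_threshold": self.fmax_threshold,
            "macro_aupr": self.macro_aupr,
            "micro_aupr": self.micro_aupr,
            "term_centric_auc": self.term_centric_auc,
            "per_term_auc": self.per_term_auc,
            "n_proteins": self.n_proteins,
            "n_terms": self.n_terms,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate(
    predictions: PredictionMatrix,
    truth: np.ndarray,
    exclude_terms: set[str] | None = None,
) -> EvalReport:
    """Full report; ``exclude_terms`` typically holds the aspect root."""
    preds = predictions
    truth = np.asarray(truth, dtype=np.float64)
    if exclude_terms:
        keep = [j for j, t in enumerate(preds.term_ids) if t not in exclude_terms]
        truth = truth[:, keep]
        preds = preds.drop_terms(set(exclude_terms))
    f, tau = fmax(preds.probs, truth)
    return EvalReport(
        fmax=f,
        fmax_threshold=tau,
        macro_aupr=macro_aupr(preds.probs, truth),
        micro_aupr=micro_aupr(preds.probs, truth),
        term_centric_auc=term_centric_auc(preds.probs, truth),
        per_term_auc=per_term_auc(preds.probs, truth, preds.term_ids),
        n_proteins=len(preds.protein_ids),
        n_terms=len(preds.term_ids),
    )
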