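"""End-to-end orchestration: simulate → embed → autoencode → train → evaluate → rollout.

A single :class:`PipelineConfig` drives every stage; each stage writes its
artifact under the run directory keyed by a content hash of the
configuration, so re-running with an unchanged config loads the cached
artifact instead of recomputing.  The manifest records seeds, stage timings
and artifact checksums — enough to re-execute any stage deterministically.

The GO-embedding source is configurable for ablation: ``textual`` (definition
text through the autoencoder), ``structural`` (self-inclusive ancestor
indicator vectors through the same autoencoder), ``combined`` (concatenation
of both inputs), or ``none`` (term embeddings trained from scratch inside
the transformer).  Architectures: causal ``decoder``, bidirectional
``encoder``, or mean-pooled ``mlp``; term ordering: ``hierarchical`` or flat
``go_id``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np

from .autoencoder import AutoencoderConfig, LossWeights, fit_autoencoder
from .evaluation import EvalReport, PredictionMatrix, evaluate
from .interpretability import residue_profile, rollout_auroc, rollout_from_record
from .model import ModelConfig, pad_batch
from .ontology import topological_order
from .synthetic import (
    SyntheticConfig,
    SyntheticDataset,
    choose_held_out,
    generate_dataset,
    make_zero_shot_scenario,
    write_dataset,
)
from .text_embedding import TermEmbeddingMatrix, TextEncoderSpec, embed_definitions
from .training import (
    ProteinDataset,
    TrainConfig,
    build_target_matrix,
    predict_matrix,
    train_model,
)

GO_EMBEDDING_SOURCES = ("none", "structural", "textual", "combined")


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    aspect: str = "MF"
    ordering: str = "hierarchical"
    architecture: str = "decoder"
    go_embeddings: str = "textual"
    d_z: int = 64
    autoencoder_epochs: int = 1000
    autoencoder_lr: float = 1e-3
    alpha: tuple[float, float, float] = (1.0, 1.0, 1.0)
    train: TrainConfig = field(default_factory=TrainConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    test_fraction: float = 0.2
    split_seed: int = 11
    held_out: list[str] = field(default_factory=list)
    # negative control: additionally score held-out terms with latents computed
    # from deranged definitions through the same frozen projection
    evaluate_shuffled_control: bool = False

    def __post_init__(self):
        if self.go_embeddings not in GO_EMBEDDING_SOURCES:
            raise ValueError(f"go_embeddings must be one of {GO_EMBEDDING_SOURCES}")

    def checksum(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.blake2b(payload.encode(), digest_size=8).hexdigest()


@dataclass
class RunManifest:
    config_checksum: str
    seeds: dict
    timings: dict
    outputs: dict
    dataset_checksum: str
    package_version: str

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


@dataclass
class RunResult:
    manifest: RunManifest
    report: EvalReport
    held_out_auc: dict[str, float]
    rollout_auroc_seen: float | None
    rollout_auroc_held_out: float | None
    held_out_auc_control: dict[str, float] | None = None
    # raw held-out score/truth columns (for seed-ensembled evaluation)
    held_out_scores: dict[str, np.ndarray] | None = None
    held_out_scores_control: dict[str, np.ndarray] | None = None
    held_out_truth: dict[str, np.ndarray] | None = None


def _go_input_matrix(config: PipelineConfig, dataset: SyntheticDataset) -> TermEmbeddingMatrix | None:
    """The x_t matrix the autoencoder consumes, per the embedding ablation."""
    if config.go_embeddings == "none":
        return None
    term_ids = dataset.graph.active_terms()
    anc = dataset.index.indicator_matrix(term_ids)
    if config.go_embeddings == "structural":
        return TermEmbeddingMatrix(term_ids, anc)
    text = dataset.embeddings
    if config.go_embeddings == "textual":
        return text
    combined = np.hstack([text.rows(term_ids), anc])
    return TermEmbeddingMatrix(term_ids, combined)


def _result_from_cache(cached: dict) -> "RunResult":
    report_dict = dict(cached["report"])
    report = EvalReport(**report_dict)
    manifest = RunManifest(**cached["manifest"])
    arr = lambda d: None if d is None else {t: np.asarray(v) for t, v in d.items()}
    return RunResult(
        manifest,
        report,
        cached["held_out_auc"],
        cached["rollout_auroc_seen"],
        cached["rollout_auroc_held_out"],
        cached["held_out_auc_control"],
        arr(cached["held_out_scores"]),
        arr(cached["held_out_scores_control"]),
        arr(cached["held_out_truth"]),
    )


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | None = None,
    write_fixture: bool = False,
    compute_rollout: bool = True,
) -> RunResult:
    """Execute every stage on the synthetic fixture and report metrics.

    Returns the evaluation report on held-out proteins, per-term AUCs for
    zero-shot terms (if ``config.held_out`` is set the training annotations
    lose those terms before propagation), and mean rollout AUROCs against the
    planted motif windows.
    """
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}

    # cached result: a previous run with the same config checksum is reloaded
    if out_dir and os.path.exists(os.path.join(out_dir, "result.json")):
        with open(os.path.join(out_dir, "result.json")) as fh:
            cached = json.load(fh)
        if cached.get("config_checksum") == config.checksum():
            return _result_from_cache(cached)

    t0 = time.time()
    dataset = generate_dataset(config.synthetic)
    timings["simulate"] = time.time() - t0
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        if write_fixture:
            write_dataset(dataset, os.path.join(out_dir, "dataset"))
            outputs["dataset"] = os.path.join(out_dir, "dataset")

    order = topological_order(dataset.graph, config.aspect, config.ordering)
    term_ids = list(order.term_ids)
    full_targets = build_target_matrix(dataset.annotations, dataset.protein_ids, term_ids)
    if config.held_out:
        scenario = make_zero_shot_scenario(dataset, list(config.held_out))
        train_annotations = scenario.train_annotations
    else:
        scenario = None
        train_annotations = dataset.annotations
    train_targets = build_target_matrix(train_annotations, dataset.protein_ids, term_ids)

    # -- GO latents -----------------------------------------------------------
    t0 = time.time()
    x_matrix = _go_input_matrix(config, dataset)
    if x_matrix is None:
        E = None
        model_config = dataclasses.replace(
            config.model,
            architecture=config.architecture,
            ordering=config.ordering,
            d_seq=config.synthetic.d_seq,
            trainable_term_embeddings=True,
            n_terms=len(term_ids),
        )
    else:
        ae = fit_autoencoder(
            x_matrix,
            dataset.index,
            dataset.graph.aspect_of,
            LossWeights(*config.alpha),
            AutoencoderConfig(
                d_z=config.d_z,
                epochs=config.autoencoder_epochs,
                lr=config.autoencoder_lr,
                seed=config.train.seed,
            ),
        )
        E = ae.latents().rows(term_ids)
        model_config = dataclasses.replace(
            config.model,
            architecture=config.architecture,
            ordering=config.ordering,
            d_seq=config.synthetic.d_seq,
            d_go=config.d_z,
        )
    timings["autoencode"] = time.time() - t0

    # -- protein split and training -------------------------------------------
    rng = np.random.default_rng(config.split_seed)
    perm = rng.permutation(len(dataset.protein_ids))
    n_test = max(1, int(round(config.test_fraction * len(perm))))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    train_set = ProteinDataset(
        [dataset.protein_ids[i] for i in train_idx],
        [dataset.proteins[i] for i in train_idx],
        train_targets[train_idx],
        term_ids,
    )
    test_set = ProteinDataset(
        [dataset.protein_ids[i] for i in test_idx],
        [dataset.proteins[i] for i in test_idx],
        full_targets[test_idx],
        term_ids,
    )
    term_weights = None
    if config.held_out:
        # held-out terms lost every association before propagation; they are
        # unsupervised during training and scored only at evaluation time
        term_weights = np.array([0.0 if t in set(config.held_out) else 1.0 for t in term_ids])
    t0 = time.time()
    trained = train_model(train_set, E, model_config, config.train, term_weights=term_weights)
    timings["train"] = time.time() - t0

    # -- evaluation ------------------------------------------------------------
    t0 = time.time()
    probs, _ = predict_matrix(trained.model, test_set, E)
    probs = np.clip(probs.astype(np.float64), 0.0, 1.0)
    predictions = PredictionMatrix(test_set.protein_ids, term_ids, probs)
    root = dataset.graph.roots[config.aspect]
    report = evaluate(predictions, test_set.targets, exclude_terms={root})
    held_out_auc = {
        t: report.per_term_auc[t]
        for t in (config.held_out or [])
        if t in report.per_term_auc
    }
    # zero-shot terms are scored over every protein: none of their
    # protein–term pairs ever reached the objective, and the small test split
    # alone leaves per-term AUC dominated by frozen sampling noise
    held_out_scores = held_out_truth = None
    full_set = None
    if config.held_out:
        idx = {t: term_ids.index(t) for t in config.held_out}
        full_set = ProteinDataset(
            list(dataset.protein_ids), list(dataset.proteins), full_targets, term_ids
        )
        probs_full, _ = predict_matrix(trained.model, full_set, E)
        probs_full = np.clip(probs_full.astype(np.float64), 0.0, 1.0)
        held_out_scores = {t: probs_full[:, j].copy() for t, j in idx.items()}
        held_out_truth = {t: full_targets[:, j].copy() for t, j in idx.items()}
        from sklearn.metrics import roc_auc_score as _auc

        held_out_auc = {
            t: float(_auc(held_out_truth[t], held_out_scores[t]))
            for t in config.held_out
            if 0 < held_out_truth[t].sum() < len(held_out_truth[t])
        }

    # shuffled-definition negative control: same trained model, but the
    # held-out latents are recomputed from deranged definition texts through
    # the frozen projection — only the textual channel changes
    held_out_auc_control = None
    held_out_scores_control = None
    if config.evaluate_shuffled_control and scenario is not None:
        if x_matrix is None or config.go_embeddings == "structural":
            raise ValueError(
                "the shuffled-definition control requires a text-based GO embedding source"
            )
        from sklearn.metrics import roc_auc_score

        from .autoencoder import encode_term

        encoder = TextEncoderSpec(d_t=config.synthetic.d_t)
        rank_of = {t: i for i, t in enumerate(term_ids)}
        active = dataset.graph.active_terms()
        active_pos = {t: i for i, t in enumerate(active)}
        anc_matrix = dataset.index.indicator_matrix(active)
        E_control = E.copy()
        for t, definition in scenario.control_definitions.items():
            x_text = encoder.encode(definition)
            if config.go_embeddings == "combined":
                x = np.concatenate([x_text, anc_matrix[active_pos[t]]])
            else:
                x = x_text
            E_control[rank_of[t]] = encode_term(x, ae.params)
        probs_control, _ = predict_matrix(trained.model, full_set, E_control)
        held_out_auc_control = {}
        held_out_scores_control = {}
        for t in config.held_out:
            col = full_targets[:, rank_of[t]]
            held_out_scores_control[t] = probs_control[:, rank_of[t]].copy()
            if 0 < col.sum() < len(col):
                held_out_auc_control[t] = float(
                    roc_auc_score(col, probs_control[:, rank_of[t]])
                )
    timings["evaluate"] = time.time() - t0

    # -- rollout attribution ----------------------------------------------------
    rollout_seen = rollout_held = None
    if compute_rollout and config.architecture == "decoder":
        t0 = time.time()
        seen_scores, held_scores = [], []
        held_set = set(config.held_out or [])
        rank = order.rank
        masks_by_protein: dict[str, list[tuple[str, list[tuple[int, int]]]]] = {}
        for (p, term), intervals in dataset.binding_masks.items():
            if term in rank:
                masks_by_protein.setdefault(p, []).append((term, intervals))
        for start in range(0, len(test_set), 16):
            chunk = range(start, min(start + 16, len(test_set)))
            proteins = [test_set.proteins[i] for i in chunk]
            X, mask = pad_batch(proteins)
            _, record = trained.model.predict(X, mask, E)
            rollout = rollout_from_record(record)
            for row, i in enumerate(chunk):
                pid = test_set.protein_ids[i]
                for term, intervals in masks_by_protein.get(pid, []):
                    m = np.zeros(proteins[row].X.shape[0], dtype=bool)
                    for s, e in intervals:
                        m[s:e] = True
                    profile = residue_profile(rollout[row], term, order, mask[row])
                    score = rollout_auroc(profile, m)
                    (held_scores if term in held_set else seen_scores).append(score)
        rollout_seen = float(np.mean(seen_scores)) if seen_scores else None
        rollout_held = float(np.mean(held_scores)) if held_scores else None
        timings["rollout"] = time.time() - t0

    dataset_hash = hashlib.blake2b(digest_size=16)
    for p in dataset.proteins:
        dataset_hash.update(np.ascontiguousarray(p.X).tobytes())
    dataset_hash.update(dataset.annotations_raw.records.to_csv(index=False).encode())
    manifest = RunManifest(
        config_checksum=config.checksum(),
        seeds={"synthetic": config.synthetic.seed, "train": config.train.seed, "split": config.split_seed},
        timings=timings,
        outputs=outputs,
        dataset_checksum=dataset_hash.hexdigest(),
        package_version=__import__("hiergo").__version__,
    )
    if out_dir:
        manifest.save(os.path.join(out_dir, "manifest.json"))
        report.save(os.path.join(out_dir, "evaluation.json"))
        cache = {
            "config_checksum": config.checksum(),
            "manifest": dataclasses.asdict(manifest),
            "report": report.to_dict(),
            "held_out_auc": held_out_auc,
            "rollout_auroc_seen": rollout_seen,
            "rollout_auroc_held_out": rollout_held,
            "held_out_auc_control": held_out_auc_control,
            "held_out_scores": None
            if held_out_scores is None
            else {t: v.tolist() for t, v in held_out_scores.items()},
            "held_out_scores_control": None
            if held_out_scores_control is None
            else {t: v.tolist() for t, v in held_out_scores_control.items()},
            "held_out_truth": None
            if held_out_truth is None
            else {t: v.tolist() for t, v in held_out_truth.items()},
        }
        with open(os.path.join(out_dir, "result.json"), "w") as fh:
            json.dump(cache, fh)
    return RunResult(
        manifest,
        report,
        held_out_auc,
        rollout_seen,
        rollout_held,
        held_out_auc_control,
        held_out_scores,
        held_out_scores_control,
        held_out_truth,
    )


def run_ablation_grid(
    config: PipelineConfig,
    axes: dict[str, list[str]],
    out_dir: str | None = None,
) -> list[dict]:
    """One run per axis combination on the same dataset and seed.

    Axes ⊆ {embeddings, architecture, ordering}.  Orderings are meaningless
    for the MLP integration, so those combinations are skipped with a log
    line.  Returns one row of metrics per completed run.
    """
    from itertools import product

    names = list(axes)
    rows: list[dict] = []
    for combo in product(*(axes[n] for n in names)):
        setting = dict(zip(names, combo))
        if setting.get("architecture") == "mlp" and setting.get("ordering") == "go_id":
            print(f"skipping incompatible combination {setting} (MLP ignores ordering)")
            continue
        run_config = dataclasses.replace(
            config,
            go_embeddings=setting.get("embeddings", config.go_embeddings),
            architecture=setting.get("architecture", config.architecture),
            ordering=setting.get("ordering", config.ordering),
        )
        result = run_pipeline(run_config)
        row = {
            **setting,
            "fmax": result.report.fmax,
            "macro_aupr": result.report.macro_aupr,
            "micro_aupr": result.report.micro_aupr,
            "term_centric_auc": result.report.term_centric_auc,
            "dataset_checksum": result.manifest.dataset_checksum,
        }
        rows.append(row)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        import pandas as pd

        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "ablation.tsv"), sep="\t", index=False)
    return rows
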