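"""Download-free synthetic fixtures with the statistical structure the method assumes.

Generates (i) a random rooted DAG ontology with three aspects whose term
definitions are templated sentences carrying signature tokens shared along
parent–child edges (so text similarity correlates with ontology proximity),
(ii) proteins as residue-embedding matrices with term-specific motif windows
planted at a configurable signal-to-noise ratio, (iii) upward-closed
annotation tables, and (iv) zero-shot scenarios including a
shuffled-definition negative control.

Two features of real annotation data are emulated because the method's
zero-shot mechanism depends on them.  First, motifs are *hierarchically
structured* the way protein families are: a leaf term's planted window
carries a family component shared with its sibling leaves (the image of the
parent's signature token) plus a leaf-specific component orthonormalized
across leaves — related functions share sequence features.  Second,
annotations *co-occur*: each protein draws its leaf annotations
preferentially from the children of one "theme" parent, so functionally
related terms appear on the same proteins, as they do in curated
annotation corpora.  Both component sets are images of signature-token hash
vectors under a fixed random linear map (QR-orthonormalized, which in this
dimension perturbs the projections only mildly), keeping the planted
text→function mapping linear and hence recoverable — including for terms
held out of training.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .model import ResidueEmbeddings
from .ontology import (
    ASPECTS,
    AncestorIndex,
    AnnotationTable,
    OntologyGraph,
    ancestor_index,
    make_zero_shot_split,
    parse_obo,
    propagate_true_path,
)
from .text_embedding import (
    TermEmbeddingMatrix,
    TextEncoderSpec,
    _token_vector,
    embed_definitions,
)

ASPECT_NAMESPACE = {
    "MF": "molecular_function",
    "BP": "biological_process",
    "CC": "cellular_component",
}


@dataclass
class SyntheticConfig:
    leaves_per_aspect: int = 50
    internal_per_aspect: int = 15
    max_depth: int = 4
    max_parents: int = 3
    leaf_max_parents: int = 1  # leaves sit under a single family by default
    n_proteins: int = 300
    length_range: tuple[int, int] = (40, 120)
    d_seq: int = 96
    d_t: int = 256
    motif_len: int = 8
    snr: float = 3.0
    annotations_per_protein: tuple[int, int] = (1, 3)
    annotation_aspect: str = "MF"
    max_descendant_tokens: int = 8
    theme_mix: float = 0.7  # weight of the shared family component in a motif
    parent_token_repeats: int = 2  # how often parent tokens appear in a definition
    themes_per_protein: float = 1.5  # expected active themes (independent Bernoulli)
    off_theme_rate: float = 0.2  # chance an annotation ignores the protein's themes
    seed: int = 0

    def __post_init__(self):
        for v in (self.leaves_per_aspect, self.internal_per_aspect, self.n_proteins,
                  self.motif_len, self.d_seq, self.d_t):
            if v <= 0:
                raise ValueError("all counts must be positive")
        if self.leaves_per_aspect + self.internal_per_aspect > self.d_seq:
            raise ValueError(
                "orthonormal motif components need leaves + internal terms <= d_seq"
            )
        if not 0.0 <= self.theme_mix < 1.0:
            raise ValueError("theme_mix must lie in [0, 1)")

    def checksum(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.blake2b(payload.encode(), digest_size=8).hexdigest()


def _term_id(aspect: str, number: int) -> str:
    return f"SG:{ASPECTS.index(aspect)}{number:06d}"


def _sig_token(term_id: str) -> str:
    return "sig" + term_id.replace(":", "")


def generate_ontology(config: SyntheticConfig) -> tuple[str, OntologyGraph]:
    """Random three-aspect DAG as OBO text plus its parsed graph.

    Every non-root term draws 1–``max_parents`` parents from strictly
    shallower levels of the same aspect.  Definitions embed the term's own
    signature token, its parents' tokens, and (for internal terms) a capped
    sample of descendant-leaf tokens, giving the text encoder a path from
    definition to planted function.
    """
    rng = np.random.default_rng(config.seed)
    stanzas: list[str] = ["format-version: 1.2\nontology: synthetic-go"]
    all_terms: dict[str, dict] = {}
    for aspect in ASPECTS:
        ns = ASPECT_NAMESPACE[aspect]
        root = _term_id(aspect, 0)
        levels: dict[int, list[str]] = {0: [root]}
        all_terms[root] = {"aspect": aspect, "parents": [], "level": 0, "leaf": False}
        counter = 1
        n_internal_levels = config.max_depth - 1
        per_level = int(np.ceil(config.internal_per_aspect / n_internal_levels))
        for depth in range(1, config.max_depth):
            n_here = min(per_level, config.internal_per_aspect - (depth - 1) * per_level)
            levels[depth] = []
            for _ in range(max(n_here, 0)):
                tid = _term_id(aspect, counter)
                counter += 1
                pool = [t for d in range(depth) for t in levels[d]]
                k = int(rng.integers(1, min(config.max_parents, len(pool)) + 1))
                parents = sorted(rng.choice(pool, size=k, replace=False))
                levels[depth].append(tid)
                all_terms[tid] = {
                    "aspect": aspect, "parents": list(parents), "level": depth, "leaf": False,
                }
        leaf_level = config.max_depth
        levels[leaf_level] = []
        pool = [t for d in range(1, leaf_level) for t in levels[d]] or [root]
        for _ in range(config.leaves_per_aspect):
            tid = _term_id(aspect, counter)
            counter += 1
            k = int(rng.integers(1, min(config.leaf_max_parents, len(pool)) + 1))
            parents = sorted(rng.choice(pool, size=k, replace=False))
            levels[leaf_level].append(tid)
            all_terms[tid] = {
                "aspect": aspect, "parents": list(parents), "level": leaf_level, "leaf": True,
            }
    # descendant-leaf tokens for internal terms
    children: dict[str, list[str]] = {t: [] for t in all_terms}
    for tid, info in all_terms.items():
        for p in info["parents"]:
            children[p].append(tid)

    def descendant_leaves(tid: str) -> list[str]:
        out, stack = [], [tid]
        seen = set()
        while stack:
            node = stack.pop()
            for ch in children[node]:
                if ch not in seen:
                    seen.add(ch)
                    if all_terms[ch]["leaf"]:
                        out.append(ch)
                    stack.append(ch)
        return sorted(out)

    for tid in sorted(all_terms):
        info = all_terms[tid]
        aspect = info["aspect"]
        tokens = [_sig_token(tid)] + [
            _sig_token(p) for p in info["parents"] for _ in range(config.parent_token_repeats)
        ]
        if not info["leaf"]:
            desc = descendant_leaves(tid)
            if len(desc) > config.max_descendant_tokens:
                idx = rng.choice(len(desc), size=config.max_descendant_tokens, replace=False)
                desc = [desc[i] for i in sorted(idx)]
            tokens += [_sig_token(d) for d in desc]
        kind = "leaf" if info["leaf"] else ("root" if info["level"] == 0 else "branch")
        definition = (
            f"A synthetic {ASPECT_NAMESPACE[aspect].replace('_', ' ')} {kind} process "
            f"characterised by {' '.join(tokens)} within the simulated cell."
        )
        stanza = [
            "[Term]",
            f"id: {tid}",
            f"name: synthetic term {tid}",
            f"namespace: {ASPECT_NAMESPACE[aspect]}",
            f'def: "{definition}" [SG:curators]',
        ]
        stanza += [f"is_a: {p}" for p in info["parents"]]
        stanzas.append("\n".join(stanza))
    obo_text = "\n\n".join(stanzas) + "\n"
    return obo_text, parse_obo(obo_text)


def leaf_signatures(
    graph: OntologyGraph, config: SyntheticConfig
) -> dict[str, np.ndarray]:
    """Unit-norm planted signature per annotated-aspect leaf.

    Each signature mixes a leaf-specific component (orthonormal across
    leaves) with the mean of its parents' family components (orthonormal
    across internal terms and against the leaf set), weighted by
    ``theme_mix``; sibling leaves thereby share part of their motif, the way
    members of a protein family share a domain.  All components are
    QR-orthonormalized images of signature-token hash vectors under one fixed
    random projection, so the whole construction stays linear in the
    definition text.
    """
    aspect = config.annotation_aspect
    leaves = graph.leaves(aspect)
    internal = sorted(
        t
        for t in graph.aspect_terms(aspect)
        if t not in set(leaves) and t != graph.roots[aspect]
    )
    rng = np.random.default_rng(config.seed + 1)
    P = rng.standard_normal((config.d_seq, config.d_t)) / np.sqrt(config.d_t)
    cols = leaves + internal
    E = np.stack([_token_vector(_sig_token(t), config.d_t, seed=0) for t in cols], axis=1)
    A = P @ E  # (d_seq, n_leaves + n_internal)
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))  # keep Q_k aligned with A_k
    basis = {t: Q[:, i] for i, t in enumerate(cols)}
    rho = config.theme_mix
    out: dict[str, np.ndarray] = {}
    for leaf in leaves:
        parents = sorted(p for p in graph.parents(leaf) if p in basis)
        if parents and rho > 0:
            family = np.mean([basis[p] for p in parents], axis=0)
            family /= np.linalg.norm(family)
            vec = np.sqrt(1.0 - rho**2) * basis[leaf] + rho * family
        else:
            vec = basis[leaf]
        out[leaf] = vec / np.linalg.norm(vec)
    return out


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    obo_text: str
    graph: OntologyGraph
    index: AncestorIndex
    embeddings: TermEmbeddingMatrix
    protein_ids: list[str]
    proteins: list[ResidueEmbeddings]
    annotations_raw: AnnotationTable
    annotations: AnnotationTable  # true-path propagated
    binding_masks: dict[tuple[str, str], list[tuple[int, int]]]
    signatures: dict[str, np.ndarray]
    manifest: dict


def generate_proteins(
    config: SyntheticConfig, graph: OntologyGraph
) -> tuple[list[str], list[ResidueEmbeddings], AnnotationTable, dict]:
    """Proteins as residue-embedding matrices with planted motif windows.

    Each protein activates every *theme* — an internal term with at least two
    leaf children — independently with probability
    ``themes_per_protein / n_themes``; every active theme contributes 1–2
    leaf annotations from its children (escaping to a uniform leaf at
    ``off_theme_rate``), and themeless proteins carry one uniform
    annotation.  Related leaves thereby co-occur on proteins the way
    annotations co-occur in curated corpora, while the *independent*
    activation keeps different families statistically uncoupled — presence
    of one family says nothing about another, as required for family-level
    negative controls to read chance.
    """
    rng = np.random.default_rng(config.seed + 2)
    sigs = leaf_signatures(graph, config)
    leaves = sorted(sigs)
    leaf_set = set(leaves)
    themes = sorted(
        t
        for t in graph.aspect_terms(config.annotation_aspect)
        if len(graph.children(t) & leaf_set) >= 2
    )
    lo, hi = config.length_range
    a_lo, a_hi = config.annotations_per_protein
    noise_scale = 1.0 / np.sqrt(config.d_seq)
    protein_ids, proteins, pairs, masks = [], [], [], {}
    for i in range(config.n_proteins):
        pid = f"P{i:05d}"
        L = int(rng.integers(lo, hi + 1))
        X = rng.normal(0.0, noise_scale, size=(L, config.d_seq))
        if themes:
            p_active = min(1.0, config.themes_per_protein / len(themes))
            flags = rng.random(len(themes)) < p_active
            own_themes = [t for t, f in zip(themes, flags) if f]
        else:
            own_themes = []
        # each active family contributes draws independently of the others,
        # so one term's presence carries no information about another family
        # (no family is ever forced: forcing would couple them negatively);
        # themeless proteins carry a single uniform annotation, and the cap
        # only trims the rare over-quota protein
        quotas = {t: int(rng.integers(1, 3)) for t in own_themes}
        while sum(quotas.values()) > a_hi:
            t = str(rng.choice([t for t, q in quotas.items() if q > 0]))
            quotas[t] -= 1
        chosen_set: set[str] = set()
        for theme, quota in quotas.items():
            theme_leaves = sorted(graph.children(theme) & leaf_set)
            for _ in range(quota):
                pool = (
                    leaves
                    if (not theme_leaves or rng.random() < config.off_theme_rate)
                    else theme_leaves
                )
                remaining = [t for t in pool if t not in chosen_set] or [
                    t for t in leaves if t not in chosen_set
                ]
                if remaining:
                    chosen_set.add(str(rng.choice(remaining)))
        if not chosen_set and leaves:
            chosen_set.add(str(rng.choice(leaves)))
        chosen = sorted(chosen_set)
        taken: list[tuple[int, int]] = []
        for leaf in chosen:
            placed = None
            for _ in range(50):
                start = int(rng.integers(0, L - config.motif_len + 1))
                window = (start, start + config.motif_len)
                if all(window[1] <= s or window[0] >= e for s, e in taken):
                    placed = window
                    break
            if placed is None:
                placed = (0, config.motif_len)
            taken.append(placed)
            s, e = placed
            X[s:e] = config.snr * sigs[leaf] + rng.normal(0.0, noise_scale, size=(e - s, config.d_seq))
            pairs.append((pid, leaf))
            masks[(pid, leaf)] = [placed]
        protein_ids.append(pid)
        proteins.append(ResidueEmbeddings(X))
    return protein_ids, proteins, AnnotationTable.from_pairs(pairs), masks


def generate_dataset(
    config: SyntheticConfig, encoder: TextEncoderSpec | None = None
) -> SyntheticDataset:
    """Full fixture: ontology + definitions + embeddings + proteins + annotations."""
    obo_text, graph = generate_ontology(config)
    index = ancestor_index(graph, include_self=True)
    enc = encoder or TextEncoderSpec(d_t=config.d_t)
    terms = [graph.terms[t] for t in graph.active_terms()]
    embeddings = embed_definitions(terms, enc)
    protein_ids, proteins, raw, masks = generate_proteins(config, graph)
    propagated = propagate_true_path(raw, index)
    manifest = {"seed": config.seed, "config_checksum": config.checksum()}
    return SyntheticDataset(
        config=config,
        obo_text=obo_text,
        graph=graph,
        index=index,
        embeddings=embeddings,
        protein_ids=protein_ids,
        proteins=proteins,
        annotations_raw=raw,
        annotations=propagated,
        binding_masks=masks,
        signatures=leaf_signatures(graph, config),
        manifest=manifest,
    )


def choose_held_out(
    dataset: SyntheticDataset, n: int = 3, min_annotations: int = 10
) -> list[str]:
    """Held-out leaves for the zero-shot protocol.

    Zero-shot transfer through definitions requires the held-out term's
    *family* to be represented in training: candidates must be well
    annotated (≥ ``min_annotations``) and are ranked by the fraction of
    their proteins that also carry an annotated sibling leaf — the
    co-annotation support the textual channel rides on (the analogue of
    holding out only well-supported classes in real corpora).  Terms are
    taken from pairwise-disjoint branches so a shuffled-definition control
    swaps semantics *across* families.  Deterministic given the dataset.
    """
    counts = dataset.annotations_raw.records["term_id"].value_counts()
    leaf_set = {t for a in ("MF", "BP", "CC") for t in dataset.graph.leaves(a)}
    by_protein: dict[str, set[str]] = {}
    for p, t in dataset.annotations_raw.records.itertuples(index=False):
        by_protein.setdefault(p, set()).add(t)

    def support(term: str) -> float:
        siblings: set[str] = set()
        for parent in dataset.graph.parents(term):
            siblings |= dataset.graph.children(parent) & leaf_set
        siblings -= {term}
        co = sum(1 for terms in by_protein.values() if term in terms and terms & siblings)
        return co / counts[term]

    candidates = [
        str(t) for t in counts.index if str(t) in leaf_set and counts[t] >= min_annotations
    ]
    if len(candidates) < n:  # small fixtures: fall back to raw counts
        candidates = [str(t) for t in counts.index if str(t) in leaf_set]
    ranked = sorted(candidates, key=lambda t: (-support(t), t))
    chosen: list[str] = []
    used_parents: set[str] = set()
    for t in ranked:
        parents = dataset.graph.parents(t)
        if parents & used_parents:
            continue
        chosen.append(t)
        used_parents |= parents
        if len(chosen) == n:
            break
    for t in ranked:  # fill if branch-disjointness is unattainable
        if len(chosen) == n:
            break
        if t not in chosen:
            chosen.append(t)
    return sorted(chosen)


@dataclass
class ZeroShotScenario:
    train_annotations: AnnotationTable  # held-out associations removed, then propagated
    held_out: frozenset[str]
    control_definitions: dict[str, str]  # deranged definition per held-out term


def make_zero_shot_scenario(
    dataset: SyntheticDataset, held_out: list[str]
) -> ZeroShotScenario:
    """Zero-shot split plus a shuffled-definition negative control.

    The control rotates definitions among the held-out terms (a derangement
    for any n ≥ 2), destroying the text→function link while keeping the
    marginal text statistics intact.
    """
    for t in held_out:
        if t not in dataset.graph.dag.nodes or dataset.graph.children(t):
            raise ValueError(f"held-out term {t!r} must be an ontology leaf")
        if t not in set(dataset.annotations_raw.records["term_id"]):
            import warnings

            warnings.warn(f"held-out term {t} has no annotated protein")
    train, held = make_zero_shot_split(dataset.annotations_raw, set(held_out), dataset.index)
    ordered = sorted(held_out)
    rotated = ordered[1:] + ordered[:1]
    control = {t: dataset.graph.definition(src) for t, src in zip(ordered, rotated)}
    return ZeroShotScenario(train_annotations=train, held_out=held, control_definitions=control)


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Persist the fixture as plain-text/npz files plus a manifest."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "ontology.obo"), "w") as fh:
        fh.write(dataset.obo_text)
    dataset.annotations_raw.records.to_csv(
        os.path.join(out_dir, "annotations.tsv"), sep="\t", index=False
    )
    np.savez(
        os.path.join(out_dir, "proteins.npz"),
        **{pid: p.X for pid, p in zip(dataset.protein_ids, dataset.proteins)},
    )
    with open(os.path.join(out_dir, "masks.tsv"), "w") as fh:
        fh.write("protein_id\tterm_id\tstart\tend\n")
        for (pid, term), intervals in sorted(dataset.binding_masks.items()):
            for s, e in intervals:
                fh.write(f"{pid}\t{term}\t{s}\t{e}\n")
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(dataset.manifest, fh, indent=2)
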