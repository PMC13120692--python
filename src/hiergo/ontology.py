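"""Gene Ontology graph machinery.

Parses OBO documents into a rooted DAG per aspect (molecular function,
biological process, cellular component), computes transitive ancestor
closures, propagates protein annotations upward by the true path rule,
produces the deterministic topological orderings the hierarchical decoder
relies on, and builds zero-shot annotation splits in which selected terms are
stripped from the training records *before* propagation.
"""

from __future__ import annotations

import io
import re
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd

DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

NAMESPACE_TO_ASPECT = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}

ASPECTS = ("MF", "BP", "CC")


class OntologyError(ValueError):
    """Structural or referential problem in an ontology document."""


@dataclass(frozen=True)
class GoTerm:
    id: str
    name: str
    definition: str
    aspect: str | None
    obsolete: bool = False


_DEF_CITATION = re.compile(r"\s*\[[^\]]*\]\s*$")


def _clean_definition(raw: str | None) -> str:
    """Strip OBO quoting and the trailing citation bracket from a def field."""
    if not raw:
        return ""
    text = raw.strip()
    text = _DEF_CITATION.sub("", text)
    if text.startswith('"') and text.endswith('"'):
        text = text[1:-1]
    return text


class OntologyGraph:
    """A parsed ontology: terms, child→parent edges, one root per aspect.

    ``dag`` is a networkx DiGraph whose edges point from child to parent, so
    reachability *along* edges means "is an ancestor of me".
    """

    def __init__(
        self,
        terms: dict[str, GoTerm],
        edges: list[tuple[str, str, str]],
        retained_relations: frozenset[str] = DEFAULT_RELATIONS,
    ):
        self.terms = terms
        self.retained_relations = frozenset(retained_relations)
        self.dag = nx.DiGraph()
        for tid, term in terms.items():
            if not term.obsolete:
                self.dag.add_node(tid)
        for child, parent, rel in edges:
            if rel not in self.retained_relations:
                continue
            if terms[child].obsolete or terms[parent].obsolete:
                continue
            self.dag.add_edge(child, parent, relation=rel)
        if not nx.is_directed_acyclic_graph(self.dag):
            cycle = nx.find_cycle(self.dag)
            raise OntologyError(f"ontology contains a cycle through {cycle[0][0]!r}")
        self._assign_aspects()

    # -- structure ------------------------------------------------------------
    def _assign_aspects(self) -> None:
        self.roots: dict[str, str] = {}
        root_ids = [n for n in self.dag.nodes if self.dag.out_degree(n) == 0]
        for rid in root_ids:
            ns = getattr(self.terms[rid], "aspect", None)
            if ns is None:
                raise OntologyError(f"root term {rid!r} has no namespace")
            if ns in self.roots:
                raise OntologyError(f"aspect {ns} has two roots: {self.roots[ns]}, {rid}")
            self.roots[ns] = rid
        root_set = set(root_ids)
        self.aspect_of: dict[str, str] = {}
        aspect_by_root = {rid: a for a, rid in self.roots.items()}
        for node in self.dag.nodes:
            reach = {node} | nx.descendants(self.dag, node)
            reachable_roots = reach & root_set
            if len(reachable_roots) != 1:
                raise OntologyError(
                    f"term {node!r} reaches {len(reachable_roots)} aspect roots; expected exactly 1"
                )
            self.aspect_of[node] = aspect_by_root[reachable_roots.pop()]

    def active_terms(self) -> list[str]:
        """Non-obsolete term ids, sorted."""
        return sorted(self.dag.nodes)

    def aspect_terms(self, aspect: str) -> list[str]:
        return sorted(t for t in self.dag.nodes if self.aspect_of[t] == aspect)

    def parents(self, term: str) -> set[str]:
        return set(self.dag.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.dag.predecessors(term))

    def leaves(self, aspect: str | None = None) -> list[str]:
        nodes = self.dag.nodes if aspect is None else self.aspect_terms(aspect)
        return sorted(t for t in nodes if self.dag.in_degree(t) == 0)

    def definition(self, term: str) -> str:
        return self.terms[term].definition


def parse_obo(
    obo_text: str,
    retained_relations: frozenset[str] | set[str] = DEFAULT_RELATIONS,
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 document into an :class:`OntologyGraph`.

    Obsolete terms are kept as terms but stripped of all edges.  Only edges
    whose relation label is in ``retained_relations`` (default is_a/part_of)
    enter the DAG.  A term referencing an undeclared parent raises
    :class:`OntologyError`, as does any directed cycle.
    """
    multi = obonet.read_obo(io.StringIO(obo_text), ignore_obsolete=False)
    terms: dict[str, GoTerm] = {}
    edges: list[tuple[str, str, str]] = []
    for node, data in multi.nodes(data=True):
        if "name" not in data and not data.get("is_obsolete"):
            raise OntologyError(f"term {node!r} referenced as a parent but never declared")
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        terms[node] = GoTerm(
            id=node,
            name=data.get("name", ""),
            definition=_clean_definition(data.get("def")),
            aspect=NAMESPACE_TO_ASPECT.get(data.get("namespace", ""), None),
            obsolete=obsolete,
        )
    for child, parent, rel in multi.edges(keys=True):
        edges.append((child, parent, rel))
    return OntologyGraph(terms, edges, frozenset(retained_relations))


# -- ancestor closure ---------------------------------------------------------


class AncestorIndex:
    """Transitive ancestor closure per non-obsolete term.

    ``include_self=True`` (the default used for autoencoder targets, matching
    the anc2vec convention) adds each term to its own ancestor set.
    """

    def __init__(self, graph: OntologyGraph, include_self: bool = False):
        self.include_self = include_self
        self.ancestors: dict[str, frozenset[str]] = {}
        order = list(nx.topological_sort(graph.dag))  # child before parent
        for node in reversed(order):  # parents first
            anc: set[str] = set()
            for parent in graph.dag.successors(node):
                anc.add(parent)
                anc |= self.ancestors[parent]
            self.ancestors[node] = frozenset(anc)
        if include_self:
            self.ancestors = {t: s | {t} for t, s in self.ancestors.items()}
        self.term_ids = sorted(self.ancestors)

    def __len__(self) -> int:
        return len(self.ancestors)

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.ancestors[term]

    def __contains__(self, term: str) -> bool:
        return term in self.ancestors

    def indicator_matrix(self, term_order: list[str] | None = None) -> np.ndarray:
        """Binary (terms × terms) ancestor-indicator matrix in ``term_order``."""
        order = term_order or self.term_ids
        pos = {t: i for i, t in enumerate(order)}
        mat = np.zeros((len(order), len(order)))
        for t in order:
            for a in self.ancestors[t]:
                if a in pos:
                    mat[pos[t], pos[a]] = 1.0
        return mat


def ancestor_index(graph: OntologyGraph, include_self: bool = False) -> AncestorIndex:
    return AncestorIndex(graph, include_self=include_self)


# -- annotations --------------------------------------------------------------


@dataclass
class AnnotationTable:
    """(protein, term) association records; ``propagated`` marks true-path closure."""

    records: pd.DataFrame  # columns: protein_id, term_id
    propagated: bool = False

    def __post_init__(self):
        expected = ["protein_id", "term_id"]
        self.records = (
            self.records[expected]
            .drop_duplicates()
            .sort_values(expected)
            .reset_index(drop=True)
        )

    @classmethod
    def from_pairs(cls, pairs, propagated: bool = False) -> "AnnotationTable":
        df = pd.DataFrame(list(pairs), columns=["protein_id", "term_id"])
        return cls(df, propagated=propagated)

    def terms_of(self, protein: str) -> set[str]:
        mask = self.records["protein_id"] == protein
        return set(self.records.loc[mask, "term_id"])

    def proteins(self) -> list[str]:
        return sorted(self.records["protein_id"].unique())

    def __len__(self) -> int:
        return len(self.records)


def read_annotations(path_or_buffer) -> AnnotationTable:
    """Read protein→term records.

    Accepts the package's simple headered TSV (protein_id, term_id[, aspect])
    or GAF 2.x by column position (column 2 = protein, column 5 = GO id;
    evidence columns ignored; ``!`` comment lines skipped).
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("!")]
    if not lines:
        raise ValueError("empty annotation file")
    header = lines[0].split("\t")
    if "protein_id" in header and "term_id" in header:
        df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t")
        return AnnotationTable(df[["protein_id", "term_id"]])
    pairs = []
    for ln in lines:
        cols = ln.split("\t")
        if len(cols) < 5:
            raise ValueError(f"malformed GAF line (need ≥5 columns): {ln[:60]!r}")
        pairs.append((cols[1], cols[4]))
    return AnnotationTable.from_pairs(pairs)


def write_annotations(table: AnnotationTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def propagate_true_path(annotations: AnnotationTable, index: AncestorIndex) -> AnnotationTable:
    """Close each protein's term set upward over the ancestor index.

    Idempotent and monotone: applying twice equals applying once, and no
    input record is ever removed.
    """
    unknown = sorted(set(annotations.records["term_id"]) - set(index.ancestors))
    if unknown:
        raise ValueError(f"annotation term ids not in ontology index: {unknown}")
    pairs: set[tuple[str, str]] = set()
    for protein, term in annotations.records.itertuples(index=False):
        pairs.add((protein, term))
        for anc in index[term]:
            pairs.add((protein, anc))
    return AnnotationTable.from_pairs(sorted(pairs), propagated=True)


def make_zero_shot_split(
    annotations: AnnotationTable,
    held_out_terms: set[str],
    index: AncestorIndex,
) -> tuple[AnnotationTable, frozenset[str]]:
    """Strip held-out terms from the raw records, then propagate.

    Removal happens *before* true-path propagation, so a protein annotated
    only with a held-out leaf ends up with an empty propagated set; a held-out
    term can still surface as a propagated ancestor of a different retained
    annotation.
    """
    missing = sorted(set(held_out_terms) - set(index.ancestors))
    if missing:
        raise ValueError(f"held-out terms not in ontology: {missing}")
    kept = annotations.records[~annotations.records["term_id"].isin(held_out_terms)]
    train = propagate_true_path(AnnotationTable(kept.copy()), index)
    return train, frozenset(held_out_terms)


# -- topological ordering -----------------------------------------------------


@dataclass(frozen=True)
class TopologicalOrder:
    """Bijection between decoder rank and term id for a single aspect."""

    term_ids: tuple[str, ...]
    mode: str

    def rank_of(self, term: str) -> int:
        return self.term_ids.index(term)

    def __len__(self) -> int:
        return len(self.term_ids)

    @property
    def rank(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.term_ids)}


def topological_order(
    graph: OntologyGraph, aspect: str, mode: str = "hierarchical"
) -> TopologicalOrder:
    """Order one aspect's terms for decoding.

    ``hierarchical``: level-order from the aspect root, where a term's level
    is the length of the longest root→term path, so every parent occupies a
    strictly shallower level than each of its children; ties within a level
    break lexicographically by id.  ``go_id``: flat lexicographic sort (the
    flat-ordering ablation).
    """
    terms = graph.aspect_terms(aspect)
    if mode == "go_id":
        return TopologicalOrder(tuple(sorted(terms)), mode)
    if mode != "hierarchical":
        raise ValueError(f"unknown ordering mode {mode!r}")
    root = graph.roots[aspect]
    term_set = set(terms)
    level = {root: 0}
    # longest-path levels: process in topological (parent-before-child) order
    sub = graph.dag.subgraph(term_set)
    for node in reversed(list(nx.topological_sort(sub))):  # parents first
        if node == root:
            continue
        parents = [p for p in sub.successors(node)]
        if not parents:
            raise OntologyError(f"term {node!r} has no path to aspect root {root!r}")
        level[node] = 1 + max(level[p] for p in parents)
    ordered = sorted(term_set, key=lambda t: (level[t], t))
    return TopologicalOrder(tuple(ordered), "hierarchical")


# -- subsumption ranking ------------------------------------------------------


@dataclass
class SubsumptionReport:
    mrr: float
    hits_at_1: float
    hits_at_10: float
    auc: float
    n_children: int


def subsumption_ranking_eval(embeddings, graph: OntologyGraph) -> SubsumptionReport:
    """Rank candidate parents of each child by cosine similarity of embeddings.

    For every non-root term, all other terms are ranked by cosine similarity
    to the child; direct parents are the positives.  Reports mean reciprocal
    rank of the best-ranked parent, hits@{1,10} and the mean per-child ROC AUC
    of parents versus non-parents.
    """
    term_ids = embeddings.term_ids
    pos = {t: i for i, t in enumerate(term_ids)}
    missing = [t for t in graph.active_terms() if t not in pos]
    if missing:
        raise ValueError(f"terms without embedding rows: {missing[:5]}")
    X = embeddings.matrix
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = X / norms
    sims = U @ U.T
    rrs, h1, h10, aucs = [], [], [], []
    for child in graph.active_terms():
        parents = graph.parents(child)
        if not parents:
            continue
        i = pos[child]
        cand = [j for j, t in enumerate(term_ids) if t != child]
        scores = sims[i, cand]
        labels = np.array([term_ids[j] in parents for j in cand])
        from scipy.stats import rankdata

        # descending average ranks: ties share credit instead of following
        # index order
        desc_rank = rankdata(-scores, method="average")
        best = desc_rank[labels].min()
        rrs.append(1.0 / best)
        h1.append(1.0 if best <= 1 else 0.0)
        h10.append(1.0 if best <= 10 else 0.0)
        npos, nneg = labels.sum(), (~labels).sum()
        if npos and nneg:
            # Mann–Whitney AUC with 0.5 credit for ties
            r = rankdata(scores)
            aucs.append((r[labels].sum() - npos * (npos + 1) / 2) / (npos * nneg))
    return SubsumptionReport(
        mrr=float(np.mean(rrs)),
        hits_at_1=float(np.mean(h1)),
        hits_at_10=float(np.mean(h10)),
        auc=float(np.mean(aucs)) if aucs else float("nan"),
        n_children=len(rrs),
    )
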