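import numpy as np
import pytest

from hiergo.ontology import parse_obo


def make_obo(stanzas: list[str]) -> str:
    return "format-version: 1.2\nontology: test\n\n" + "\n\n".join(stanzas) + "\n"


def term_stanza(tid, name="t", namespace="molecular_function", parents=(), definition=None, obsolete=False):
    lines = [f"[Term]", f"id: {tid}", f"name: {name}", f"namespace: {namespace}"]
    if definition:
        lines.append(f'def: "{definition}" [ref:1]')
    for p in parents:
        lines.append(f"is_a: {p}")
    if obsolete:
        lines.append("is_obsolete: true")
    return "\n".join(lines)


@pytest.fixture
def chain_graph():
    """r ← a ← c, one aspect."""
    text = make_obo(
        [
            term_stanza("T:0", "root", definition="the root"),
            term_stanza("T:1", "a", parents=["T:0"], definition="mid level"),
            term_stanza("T:2", "c", parents=["T:1"], definition="leaf level"),
        ]
    )
    return parse_obo(text)


@pytest.fixture
def diamond_graph():
    """r ← {a, b} ← c."""
    text = make_obo(
        [
            term_stanza("T:0", "root", definition="the root"),
            term_stanza("T:a", "a", parents=["T:0"], definition="left"),
            term_stanza("T:b", "b", parents=["T:0"], definition="right"),
            term_stanza("T:c", "c", parents=["T:a", "T:b"], definition="bottom"),
        ]
    )
    return parse_obo(text)


def random_dag_obo(rng: np.random.Generator, n_terms: int = 50) -> str:
    """Single-aspect random DAG: term i draws parents among terms < i."""
    stanzas = [term_stanza("R:000", "root", definition="root term")]
    ids = ["R:000"]
    for i in range(1, n_terms):
        tid = f"R:{i:03d}"
        k = int(rng.integers(1, min(3, len(ids)) + 1))
        parents = list(rng.choice(ids, size=k, replace=False))
        stanzas.append(term_stanza(tid, f"term {i}", parents=parents, definition=f"definition {i}"))
        ids.append(tid)
    return make_obo(stanzas)
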