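"""Shared fixtures: tiny hand-built graphs and test-side brute-force oracles.

The brute-force helpers here deliberately avoid the package's traversal code
(and networkx): they recompute reachability by naive recursion over the raw
parent lists, so they can serve as independent oracles.
"""

from __future__ import annotations

import pytest

from hpoprofile.ontology_model import OntologyGraph, Term

ROOT = "HP:0000118"


def make_graph(*terms: Term) -> OntologyGraph:
    return OntologyGraph(terms)


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    """Root with two categories A and B sharing one leaf (DAG diamond).

    A's subtree: a1 (leaf), a2 -> a3 (leaf).  The shared leaf descends from
    both a2 (in A) and B directly.  One detached obsolete term for flag
    handling.
    """
    return make_graph(
        Term(id=ROOT, label="Phenotypic abnormality"),
        Term(id="HP:0000001", label="Cat A", parent_ids=frozenset({ROOT})),
        Term(id="HP:0000002", label="Cat B", parent_ids=frozenset({ROOT})),
        Term(id="HP:0000011", label="a1", parent_ids=frozenset({"HP:0000001"})),
        Term(id="HP:0000012", label="a2", parent_ids=frozenset({"HP:0000001"})),
        Term(id="HP:0000013", label="a3", parent_ids=frozenset({"HP:0000012"})),
        Term(id="HP:0000020", label="shared leaf",
             parent_ids=frozenset({"HP:0000012", "HP:0000002"})),
        Term(id="HP:0000021", label="b1", parent_ids=frozenset({"HP:0000002"})),
        Term(id="HP:0000099", label="old term", obsolete=True),
    )


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """Root -> category -> chain of five terms (exactly one leaf)."""
    terms = [
        Term(id=ROOT, label="Phenotypic abnormality"),
        Term(id="HP:0000001", label="Cat chain", parent_ids=frozenset({ROOT})),
    ]
    prev = "HP:0000001"
    for i in range(5):
        tid = f"HP:{200 + i:07d}"
        terms.append(Term(id=tid, label=f"link {i}", parent_ids=frozenset({prev})))
        prev = tid
    return make_graph(*terms)


def brute_force_descendants(graph: OntologyGraph, term_id: str) -> set[str]:
    """Naive recursive closure over raw parent lists (oracle)."""
    children: dict[str, set[str]] = {}
    for t in graph.terms.values():
        if t.obsolete:
            continue
        for p in t.parent_ids:
            pt = graph.terms.get(p)
            if pt is not None and not pt.obsolete:
                children.setdefault(p, set()).add(t.id)
    out: set[str] = set()

    def walk(node: str) -> None:
        for child in children.get(node, ()):
            if child not in out:
                out.add(child)
                walk(child)

    walk(term_id)
    return out


def brute_force_leaves(graph: OntologyGraph, members: set[str]) -> set[str]:
    """Members with no outgoing child edge anywhere in the live graph."""
    has_child: set[str] = set()
    for t in graph.terms.values():
        if t.obsolete:
            continue
        for p in t.parent_ids:
            pt = graph.terms.get(p)
            if pt is not None and not pt.obsolete:
                has_child.add(p)
    return {m for m in members if m not in has_child}
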