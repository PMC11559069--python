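"""Category layer extraction: direct children of the root and their leaf sets.

A *category* is a direct (one-edge) subclass child of the configured root —
for the Human Phenotype Ontology, the organ/system branches directly under
"Phenotypic abnormality" (HP:0000118).  Because the ontology is a DAG, a
multi-parent term descends from every category it is reachable from and is
counted in each of them: per-category totals may double-count across rows.

"Leaf" means: no non-obsolete subclass child anywhere in the graph.  Under
subclass closure this is equivalent to leaf-within-the-category (a member's
child is always also a member), a property the test suite asserts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .ontology_model import LookupError_, OntologyGraph, descendants

DEFAULT_ROOT_ID = "HP:0000118"
DEFAULT_ROOT_LABEL = "Phenotypic abnormality"


@dataclass(frozen=True)
class Category:
    """One direct child of the root."""

    term_id: str
    label: str


@dataclass(frozen=True)
class CategoryExtract:
    """A category with its descendant closure and leaf-term set."""

    category: Category
    members: frozenset[str]
    leaves: frozenset[str]

    def __post_init__(self) -> None:
        if not self.leaves <= self.members:
            raise ValueError("leaves must be a subset of members")
        if self.category.term_id in self.members:
            raise ValueError("members must exclude the category term itself")


def _norm_label(label: str) -> str:
    return re.sub(r"\s+", " ", label).strip().casefold()


def check_root(graph: OntologyGraph, root_id: str = DEFAULT_ROOT_ID,
               expected_label: str | None = DEFAULT_ROOT_LABEL) -> None:
    """Guard against wrong-root runs: the root must exist, be live, and
    (unless *expected_label* is None) carry the expected label."""
    root = graph[root_id]
    if root.obsolete:
        raise LookupError_(f"root term {root_id} is obsolete")
    if expected_label is not None and _norm_label(root.label) != _norm_label(expected_label):
        raise LookupError_(
            f"root {root_id} is labelled {root.label!r}, expected {expected_label!r}")


def list_categories(graph: OntologyGraph, root_id: str = DEFAULT_ROOT_ID) -> list[Category]:
    """Non-obsolete direct children of the root, sorted by label (deterministic)."""
    root = graph[root_id]
    if root.obsolete:
        raise LookupError_(f"root term {root_id} is obsolete")
    cats = [
        Category(term_id=cid, label=graph[cid].label)
        for cid in graph.children(root_id)
    ]
    return sorted(cats, key=lambda c: (c.label, c.term_id))


def extract_category(graph: OntologyGraph, category_id: str) -> CategoryExtract:
    """Descendant closure and leaf set of one category.

    ``members`` excludes the category term itself; ``leaves`` are the members
    with no non-obsolete subclass child in the whole graph.
    """
    term = graph[category_id]
    members = frozenset(descendants(graph, category_id))
    leaves = frozenset(t for t in members if graph.is_leaf(t))
    return CategoryExtract(
        category=Category(term_id=category_id, label=term.label),
        members=members,
        leaves=leaves,
    )


def extract_all(graph: OntologyGraph, root_id: str = DEFAULT_ROOT_ID) -> list[CategoryExtract]:
    """One extract per category, in ``list_categories`` (label) order."""
    return [extract_category(graph, c.term_id) for c in list_categories(graph, root_id)]


def membership_map(graph: OntologyGraph, root_id: str = DEFAULT_ROOT_ID) -> dict[str, set[Category]]:
    """For every leaf under the root, the set of categories containing it.

    A multi-parent leaf maps to two or more categories; in a tree-shaped
    ontology every leaf maps to exactly one.
    """
    mapping: dict[str, set[Category]] = {}
    for extract in extract_all(graph, root_id):
        for leaf in extract.leaves:
            mapping.setdefault(leaf, set()).add(extract.category)
    return mapping


def select_categories(
    categories: list[Category], wanted: list[str]
) -> list[Category]:
    """Resolve user-supplied category labels or ids to Category objects.

    Labels match case-insensitively after whitespace normalization; ids match
    exactly.  No fuzzy matching — a silent near-match is dangerous in a
    curation workflow.
    """
    by_label = {_norm_label(c.label): c for c in categories}
    by_id = {c.term_id: c for c in categories}
    out = []
    for w in wanted:
        cat = by_id.get(w) or by_label.get(_norm_label(w))
        if cat is None:
            available = ", ".join(c.label for c in categories)
            raise LookupError_(
                f"no category matching {w!r}; available: {available}")
        out.append(cat)
    return out
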