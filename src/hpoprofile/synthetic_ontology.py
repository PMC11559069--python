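"""Seeded generator of test ontologies and curation tables with ground truth.

Emulates the structure the analysis depends on: a rooted DAG, a category
layer directly under the root, layered subtrees of endophenotype terms with
occasional extra parents, and per-leaf multi-label attribute tags drawn at
stated per-category proportions.

Two guarantees matter for its role as an oracle:

* acyclicity is structural, not checked — extra cross-link edges only point
  from deeper layers to strictly shallower ones, so no rejection step biases
  the seeded random stream;
* ground truth (category list, per-category leaf and member sets, true flag
  counts) is recorded from the generator's own bookkeeping, never by running
  the traversal code under test.

Randomness uses one named substream per concern (topology, decorations,
tags), so changing tag proportions never perturbs topology at a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import published
from .attribute_tagging import (
    ATTRIBUTES,
    TEST_DATA_SUBTYPES,
    AttributeSet,
    CurationRecord,
    CurationTable,
    write_curation,
)
from .ontology_model import OntologyGraph, Term, write_obo, write_tabular

ROOT_ID = "HP:0000118"
ROOT_LABEL = "Phenotypic abnormality"

_STREAMS = {"topology": 0, "decorations": 1, "tags": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


def default_attribute_proportions(n_categories: int) -> dict[int, dict[str, float]]:
    """Per-category attribute probabilities emulating the published survey.

    Symptoms-and-Findings proportions cycle through the 16 published curated
    ratios (0.0 ... 0.931); the other three attributes get fixed base rates
    (disease_name 0.1, condition 0.2, test_data 0.3).
    """
    sf = published.symptoms_findings_fractions()
    return {
        i: {
            "disease_name": 0.1,
            "condition": 0.2,
            "test_data": 0.3,
            "symptoms_findings": sf[i % len(sf)],
        }
        for i in range(n_categories)
    }


@dataclass(frozen=True)
class SyntheticSpec:
    """Seeded parameters; generation is a pure function of this object."""

    seed: int = 0
    n_categories: int = 23
    depth: int = 4
    branching_mean: float = 3.0
    multi_parent_prob: float = 0.1
    n_obsolete: int = 0
    attribute_proportions: Mapping[int, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_categories < 1:
            raise ValueError("need at least one category")
        if self.depth < 1:
            raise ValueError("need depth >= 1")
        if self.branching_mean <= 0:
            raise ValueError("branching_mean must be positive")
        if not 0.0 <= self.multi_parent_prob <= 1.0:
            raise ValueError("multi_parent_prob must be a probability")
        for props in (self.attribute_proportions or {}).values():
            for attr, p in props.items():
                if attr not in ATTRIBUTES:
                    raise ValueError(f"unknown attribute {attr!r}")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability out of range: {attr}={p}")

    def proportions(self) -> dict[int, dict[str, float]]:
        if self.attribute_proportions is None:
            return default_attribute_proportions(self.n_categories)
        return {i: dict(p) for i, p in self.attribute_proportions.items()}


@dataclass
class GroundTruth:
    """What the generator knows to be true about its own output."""

    root_id: str
    categories: list[tuple[str, str]]  # (term_id, label), label-sorted
    member_sets: dict[str, frozenset[str]]  # category label -> closure
    leaf_sets: dict[str, frozenset[str]]  # category label -> leaves
    n_terms: int

    @property
    def category_labels(self) -> list[str]:
        return [label for _, label in self.categories]


def _term_id(counter: int) -> str:
    # skip 118, reserved for the root
    if counter >= 118:
        counter += 1
    return f"HP:{counter:07d}"


def generate_ontology(spec: SyntheticSpec) -> tuple[OntologyGraph, GroundTruth]:
    """Build a rooted DAG plus its recorded ground truth.

    The root's direct children are exactly ``n_categories`` category terms.
    Below each category, ``depth`` layers of terms are grown with
    Poisson(``branching_mean``) children per node (a category always gets at
    least one child); then every term below the category layer acquires,
    with probability ``multi_parent_prob``, one extra parent drawn uniformly
    from the strictly shallower non-root layers of the whole forest.
    """
    topo = _rng(spec.seed, "topology")
    deco = _rng(spec.seed, "decorations")

    parents: dict[str, list[str]] = {ROOT_ID: []}
    depth_of: dict[str, int] = {ROOT_ID: 0}
    order: list[str] = []  # creation order below the root
    counter = 1

    def new_node(parent: str) -> str:
        nonlocal counter
        nid = _term_id(counter)
        counter += 1
        parents[nid] = [parent]
        depth_of[nid] = depth_of[parent] + 1
        order.append(nid)
        return nid

    category_ids = [new_node(ROOT_ID) for _ in range(spec.n_categories)]

    frontier = list(category_ids)
    for _ in range(spec.depth):
        next_frontier = []
        for node in frontier:
            k = int(topo.poisson(spec.branching_mean))
            if node in category_ids and k == 0:
                k = 1  # a category with no terms is degenerate
            next_frontier.extend(new_node(node) for _ in range(k))
        frontier = next_frontier

    # extra parents: strictly deeper -> shallower, so acyclicity is structural
    if spec.multi_parent_prob > 0:
        by_depth: dict[int, list[str]] = {}
        for nid in order:
            by_depth.setdefault(depth_of[nid], []).append(nid)
        for nid in order:
            d = depth_of[nid]
            if d < 2:
                continue  # categories keep the root as their only parent
            if topo.random() >= spec.multi_parent_prob:
                continue
            candidates = [n for sd in range(1, d) for n in by_depth.get(sd, ())]
            extra = candidates[int(topo.integers(len(candidates)))]
            if extra not in parents[nid]:
                parents[nid].append(extra)

    # decorations: labels are deterministic; some terms get definitions/synonyms
    terms = [Term(id=ROOT_ID, label=ROOT_LABEL)]
    cat_index = {cid: i for i, cid in enumerate(category_ids)}
    for nid in order:
        if nid in cat_index:
            label = f"Abnormality of system {cat_index[nid] + 1:02d}"
        else:
            label = f"Synthetic phenotype {nid.split(':')[1]}"
        definition = None
        synonyms: tuple[str, ...] = ()
        if deco.random() < 0.3:
            definition = f"A synthetic endophenotype generated as {nid}."
        if deco.random() < 0.2:
            synonyms = (f"syn {nid}",)
        terms.append(
            Term(id=nid, label=label, synonyms=synonyms, definition=definition,
                 parent_ids=frozenset(parents[nid]))
        )
    for i in range(spec.n_obsolete):
        nid = _term_id(counter)
        counter += 1
        terms.append(Term(id=nid, label=f"obsolete term {i}", obsolete=True))

    graph = OntologyGraph(terms)

    # ground truth from the generator's own adjacency, not the code under test
    children_of: dict[str, list[str]] = {nid: [] for nid in parents}
    for nid, pars in parents.items():
        for p in pars:
            children_of[p].append(nid)
    leaves = {nid for nid in order if not children_of[nid]}

    cats = sorted(
        ((cid, f"Abnormality of system {cat_index[cid] + 1:02d}") for cid in category_ids),
        key=lambda c: c[1],
    )
    member_sets: dict[str, frozenset[str]] = {}
    leaf_sets: dict[str, frozenset[str]] = {}
    # upward reachability memoised per term
    reach_cache: dict[str, frozenset[str]] = {}

    def categories_above(nid: str) -> frozenset[str]:
        if nid in reach_cache:
            return reach_cache[nid]
        found: set[str] = set()
        for p in parents[nid]:
            if p in cat_index:
                found.add(p)
            if p != ROOT_ID:
                found |= categories_above(p)
        result = frozenset(found)
        reach_cache[nid] = result
        return result

    membership: dict[str, set[str]] = {cid: set() for cid in category_ids}
    for nid in order:
        if nid in cat_index:
            continue
        for cid in categories_above(nid):
            membership[cid].add(nid)
    for cid, label in cats:
        members = frozenset(membership[cid])
        member_sets[label] = members
        leaf_sets[label] = frozenset(members & leaves)

    truth = GroundTruth(
        root_id=ROOT_ID,
        categories=cats,
        member_sets=member_sets,
        leaf_sets=leaf_sets,
        n_terms=len(terms),
    )
    return graph, truth


def generate_curation(
    leaf_sets: Mapping[str, frozenset[str]],
    proportions: Mapping[int, Mapping[str, float]],
    seed: int,
    labels: Mapping[str, str] | None = None,
) -> tuple[CurationTable, dict[str, dict[str, int]]]:
    """Draw per-leaf attribute flags and record the true per-category counts.

    ``leaf_sets`` maps category label -> leaf ids; ``proportions`` maps the
    category's index (position in label order) -> attribute -> probability.
    Each leaf's flags are drawn independently per attribute.  A leaf present
    in several categories is drawn once, under the first (label-ordered)
    category containing it; the recorded true counts attribute those same
    flags to every containing category.
    """
    tags = _rng(seed, "tags")
    cat_labels = sorted(leaf_sets)
    flag_of: dict[str, AttributeSet] = {}
    for idx, cat in enumerate(cat_labels):
        props = proportions.get(idx, {})
        for leaf in sorted(leaf_sets[cat]):
            if leaf in flag_of:
                continue
            flags = {a: bool(tags.random() < props.get(a, 0.0)) for a in ATTRIBUTES}
            subtypes: frozenset[str] = frozenset()
            if flags["test_data"] and tags.random() < 0.5:
                pool = sorted(TEST_DATA_SUBTYPES)
                n_sub = 1 + int(tags.integers(2))
                picked = tags.choice(len(pool), size=n_sub, replace=False)
                subtypes = frozenset(pool[i] for i in picked)
            flag_of[leaf] = AttributeSet(**flags, test_data_subtypes=subtypes)

    true_counts = {
        cat: {a: sum(1 for leaf in leaf_sets[cat] if flag_of[leaf].has(a))
              for a in ATTRIBUTES}
        for cat in cat_labels
    }
    records = [
        CurationRecord(
            term_id=leaf,
            label=(labels or {}).get(leaf, ""),
            attributes=flag_of[leaf],
            source="synthetic",
        )
        for leaf in sorted(flag_of)
    ]
    return CurationTable(records), true_counts


def write_fixture_set(spec: SyntheticSpec, outdir, curation_format: str = "csv") -> dict:
    """Emit OBO, the two-table dialect, per-category curation and ground truth.

    Returns a manifest of what was written (paths and ground-truth counts).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph, truth = generate_ontology(spec)
    write_obo(graph, outdir / "ontology.obo")
    defs, rel = write_tabular(graph)
    defs.to_csv(outdir / "definitions.csv", index=False)
    rel.to_csv(outdir / "parent_child.csv", index=False)

    label_map = {tid: t.label for tid, t in graph.terms.items()}
    table, true_counts = generate_curation(
        truth.leaf_sets, spec.proportions(), spec.seed, labels=label_map)
    curation_path = outdir / f"curation.{curation_format}"
    write_curation(table, curation_path)

    manifest = {
        "spec": {
            "seed": spec.seed,
            "n_categories": spec.n_categories,
            "depth": spec.depth,
            "branching_mean": spec.branching_mean,
            "multi_parent_prob": spec.multi_parent_prob,
            "n_obsolete": spec.n_obsolete,
        },
        "root_id": truth.root_id,
        "n_terms": truth.n_terms,
        "categories": [
            {
                "term_id": cid,
                "label": label,
                "n_members": len(truth.member_sets[label]),
                "n_leaves": len(truth.leaf_sets[label]),
                "true_counts": true_counts[label],
            }
            for cid, label in truth.categories
        ],
        "files": {
            "obo": "ontology.obo",
            "definitions": "definitions.csv",
            "parent_child": "parent_child.csv",
            "curation": curation_path.name,
        },
    }
    return manifest
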