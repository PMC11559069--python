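"""Parse, represent and validate a subclass ontology as a rooted DAG.

The ontology is modelled the way the Human Phenotype Ontology is distributed:
terms identified by CURIEs (``HP:0000118``), connected child -> parent along
``is_a`` (subclass) edges only.  Other relationship types found in an OBO
input are parsed and ignored (their count is logged), because category
membership in this analysis is purely subclass-based.

Two input dialects are supported:

* OBO 1.2/1.4 flat files (the ontology's standard distribution format);
* a two-table spreadsheet export: a *definitions* table with columns
  ``HPO id / Label / Definition / Synonyms`` and a *parent-child* table with
  columns ``HPO id / Label / Parent / Child``, multi-valued cells joined by a
  configurable delimiter (default ``|``).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

_CURIE_RE = re.compile(r"^(?P<prefix>[A-Za-z][A-Za-z0-9_]*):(?P<local>\d+)$")


class OntologyError(Exception):
    """Base class for ontology loading/validation failures."""


class ParseError(OntologyError):
    """Malformed input; message names the offending line or row."""


class FormatError(OntologyError):
    """Structurally wrong table (e.g. a required column is missing)."""


class ValidationError(OntologyError):
    """Graph-level invariant violation (cycles, dangling parents, ...)."""


class LookupError_(OntologyError, KeyError):
    """Unknown term id."""


def check_term_id(value: str, prefix: str = "HP") -> str:
    """Validate a CURIE of the form ``<prefix>:<digits>`` and return it.

    Equality of term ids is exact string equality throughout the package.
    """
    m = _CURIE_RE.match(value)
    if m is None or (prefix is not None and m.group("prefix") != prefix):
        raise ValueError(f"not a valid {prefix!s} CURIE: {value!r}")
    return value


@dataclass(frozen=True)
class Term:
    """One ontology term with the metadata retained by this analysis."""

    id: str
    label: str
    synonyms: tuple[str, ...] = ()
    definition: str | None = None
    obsolete: bool = False
    parent_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.obsolete and not self.label:
            raise ValueError(f"non-obsolete term {self.id} has an empty label")
        if self.id in self.parent_ids:
            raise ValueError(f"term {self.id} lists itself as a parent")


@dataclass
class Issue:
    """A validation finding; issues are data, not exceptions."""

    kind: str  # one of: cycle, dangling_parent, duplicate_id, self_loop
    term_ids: tuple[str, ...]
    message: str


class OntologyGraph:
    """The validated DAG of terms; edges run child -> parent (subclass only).

    Obsolete terms are retained for diagnostics but excluded from traversal:
    ``descendants``, leaf predicates and all counts see only the live graph.
    """

    def __init__(self, terms: Iterable[Term]):
        self.terms: dict[str, Term] = {}
        for t in terms:
            if t.id in self.terms:
                raise ValidationError(f"duplicate term id {t.id}")
            self.terms[t.id] = t
        self._digraph: nx.DiGraph | None = None

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise LookupError_(f"unknown term id {term_id}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return self.terms == other.terms

    @property
    def live_graph(self) -> nx.DiGraph:
        """child -> parent digraph over non-obsolete terms (lazily built)."""
        if self._digraph is None:
            g = nx.DiGraph()
            for t in self.terms.values():
                if t.obsolete:
                    continue
                g.add_node(t.id)
                for p in t.parent_ids:
                    pt = self.terms.get(p)
                    if pt is not None and not pt.obsolete:
                        g.add_edge(t.id, p)
            self._digraph = g
        return self._digraph

    def children(self, term_id: str) -> set[str]:
        """Non-obsolete direct subclasses of *term_id*."""
        self[term_id]
        g = self.live_graph
        if term_id not in g:
            return set()
        return set(g.predecessors(term_id))

    def is_leaf(self, term_id: str) -> bool:
        """True iff the term is live and has no non-obsolete subclass child."""
        t = self[term_id]
        return not t.obsolete and not self.children(term_id)


def descendants(graph: OntologyGraph, term_id: str) -> set[str]:
    """All non-obsolete terms reachable downward from *term_id*.

    Excludes *term_id* itself; each term appears once regardless of how many
    subclass paths lead to it (DAG de-duplication).
    """
    graph[term_id]  # raise on unknown id
    g = graph.live_graph
    if term_id not in g:
        return set()
    # edges run child -> parent, so "descendants" = nodes that can reach term_id
    return set(nx.ancestors(g, term_id))


def validate(graph: OntologyGraph) -> list[Issue]:
    """Check graph invariants; returns an empty list iff they all hold."""
    issues: list[Issue] = []
    for t in graph.terms.values():
        for p in sorted(t.parent_ids):
            if p == t.id:  # unreachable via Term, but guard raw construction
                issues.append(Issue("self_loop", (t.id,), f"{t.id} is its own parent"))
            elif p not in graph.terms:
                issues.append(
                    Issue("dangling_parent", (t.id, p),
                          f"{t.id} references missing parent {p}")
                )
    full = nx.DiGraph()
    full.add_nodes_from(graph.terms)
    for t in graph.terms.values():
        for p in t.parent_ids:
            if p in graph.terms:
                full.add_edge(t.id, p)
    if not nx.is_directed_acyclic_graph(full):
        for cyc in nx.simple_cycles(full):
            issues.append(
                Issue("cycle", tuple(sorted(cyc)),
                      "subclass cycle through " + " -> ".join(sorted(cyc)))
            )
    return issues


# ---------------------------------------------------------------------------
# OBO flat-file reader/writer
# ---------------------------------------------------------------------------

_QUOTED_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _strip_obo_comment(value: str) -> str:
    # a " ! " introduces a trailing comment (e.g. `is_a: HP:0000001 ! All`)
    return value.split(" ! ")[0].split("\t!")[0].strip()


def parse_obo(source, prefix: str = "HP", strict: bool = True) -> OntologyGraph:
    """Read an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Only ``[Term]`` stanzas are considered.  ``is_a`` targets become
    ``parent_ids``; ``relationship`` lines (part_of etc.) are counted and
    ignored; obsolete terms are retained but flagged.

    Parameters
    ----------
    source:
        A path, an open text stream, or a string containing OBO text.
    prefix:
        Expected CURIE prefix for term ids (id syntax is validated).
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()

    terms: list[Term] = []
    seen: set[str] = set()
    n_ignored_rel = 0

    stanza: dict | None = None
    stanza_line = 0

    def finish(at_line: int) -> None:
        nonlocal stanza
        if stanza is None:
            return
        if "id" not in stanza:
            raise ParseError(f"[Term] stanza at line {stanza_line} has no id")
        tid = stanza["id"]
        if tid in seen:
            raise ValidationError(
                f"duplicate term id {tid} (stanza at line {stanza_line})")
        seen.add(tid)
        if not stanza.get("obsolete") and not stanza.get("name"):
            raise ParseError(
                f"[Term] stanza for {tid} at line {stanza_line} has no name")
        terms.append(
            Term(
                id=tid,
                label=stanza.get("name", ""),
                synonyms=tuple(stanza.get("synonyms", ())),
                definition=stanza.get("definition"),
                obsolete=bool(stanza.get("obsolete", False)),
                parent_ids=frozenset(stanza.get("parents", ())),
            )
        )
        stanza = None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line.startswith("["):
            finish(lineno)
            if line == "[Term]":
                stanza = {"parents": [], "synonyms": []}
                stanza_line = lineno
            continue
        if stanza is None or not line or line.startswith("!"):
            continue
        if ":" not in line:
            raise ParseError(f"malformed tag line {lineno}: {raw!r}")
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            try:
                stanza["id"] = check_term_id(_strip_obo_comment(value), prefix)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
        elif tag == "name":
            stanza["name"] = _strip_obo_comment(value)
        elif tag == "is_a":
            target = _strip_obo_comment(value)
            try:
                target = check_term_id(target, prefix)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            if target not in stanza["parents"]:
                stanza["parents"].append(target)
        elif tag == "is_obsolete":
            stanza["obsolete"] = _strip_obo_comment(value).lower() == "true"
        elif tag == "def":
            m = _QUOTED_RE.search(value)
            if m is None:
                raise ParseError(f"line {lineno}: def value is not quoted")
            stanza["definition"] = m.group(1).replace('\\"', '"')
        elif tag == "synonym":
            m = _QUOTED_RE.search(value)
            if m is None:
                raise ParseError(f"line {lineno}: synonym value is not quoted")
            stanza["synonyms"].append(m.group(1).replace('\\"', '"'))
        elif tag == "relationship":
            n_ignored_rel += 1
        # all other tags (xref, comment, alt_id, ...) are irrelevant here

    finish(len(lines) + 1)
    if n_ignored_rel:
        logger.info("parse_obo: ignored %d non-is_a relationship lines", n_ignored_rel)
    graph = OntologyGraph(terms)
    if strict:
        _require_valid(graph)
    return graph


def write_obo(graph: OntologyGraph, target=None) -> str:
    """Serialize the retained fields back to OBO text (stable output order)."""
    out = io.StringIO()
    out.write("format-version: 1.2\n")
    for tid in sorted(graph.terms):
        t = graph.terms[tid]
        out.write("\n[Term]\n")
        out.write(f"id: {t.id}\n")
        out.write(f"name: {t.label}\n")
        if t.definition is not None:
            quoted = t.definition.replace('"', '\\"')
            out.write(f'def: "{quoted}" []\n')
        for syn in t.synonyms:
            quoted = syn.replace('"', '\\"')
            out.write(f'synonym: "{quoted}" EXACT []\n')
        for p in sorted(t.parent_ids):
            out.write(f"is_a: {p}\n")
        if t.obsolete:
            out.write("is_obsolete: true\n")
    text = out.getvalue()
    if target is not None:
        if isinstance(target, (str, Path)):
            Path(target).write_text(text, encoding="utf-8")
        else:
            target.write(text)
    return text


# ---------------------------------------------------------------------------
# Two-table spreadsheet dialect
# ---------------------------------------------------------------------------

DEFINITION_COLUMNS = ("HPO id", "Label", "Definition", "Synonyms")
PARENT_CHILD_COLUMNS = ("HPO id", "Label", "Parent", "Child")


def _read_table(source, columns: Sequence[str]) -> pd.DataFrame:
    """Load a CSV/TSV/XLSX table and check the required header."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        path = Path(source)
        suffix = path.suffix.lower()
        if suffix in {".xlsx", ".xlsm"}:
            df = pd.read_excel(path, sheet_name=0, dtype=str)
        elif suffix == ".tsv":
            df = pd.read_csv(path, sep="\t", dtype=str)
        else:
            df = pd.read_csv(path, dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    return df.fillna("")


def _split_multi(cell: str, delimiter: str) -> list[str]:
    return [part.strip() for part in str(cell).split(delimiter) if part.strip()]


def parse_tabular(
    definitions,
    parent_child,
    delimiter: str = "|",
    prefix: str = "HP",
    strict: bool = True,
) -> OntologyGraph:
    """Build a graph from the two-table export dialect.

    ``definitions`` carries labels, definitions and synonyms; ``parent_child``
    carries the hierarchy, one row per term, with delimiter-joined ``Parent``
    and ``Child`` cells.  The two direction columns are cross-checked: if X
    lists Y as Child then Y must list X as Parent (and vice versa).
    """
    defs = _read_table(definitions, DEFINITION_COLUMNS)
    rel = _read_table(parent_child, PARENT_CHILD_COLUMNS)

    parents: dict[str, list[str]] = {}
    children: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    for i, row in rel.iterrows():
        try:
            tid = check_term_id(str(row["HPO id"]).strip(), prefix)
        except ValueError as exc:
            raise ParseError(f"parent_child row {i + 2}: {exc}") from None
        labels[tid] = str(row["Label"]).strip()
        parents.setdefault(tid, []).extend(_split_multi(row["Parent"], delimiter))
        children.setdefault(tid, []).extend(_split_multi(row["Child"], delimiter))

    # mutual consistency of the redundant direction columns
    bad_pairs = []
    for tid, kids in children.items():
        for kid in kids:
            if tid not in parents.get(kid, []):
                bad_pairs.append((tid, kid))
    for tid, pars in parents.items():
        for par in pars:
            if par in children and tid not in children[par]:
                bad_pairs.append((par, tid))
    if bad_pairs:
        listing = "; ".join(f"{a} <-> {b}" for a, b in sorted(set(bad_pairs)))
        raise ValidationError(
            f"parent/child columns are not mutually consistent: {listing}")

    meta: dict[str, dict] = {}
    for i, row in defs.iterrows():
        try:
            tid = check_term_id(str(row["HPO id"]).strip(), prefix)
        except ValueError as exc:
            raise ParseError(f"definitions row {i + 2}: {exc}") from None
        if tid in meta:
            raise ValidationError(f"duplicate term id {tid} in definitions table")
        meta[tid] = {
            "label": str(row["Label"]).strip(),
            "definition": str(row["Definition"]).strip() or None,
            "synonyms": tuple(_split_multi(row["Synonyms"], delimiter)),
        }

    all_ids = sorted(set(parents) | set(meta))
    terms = []
    for tid in all_ids:
        m = meta.get(tid, {})
        terms.append(
            Term(
                id=tid,
                label=m.get("label") or labels.get(tid, ""),
                synonyms=m.get("synonyms", ()),
                definition=m.get("definition"),
                parent_ids=frozenset(parents.get(tid, ())),
            )
        )
    graph = OntologyGraph(terms)
    if strict:
        _require_valid(graph)
    return graph


def write_tabular(graph: OntologyGraph, delimiter: str = "|"):
    """Export the graph to the two-table dialect as two DataFrames.

    The dialect carries no obsolete flag, so only live (non-obsolete) terms
    are exported: reading the tables back reproduces the live subgraph.
    """
    live = {tid: t for tid, t in graph.terms.items() if not t.obsolete}
    child_of: dict[str, list[str]] = {tid: [] for tid in live}
    for t in live.values():
        for p in t.parent_ids:
            if p in child_of:
                child_of[p].append(t.id)
    def_rows, rel_rows = [], []
    for tid in sorted(live):
        t = live[tid]
        def_rows.append(
            {
                "HPO id": t.id,
                "Label": t.label,
                "Definition": t.definition or "",
                "Synonyms": delimiter.join(t.synonyms),
            }
        )
        rel_rows.append(
            {
                "HPO id": t.id,
                "Label": t.label,
                "Parent": delimiter.join(sorted(t.parent_ids)),
                "Child": delimiter.join(sorted(child_of[tid])),
            }
        )
    return (
        pd.DataFrame(def_rows, columns=list(DEFINITION_COLUMNS)),
        pd.DataFrame(rel_rows, columns=list(PARENT_CHILD_COLUMNS)),
    )


def _require_valid(graph: OntologyGraph, prune: bool = False) -> None:
    """Escalate validation issues to errors (loaders fail loudly by default)."""
    issues = validate(graph)
    if prune:
        issues = [i for i in issues if i.kind != "dangling_parent"]
    if issues:
        raise ValidationError(
            "; ".join(f"{i.kind}: {i.message}" for i in issues[:20]))


def prune_dangling(graph: OntologyGraph) -> OntologyGraph:
    """Return a copy with edges to missing parents dropped (opt-in repair)."""
    terms = []
    for t in graph.terms.values():
        keep = frozenset(p for p in t.parent_ids if p in graph.terms)
        terms.append(
            Term(t.id, t.label, t.synonyms, t.definition, t.obsolete, keep))
    return OntologyGraph(terms)
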