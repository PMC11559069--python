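"""Ontology parsing, validation and traversal."""

from __future__ import annotations

import pandas as pd
import pytest

from hpoprofile.ontology_model import (
    FormatError,
    LookupError_,
    OntologyGraph,
    ParseError,
    Term,
    ValidationError,
    check_term_id,
    descendants,
    parse_obo,
    parse_tabular,
    prune_dangling,
    validate,
    write_obo,
    write_tabular,
)
from hpoprofile.synthetic_ontology import SyntheticSpec, generate_ontology

from .conftest import ROOT, brute_force_descendants, make_graph

MINIMAL_OBO = """\
format-version: 1.2

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000002
name: Child term
is_a: HP:0000001 ! All
"""


class TestCheckTermId:
    def test_accepts_curie(self):
        assert check_term_id("HP:0000118") == "HP:0000118"

    @pytest.mark.parametrize("bad", ["HP0000118", "MP:0000118", "HP:12a", ""])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            check_term_id(bad)


class TestParseObo:
    def test_two_stanza_minimal_document(self):
        graph = parse_obo(MINIMAL_OBO)
        assert len(graph) == 2
        assert graph["HP:0000002"].parent_ids == {"HP:0000001"}
        assert graph["HP:0000002"].label == "Child term"

    def test_obsolete_flag_propagates_and_is_excluded_from_traversal(self):
        obo = MINIMAL_OBO + "\n[Term]\nid: HP:0000003\nname: dead\n" \
            "is_a: HP:0000001\nis_obsolete: true\n"
        graph = parse_obo(obo)
        assert graph["HP:0000003"].obsolete
        assert descendants(graph, "HP:0000001") == {"HP:0000002"}

    def test_malformed_stanza_names_the_line(self):
        bad = "[Term]\nid: HP:0000001\nname: ok\nthis line has no tag\n"
        with pytest.raises(ParseError, match="line 4"):
            parse_obo(bad)

    def test_duplicate_id_is_a_validation_error(self):
        dup = MINIMAL_OBO + "\n[Term]\nid: HP:0000001\nname: again\n"
        with pytest.raises(ValidationError, match="duplicate"):
            parse_obo(dup)

    def test_def_and_synonym_values_are_unquoted(self):
        obo = (
            "[Term]\nid: HP:0000001\nname: All\n"
            'def: "The root." [src]\nsynonym: "everything" EXACT []\n'
        )
        t = parse_obo(obo)["HP:0000001"]
        assert t.definition == "The root."
        assert t.synonyms == ("everything",)

    def test_relationship_lines_are_ignored(self):
        obo = MINIMAL_OBO + "relationship: part_of HP:0000001\n"
        graph = parse_obo(obo)
        assert graph["HP:0000002"].parent_ids == {"HP:0000001"}

    def test_round_trip_on_seeded_synthetic_graph(self):
        graph, _ = generate_ontology(
            SyntheticSpec(seed=3, n_categories=4, depth=2,
                          branching_mean=2.0, multi_parent_prob=0.2,
                          n_obsolete=2))
        assert parse_obo(write_obo(graph)) == graph

    def test_obonet_agrees_on_structure(self, tmp_path):
        """Independent OBO reader sees the same terms and is_a edges."""
        obonet = pytest.importorskip("obonet")
        graph, _ = generate_ontology(
            SyntheticSpec(seed=5, n_categories=3, depth=2,
                          branching_mean=2.0, multi_parent_prob=0.1))
        path = tmp_path / "g.obo"
        write_obo(graph, path)
        ref = obonet.read_obo(path)
        assert set(ref.nodes) == set(graph.terms)
        ours = {(t.id, p) for t in graph.terms.values() for p in t.parent_ids}
        theirs = {(c, p) for c, p, k in ref.edges(keys=True) if k == "is_a"}
        assert ours == theirs


class TestParseTabular:
    @staticmethod
    def _tables(rows):
        defs = pd.DataFrame(
            [{"HPO id": tid, "Label": lab, "Definition": "", "Synonyms": ""}
             for tid, lab, _, _ in rows])
        rel = pd.DataFrame(
            [{"HPO id": tid, "Label": lab, "Parent": par, "Child": chi}
             for tid, lab, par, chi in rows])
        return defs, rel

    def test_three_row_chain(self):
        defs, rel = self._tables([
            ("HP:0000001", "root", "", "HP:0000002"),
            ("HP:0000002", "A", "HP:0000001", "HP:0000003"),
            ("HP:0000003", "a1", "HP:0000002", ""),
        ])
        graph = parse_tabular(defs, rel)
        assert len(graph) == 3
        assert sum(len(t.parent_ids) for t in graph.terms.values()) == 2

    def test_delimited_child_cell_yields_two_edges(self):
        defs, rel = self._tables([
            ("HP:0000001", "root", "", "HP:0000002|HP:0000003"),
            ("HP:0000002", "A", "HP:0000001", ""),
            ("HP:0000003", "B", "HP:0000001", ""),
        ])
        graph = parse_tabular(defs, rel)
        assert graph["HP:0000002"].parent_ids == {"HP:0000001"}
        assert graph["HP:0000003"].parent_ids == {"HP:0000001"}

    def test_missing_column_is_a_format_error(self):
        defs, rel = self._tables([("HP:0000001", "root", "", "")])
        with pytest.raises(FormatError, match="Definition"):
            parse_tabular(defs.drop(columns=["Definition"]), rel)

    def test_inconsistent_cross_reference_lists_the_pair(self):
        defs, rel = self._tables([
            ("HP:0000001", "root", "", "HP:0000002"),
            ("HP:0000002", "A", "", ""),  # does not list root as Parent
        ])
        with pytest.raises(ValidationError, match="HP:0000001 <-> HP:0000002"):
            parse_tabular(defs, rel)

    def test_round_trip_on_seeded_synthetic_graph(self):
        graph, _ = generate_ontology(
            SyntheticSpec(seed=11, n_categories=4, depth=3,
                          branching_mean=2.0, multi_parent_prob=0.3))
        defs, rel = write_tabular(graph)
        assert parse_tabular(defs, rel) == graph


class TestValidate:
    def test_two_cycle_reported_with_both_ids(self):
        graph = make_graph(
            Term(id="HP:0000001", label="A", parent_ids=frozenset({"HP:0000002"})),
            Term(id="HP:0000002", label="B", parent_ids=frozenset({"HP:0000001"})),
        )
        kinds = [i.kind for i in validate(graph)]
        assert kinds == ["cycle"]
        assert validate(graph)[0].term_ids == ("HP:0000001", "HP:0000002")

    def test_dangling_parent_reported(self):
        graph = make_graph(
            Term(id="HP:0000001", label="A", parent_ids=frozenset({"HP:0009999"})))
        issues = validate(graph)
        assert [i.kind for i in issues] == ["dangling_parent"]
        assert prune_dangling(graph)["HP:0000001"].parent_ids == frozenset()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generated_graphs_are_clean(self, seed):
        graph, _ = generate_ontology(
            SyntheticSpec(seed=seed, n_categories=5, depth=3,
                          branching_mean=2.5, multi_parent_prob=0.3))
        assert validate(graph) == []

    def test_no_cycle_issue_iff_topological_order_exists(self):
        import networkx as nx
        graph, _ = generate_ontology(SyntheticSpec(seed=9, n_categories=3,
                                                   depth=2, branching_mean=2.0))
        assert not any(i.kind == "cycle" for i in validate(graph))
        assert nx.is_directed_acyclic_graph(graph.live_graph)


class TestDescendants:
    def test_leaf_has_empty_descendant_set(self, diamond_graph):
        assert descendants(diamond_graph, "HP:0000011") == set()

    def test_diamond_counts_shared_grandchild_once(self, diamond_graph):
        assert descendants(diamond_graph, ROOT) == {
            "HP:0000001", "HP:0000002", "HP:0000011", "HP:0000012",
            "HP:0000013", "HP:0000020", "HP:0000021",
        }

    def test_unknown_id_raises_lookup_error(self, diamond_graph):
        with pytest.raises(LookupError_):
            descendants(diamond_graph, "HP:4999999")

    def test_matches_brute_force_on_seeded_dag(self):
        graph, _ = generate_ontology(
            SyntheticSpec(seed=21, n_categories=4, depth=3,
                          branching_mean=2.5, multi_parent_prob=0.25))
        assert len(graph) >= 50
        for tid in graph.terms:
            assert descendants(graph, tid) == brute_force_descendants(graph, tid)

    def test_monotone_along_every_edge(self):
        """For every child -> parent edge, desc(child) is strictly inside
        desc(parent)."""
        graph, _ = generate_ontology(
            SyntheticSpec(seed=8, n_categories=3, depth=3,
                          branching_mean=2.0, multi_parent_prob=0.2))
        for t in graph.terms.values():
            for p in t.parent_ids:
                assert descendants(graph, t.id) < descendants(graph, p)


class TestTermInvariants:
    def test_non_obsolete_term_needs_a_label(self):
        with pytest.raises(ValueError):
            Term(id="HP:0000001", label="")

    def test_self_parent_rejected(self):
        with pytest.raises(ValueError):
            Term(id="HP:0000001", label="x",
                 parent_ids=frozenset({"HP:0000001"}))

    def test_duplicate_ids_rejected_at_graph_construction(self):
        with pytest.raises(ValidationError):
            OntologyGraph([Term(id="HP:0000001", label="a"),
                           Term(id="HP:0000001", label="b")])
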