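# Methods

## The model of the ontology

The package treats an ontology as a set of terms identified by CURIEs
(`HP:0000118`) connected child → parent along subclass (`is_a`) edges only.
Other relationship types present in an OBO input (e.g. `part_of`) are parsed
and ignored with a logged count: category membership here is subclass
membership, and mixing relation types would silently change every count.
The graph must be a DAG — a term may have several parents but never an
ancestor path back to itself — and loaders validate this (plus dangling
parents and duplicate ids) before anything downstream runs. Dangling parent
references are an error by default, because they usually indicate a
truncated export; `prune_dangling` is the explicit opt-in repair.

Obsolete terms are retained in the graph for diagnostics but excluded from
traversal, leaf predicates and all counts: a curated list should never
contain deprecated ids. The two-table spreadsheet dialect cannot represent
the obsolete flag, so its writer exports only live terms and its round-trip
identity holds on the live subgraph; the OBO round trip is identity on all
retained fields (id, label, parents, definition, synonyms, obsolete).

## Categories, leaves, multi-parent counting

A *category* is a non-obsolete direct child of the configured root (default
`HP:0000118`, with a label guard against wrong-root runs; both are
configurable). A *leaf* is a term with no non-obsolete subclass child
anywhere in the graph. Under subclass closure these are exactly the leaves
within each category's closure — a member's child is always itself a member
— which the test suite asserts rather than assumes.

A multi-parent term is counted in **every** category it descends from, so
summed per-category counts may exceed the number of distinct leaves; the
`overlap_matrix` quantifies this double-counting pairwise. Category
selection by name is case-insensitive exact matching after whitespace
normalization — never fuzzy, since a silently matched wrong category would
corrupt a curation round.

## Curation schema and statistics

Curation sheets carry `+` for an attribute's presence; the Unicode minus
`−`, the ASCII hyphen and an empty cell all mean absence (real spreadsheets
mix them). Attribute headers are matched case-insensitively against
singular/plural aliases. Any combination of the four attributes is
permitted, including none — whether curators must assign at least one
attribute is a policy question the package does not impose. Test Data
subtypes live in an optional delimiter-joined column and require the Test
Data flag itself.

Merging a curation table into a category extract never invents annotations:
leaves without a record are reported as *uncurated* but remain in the
denominator of every percentage (they count as all-false), and curated ids
outside the leaf set are reported as *stale* and excluded. Keeping
uncurated terms in the denominator is what makes a ratio like 895 flagged of
961 leaves equal 93.1%.

Percentages and the mean of the count summary are rounded **half-up** (away
from zero) to one decimal, computed through exact rational/decimal
arithmetic rather than binary floats, so 6.25% prints as 6.3 and output is
bit-stable across platforms. The percentage of an empty category is null,
rendered `NA` — 0.0 is a real observed value and must not be conflated with
no-data. Report rows follow label-sorted category order by default.

## The synthetic generator

`SyntheticSpec` is the single source of randomness: generation is a pure
function of it. Defaults emulate the published survey's conditions — 23
categories under the root, four layers of terms, Poisson branching with
mean 3 (giving ontologies of a few thousand terms), a 10% extra-parent
rate, and Symptoms-and-Findings proportions cycling through the 16
published per-category ratios (0.0 … 0.931). The other three attributes
default to fixed base rates (Disease Name 0.1, Condition 0.2, Test Data
0.3), chosen once as plausible mid-range values; none of the analyses are
sensitive to them.

Three design points matter for its role as a test oracle:

* **Structural acyclicity.** Extra parents only point from deeper layers to
  strictly shallower ones, so no generated graph can contain a cycle and no
  rejection step distorts the seeded stream.
* **Independent ground truth.** Category lists, member/leaf sets and true
  flag counts are recorded from the generator's own adjacency bookkeeping,
  never by calling the traversal code under test.
* **Named substreams.** Topology, decorations (definitions/synonyms) and
  attribute tags each draw from their own seeded substream, so changing tag
  proportions never perturbs topology at a fixed seed.

A leaf reachable from several categories is curated once — under the first
category (label order) containing it — and its flags are attributed to every
containing category's true counts, mirroring a real workflow where one term
has one curation record.

What the generator does *not* emulate: realistic phenotype label text,
semantically plausible hierarchies, HPO's actual size distribution across
categories (real counts span 4 to 2743; generated categories are more
uniform), or curator disagreement. Passing tests therefore demonstrate that
the graph algorithms, the merge semantics and the arithmetic are exact, and
that stated tag proportions are recovered at binomial accuracy — not that
any specific HPO release reproduces the published absolute counts, which
depend on the release and on the leaf-extraction tool used by the survey.

## Problem sizes and verification

The test suite checks leaf extraction against both the recorded ground
truth and a test-side brute-force DFS written directly over the raw parent
lists (no shared code with the implementation), across 51 seeded DAGs —
17 at each extra-parent rate in {0, 0.1, 0.3}, in shapes from ~100 to a few
thousand terms. Proportion recovery is asserted at a three-sigma binomial
tolerance over 200 seeds at category sizes 24 and 961 (the smallest and a
large published category). Whole-pipeline determinism is asserted by
byte-comparing every artifact of two `simulate → extract → profile` runs at
a fixed seed. `scripts/acceptance.py` re-runs these measurements from
scratch with a user-supplied seed and writes the resulting numbers as JSON.

## Known limitations

* Only `is_a` semantics; if a use case needs `part_of` closure the model
  must be extended, not reconfigured.
* The two-table dialect drops obsolete terms and per-term provenance.
* `overlap_matrix` is dense; at very large category counts a sparse
  representation would be preferable.
* The curation reader trusts the first two columns to be id and label, as
  in the published sheet layout; arbitrary column orders need explicit
  headers.
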