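"""The four-attribute curation schema and curation-table I/O.

Clinician curation assigns each leaf term any combination of four attributes:

* **Disease Name** — the term is the name of a disease entity;
* **Condition** — a state or circumstance rather than a finding;
* **Test Data** — revealed by a test; optionally sub-typed as findings made
  with tools/equipment, biochemical, physiological, imaging or pathological
  tests;
* **Symptoms and Findings** — revealed by physical examination.

Curation tables are spreadsheets (CSV/TSV/XLSX) with term id and label on
the left, followed by one column per attribute holding ``+`` (present) or
``−`` (absent).  Real spreadsheets are inconsistent, so the Unicode minus,
the ASCII hyphen and an empty cell all mean absent, and attribute headers
match case-insensitively against singular/plural aliases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .category_extraction import CategoryExtract
from .ontology_model import check_term_id

ATTRIBUTES = ("disease_name", "condition", "test_data", "symptoms_findings")

#: canonical column headers, in the curation sheet's column order
ATTRIBUTE_HEADERS = {
    "disease_name": "Disease Names",
    "condition": "Conditions",
    "test_data": "Test Data",
    "symptoms_findings": "Symptoms and Findings",
}

#: accepted aliases (lower-cased) per attribute
ATTRIBUTE_ALIASES = {
    "disease_name": {"disease names", "disease name"},
    "condition": {"conditions", "condition"},
    "test_data": {"test data"},
    "symptoms_findings": {"symptoms and findings", "symptoms/findings",
                          "symptoms & findings"},
}

TEST_DATA_SUBTYPES = frozenset(
    {"findings_with_tools", "biochemical", "physiological", "imaging",
     "pathological"}
)

SUBTYPE_HEADER = "Test Data Subtypes"

_PRESENT = {"+"}
_ABSENT = {"−", "-", ""}  # Unicode minus, ASCII hyphen, empty cell


class CurationError(Exception):
    """Unusable curation table (bad marker, duplicate id, missing column)."""


@dataclass(frozen=True)
class AttributeSet:
    """One term's multi-label assignment over the four attributes."""

    disease_name: bool = False
    condition: bool = False
    test_data: bool = False
    symptoms_findings: bool = False
    test_data_subtypes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = self.test_data_subtypes - TEST_DATA_SUBTYPES
        if bad:
            raise ValueError(f"unknown test-data subtype(s): {sorted(bad)}")
        if self.test_data_subtypes and not self.test_data:
            raise ValueError("test_data_subtypes given but test_data is false")

    def has(self, attribute: str) -> bool:
        if attribute not in ATTRIBUTES:
            raise ValueError(f"unknown attribute {attribute!r}")
        return bool(getattr(self, attribute))


NO_ATTRIBUTES = AttributeSet()


@dataclass(frozen=True)
class CurationRecord:
    term_id: str
    label: str
    attributes: AttributeSet
    source: str = ""
    note: str | None = None

    def __post_init__(self) -> None:
        check_term_id(self.term_id, prefix=self.term_id.split(":", 1)[0])


@dataclass
class CurationTable:
    """A loaded curation sheet; term ids are unique across records."""

    records: list[CurationRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.term_id in seen:
                raise CurationError(f"duplicate term id {r.term_id}")
            seen.add(r.term_id)

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, CurationRecord]:
        return {r.term_id: r for r in self.records}


@dataclass
class AnnotatedExtract:
    """A category extract joined with its curation.

    ``annotations`` covers the curated leaves, ``uncurated`` the leaves with
    no record (they count as all-false downstream but are reported), and
    ``stale`` the curated ids absent from the extract (excluded from
    statistics).
    """

    extract: CategoryExtract
    annotations: dict[str, AttributeSet]
    uncurated: frozenset[str]
    stale: frozenset[str]

    def __post_init__(self) -> None:
        keys = frozenset(self.annotations)
        if keys | self.uncurated != self.extract.leaves or keys & self.uncurated:
            raise ValueError("annotations and uncurated must partition the leaves")

    def attribute_of(self, term_id: str) -> AttributeSet:
        return self.annotations.get(term_id, NO_ATTRIBUTES)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def _load_df(source, sep_hint: str | None = None) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.fillna("")
    path = Path(source)
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xlsm"}:
        df = pd.read_excel(path, sheet_name=0, dtype=str)
    elif suffix == ".tsv" or sep_hint == "\t":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df.fillna("")


def _find_columns(df: pd.DataFrame) -> dict[str, str]:
    """Map each attribute to its actual column header, via aliases."""
    lowered = {str(c).strip().lower(): c for c in df.columns}
    mapping: dict[str, str] = {}
    for attr, aliases in ATTRIBUTE_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                mapping[attr] = lowered[alias]
                break
        else:
            raise CurationError(
                f"missing attribute column for {ATTRIBUTE_HEADERS[attr]!r}")
    return mapping


def _parse_marker(cell: str, row_number: int, column: str) -> bool:
    value = str(cell).strip()
    if value in _PRESENT:
        return True
    if value in _ABSENT:
        return False
    raise CurationError(
        f"row {row_number}: unrecognized marker {value!r} in column {column!r}")


def read_curation(source, source_name: str | None = None,
                  subtype_delimiter: str = "|") -> CurationTable:
    """Load a curation sheet; ``+`` maps to True, ``−``/``-``/empty to False.

    The first two columns are taken as term id and label regardless of their
    header text; attribute columns are located by alias.  An optional
    subtype column carries delimiter-joined Test Data subtype tokens.
    """
    df = _load_df(source)
    if df.shape[1] < 6:
        raise CurationError(
            "curation table needs id, label and four attribute columns")
    id_col, label_col = df.columns[0], df.columns[1]
    attr_cols = _find_columns(df)
    lowered = {str(c).strip().lower(): c for c in df.columns}
    subtype_col = lowered.get(SUBTYPE_HEADER.lower())
    provenance = source_name or (str(source) if not isinstance(source, pd.DataFrame) else "")

    records = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        row_number = i + 2  # header is row 1
        term_id = str(row[id_col]).strip()
        try:
            check_term_id(term_id, prefix=term_id.split(":", 1)[0])
        except ValueError as exc:
            raise CurationError(f"row {row_number}: {exc}") from None
        if term_id in seen:
            raise CurationError(f"row {row_number}: duplicate term id {term_id}")
        seen.add(term_id)
        flags = {
            attr: _parse_marker(row[col], row_number, col)
            for attr, col in attr_cols.items()
        }
        subtypes: frozenset[str] = frozenset()
        if subtype_col is not None:
            tokens = [t.strip() for t in str(row[subtype_col]).split(subtype_delimiter)
                      if t.strip()]
            subtypes = frozenset(tokens)
            bad = subtypes - TEST_DATA_SUBTYPES
            if bad:
                raise CurationError(
                    f"row {row_number}: unknown test-data subtype(s) {sorted(bad)}")
            if subtypes and not flags["test_data"]:
                raise CurationError(
                    f"row {row_number}: subtypes given but Test Data is '−'")
        records.append(
            CurationRecord(
                term_id=term_id,
                label=str(row[label_col]).strip(),
                attributes=AttributeSet(**flags, test_data_subtypes=subtypes),
                source=provenance,
            )
        )
    return CurationTable(records)


def curation_frame(table: CurationTable, include_subtypes: bool = True,
                   subtype_delimiter: str = "|") -> pd.DataFrame:
    """Render a curation table back to its spreadsheet shape."""
    rows = []
    for r in table.records:
        row = {"HPO id": r.term_id, "Label": r.label}
        for attr in ATTRIBUTES:
            row[ATTRIBUTE_HEADERS[attr]] = "+" if r.attributes.has(attr) else "−"
        if include_subtypes:
            row[SUBTYPE_HEADER] = subtype_delimiter.join(
                sorted(r.attributes.test_data_subtypes))
        rows.append(row)
    columns = ["HPO id", "Label", *ATTRIBUTE_HEADERS.values()]
    if include_subtypes:
        columns.append(SUBTYPE_HEADER)
    return pd.DataFrame(rows, columns=columns)


def write_curation(table: CurationTable, path, **kwargs) -> None:
    """Write CSV/TSV/XLSX depending on the file suffix."""
    df = curation_frame(table, **kwargs)
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xlsm"}:
        df.to_excel(path, index=False)
    elif suffix == ".tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        df.to_csv(path, index=False)


def write_template(extract: CategoryExtract, graph=None) -> pd.DataFrame:
    """A draft curation sheet: one row per leaf, all attribute cells ``−``.

    Rows are sorted by label (then id) so output is bit-stable for a fixed
    input.  Giving curators a pre-filled draft makes the overall picture of a
    category easy to grasp before any judgement is entered.
    """
    rows = []
    for leaf in extract.leaves:
        label = graph[leaf].label if graph is not None else ""
        rows.append({"HPO id": leaf, "Label": label})
    rows.sort(key=lambda r: (r["Label"], r["HPO id"]))
    for row in rows:
        for attr in ATTRIBUTES:
            row[ATTRIBUTE_HEADERS[attr]] = "−"
        row[SUBTYPE_HEADER] = ""
    columns = ["HPO id", "Label", *ATTRIBUTE_HEADERS.values(), SUBTYPE_HEADER]
    return pd.DataFrame(rows, columns=columns)


def write_template_file(extract: CategoryExtract, path, graph=None) -> None:
    df = write_template(extract, graph)
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        df.to_excel(path, index=False)
    elif path.suffix.lower() == ".tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        df.to_csv(path, index=False)


def merge(extract: CategoryExtract, curation: CurationTable) -> AnnotatedExtract:
    """Join a category extract with a curation table.

    Gaps are data, not errors: leaves without a record land in ``uncurated``
    (all-false downstream), curated ids outside the leaf set land in
    ``stale``.
    """
    by_id = curation.by_id()
    annotations = {
        tid: by_id[tid].attributes for tid in extract.leaves if tid in by_id
    }
    uncurated = frozenset(extract.leaves - annotations.keys())
    stale = frozenset(set(by_id) - set(extract.leaves))
    return AnnotatedExtract(
        extract=extract,
        annotations=annotations,
        uncurated=uncurated,
        stale=stale,
    )
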