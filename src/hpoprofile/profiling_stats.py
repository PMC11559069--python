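"""Composition statistics: per-category counts, attribute profiles, overlap.

Percentages are rounded half-up (away from zero) to one decimal so output is
bit-stable; an empty category's percentage is ``None`` (rendered ``NA``),
never ``0.0`` — zero is a real observed value and must not be conflated with
no-data.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .attribute_tagging import ATTRIBUTES, AnnotatedExtract
from .category_extraction import Category, CategoryExtract


class UndefinedDenominator(ZeroDivisionError):
    """Percentage of an empty category is undefined (callers render null)."""


def round_half_up(value, decimals: int = 1) -> float:
    """Decimal round-half-up; exact for rational inputs."""
    if isinstance(value, Fraction):
        d = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        d = Decimal(str(value))
    q = Decimal(1).scaleb(-decimals)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def percent(k: int, n: int) -> float:
    """``100*k/n`` rounded half-up to one decimal.

    >>> percent(895, 961)
    93.1
    >>> percent(1, 16)   # 6.25 rounds away from zero
    6.3
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        raise UndefinedDenominator("percentage of an empty category")
    return round_half_up(Fraction(100 * k, n))


@dataclass(frozen=True)
class ProfileRow:
    """One category's attribute profile (total, flagged count, percentage)."""

    category_label: str
    n_total: int
    n_attribute: int
    percent: float | None

    def __post_init__(self) -> None:
        if not 0 <= self.n_attribute <= self.n_total:
            raise ValueError("need 0 <= n_attribute <= n_total")
        if self.n_total == 0:
            if self.percent is not None:
                raise ValueError("empty category must have null percent")
        elif self.percent != percent(self.n_attribute, self.n_total):
            raise ValueError("percent inconsistent with counts")


@dataclass(frozen=True)
class SummaryStats:
    n_categories: int
    mean_count: float
    min_count: int
    max_count: int

    def __post_init__(self) -> None:
        if not self.min_count <= self.mean_count <= self.max_count:
            raise ValueError("need min <= mean <= max")


def count_table(extracts: Sequence[CategoryExtract]) -> list[tuple[str, int]]:
    """Per-category leaf counts, in input order."""
    return [(e.category.label, len(e.leaves)) for e in extracts]


def summarize(counts: Sequence[tuple[str, int]]) -> SummaryStats:
    """Mean (half-up, one decimal), min and max of per-category counts."""
    if not counts:
        raise ValueError("summarize needs at least one category")
    values = [int(n) for _, n in counts]
    mean = round_half_up(Fraction(sum(values), len(values)))
    return SummaryStats(
        n_categories=len(values),
        mean_count=mean,
        min_count=min(values),
        max_count=max(values),
    )


def attribute_profile(
    annotated: Sequence[AnnotatedExtract], attribute: str
) -> list[ProfileRow]:
    """Per-category count and percentage of leaves carrying *attribute*.

    Uncurated leaves count as not-flagged but stay in the denominator: the
    denominator is always the category's full leaf count.
    """
    if attribute not in ATTRIBUTES:
        raise ValueError(f"unknown attribute {attribute!r}; pick from {ATTRIBUTES}")
    rows = []
    for ann in annotated:
        n_total = len(ann.extract.leaves)
        n_attr = sum(
            1 for tid in ann.extract.leaves if ann.attribute_of(tid).has(attribute)
        )
        pct = percent(n_attr, n_total) if n_total else None
        rows.append(
            ProfileRow(
                category_label=ann.extract.category.label,
                n_total=n_total,
                n_attribute=n_attr,
                percent=pct,
            )
        )
    return rows


def overlap_matrix(membership: Mapping[str, Iterable[Category]]) -> pd.DataFrame:
    """Symmetric matrix of shared-leaf counts between categories.

    Entry (i, j), i != j, counts leaves belonging to both categories; the
    diagonal carries each category's own leaf count.  Off-diagonal zeros
    everywhere means the ontology below the root is tree-shaped.
    """
    labels = sorted({c.label for cats in membership.values() for c in cats})
    df = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for cats in membership.values():
        cat_labels = sorted(c.label for c in cats)
        for i, a in enumerate(cat_labels):
            for b in cat_labels[i:]:
                df.loc[a, b] += 1
                if a != b:
                    df.loc[b, a] += 1
    return df
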