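"""Report rendering: count tables, summaries and attribute profiles.

Every report exists in machine form (TSV/CSV/JSON) and as a Markdown table
mirroring the published tables' column layout; the renderings never diverge
in content.  Percentages print with one decimal; an empty category renders
``NA``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .profiling_stats import ProfileRow, SummaryStats

FORMATS = ("tsv", "csv", "json", "md")


def _fmt_percent(p: float | None) -> str:
    return "NA" if p is None else f"{p:.1f}"


def count_frame(counts: Sequence[tuple[str, int]]) -> pd.DataFrame:
    return pd.DataFrame(counts, columns=["category", "n_leaves"])


def summary_frame(stats: SummaryStats) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "n_categories": stats.n_categories,
                "mean_count": f"{stats.mean_count:.1f}",
                "min_count": stats.min_count,
                "max_count": stats.max_count,
            }
        ]
    )


def profile_frame(rows: Sequence[ProfileRow], attribute: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category_label,
                "total": r.n_total,
                attribute: r.n_attribute,
                "percent": _fmt_percent(r.percent),
            }
            for r in rows
        ]
    )


def frame_to_markdown(df: pd.DataFrame) -> str:
    """Minimal GitHub-style table (no third-party table formatter needed)."""
    headers = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(headers) + " |",
             "| " + " | ".join("---" for _ in headers) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def write_frame(df: pd.DataFrame, path, fmt: str) -> Path:
    """Write one report in one format; returns the path written."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown report format {fmt!r}; pick from {FORMATS}")
    path = Path(path).with_suffix("." + fmt)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        payload = df.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
    else:
        path.write_text(frame_to_markdown(df), encoding="utf-8")
    return path


def category_listing(extract, graph) -> pd.DataFrame:
    """Per-category term listing (term_id, label, is_leaf) — the shape of a
    leaf-list download, with internal members flagged for context."""
    rows = [
        {
            "term_id": tid,
            "label": graph[tid].label,
            "is_leaf": tid in extract.leaves,
        }
        for tid in sorted(extract.members)
    ]
    return pd.DataFrame(rows, columns=["term_id", "label", "is_leaf"])
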