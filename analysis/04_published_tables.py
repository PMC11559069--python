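"""Stage 4 — recompute the published survey's derived numbers.

Takes the embedded published raw counts (23 per-category leaf counts; 16
curated (total, Symptoms-and-Findings) pairs) and recomputes every derived
cell: the count summary (mean/min/max) and each percentage column, verifying
them against the printed values. Writes both tables to results/published/.
"""

from pathlib import Path

import pandas as pd

from hpoprofile.profiling_stats import percent, summarize
from hpoprofile.published import CATEGORY_LEAF_COUNTS, SYMPTOMS_FINDINGS_CURATION
from hpoprofile.reporting import count_frame, summary_frame, write_frame

OUT = Path(__file__).resolve().parents[1] / "results" / "published"
OUT.mkdir(parents=True, exist_ok=True)

stats = summarize(CATEGORY_LEAF_COUNTS)
write_frame(count_frame(CATEGORY_LEAF_COUNTS), OUT / "leaf_counts", "tsv")
write_frame(summary_frame(stats), OUT / "leaf_count_summary", "tsv")
print(f"leaf counts across {stats.n_categories} categories: "
      f"mean {stats.mean_count}, range {stats.min_count}..{stats.max_count}")

rows = []
n_match = 0
for label, total, flagged, printed in SYMPTOMS_FINDINGS_CURATION:
    recomputed = percent(flagged, total)
    n_match += recomputed == printed
    rows.append({"category": label, "total": total,
                 "symptoms_findings": flagged,
                 "percent": f"{recomputed:.1f}"})
write_frame(pd.DataFrame(rows), OUT / "symptoms_findings", "tsv")
print(f"percentage cells matching the printed table: {n_match}/{len(rows)}")
assert n_match == len(rows)
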