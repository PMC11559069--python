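"""Stage 2 — extract the category layer and per-category leaf sets.

Parses the stage-1 OBO back in, extracts every category under the root,
writes per-category term listings plus the leaf-count table and its summary
to results/extraction/, and cross-checks the counts against the generator's
ground truth.
"""

import json
from pathlib import Path

from hpoprofile.category_extraction import extract_all
from hpoprofile.ontology_model import parse_obo
from hpoprofile.profiling_stats import count_table, summarize
from hpoprofile.reporting import category_listing, count_frame, summary_frame, write_frame

ROOT_DIR = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT_DIR / "extraction"
OUT.mkdir(parents=True, exist_ok=True)

graph = parse_obo(ROOT_DIR / "synthetic" / "ontology.obo")
truth = json.loads((ROOT_DIR / "synthetic" / "ground_truth.json").read_text())

extracts = extract_all(graph, truth["root_id"])
(OUT / "categories").mkdir(exist_ok=True)
for ext in extracts:
    safe = ext.category.label.replace(" ", "_")
    category_listing(ext, graph).to_csv(OUT / "categories" / f"{safe}.tsv",
                                        sep="\t", index=False)

counts = count_table(extracts)
write_frame(count_frame(counts), OUT / "counts", "tsv")
write_frame(summary_frame(summarize(counts)), OUT / "summary", "tsv")

recorded = {c["label"]: c["n_leaves"] for c in truth["categories"]}
mismatches = [lab for lab, n in counts if recorded[lab] != n]
stats = summarize(counts)
print(f"{len(extracts)} categories; leaf counts {stats.min_count}..{stats.max_count}, "
      f"mean {stats.mean_count}")
print(f"ground-truth mismatches: {len(mismatches)} (expect 0)")
assert not mismatches
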