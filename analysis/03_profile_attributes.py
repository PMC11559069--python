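"""Stage 3 — merge curation and profile the Symptoms-and-Findings attribute.

Joins the stage-1 curation table against every category extract and writes
the per-category (total, flagged, %) profile — the shape of a published
curation table — to results/profile/, in TSV and Markdown.
"""

import json
from pathlib import Path

from hpoprofile.attribute_tagging import merge, read_curation
from hpoprofile.category_extraction import extract_all
from hpoprofile.ontology_model import parse_obo
from hpoprofile.profiling_stats import attribute_profile
from hpoprofile.reporting import profile_frame, write_frame

ROOT_DIR = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT_DIR / "profile"
OUT.mkdir(parents=True, exist_ok=True)

graph = parse_obo(ROOT_DIR / "synthetic" / "ontology.obo")
truth = json.loads((ROOT_DIR / "synthetic" / "ground_truth.json").read_text())
curation = read_curation(ROOT_DIR / "synthetic" / "curation.csv")

annotated = [merge(ext, curation) for ext in extract_all(graph, truth["root_id"])]
rows = attribute_profile(annotated, "symptoms_findings")
write_frame(profile_frame(rows, "symptoms_findings"), OUT / "profile", "tsv")
write_frame(profile_frame(rows, "symptoms_findings"), OUT / "profile", "md")

uncurated = sum(len(a.uncurated) for a in annotated)
pcts = [r.percent for r in rows if r.percent is not None]
print(f"{len(rows)} categories profiled; Symptoms-and-Findings percentage "
      f"spans {min(pcts)}..{max(pcts)}")
print(f"uncurated leaves across categories: {uncurated} (expect 0)")

recorded = {c["label"]: c["true_counts"]["symptoms_findings"]
            for c in truth["categories"]}
mismatch = [r.category_label for r in rows if recorded[r.category_label] != r.n_attribute]
print(f"true-count mismatches: {len(mismatch)} (expect 0)")
assert not mismatch
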