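"""Stage 1 — generate the synthetic study ontology and its curation.

Writes a seeded HPO-like fixture at the study conditions (23 categories
under a "Phenotypic abnormality" root, four layers of endophenotype terms,
10% extra-parent rate, Symptoms-and-Findings proportions cycling through the
published per-category ratios) to results/synthetic/, alongside the
generator's ground truth.
"""

from pathlib import Path

from hpoprofile.synthetic_ontology import SyntheticSpec, write_fixture_set
import json

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"

spec = SyntheticSpec(seed=20240101, n_categories=23, depth=4,
                     branching_mean=3.0, multi_parent_prob=0.1, n_obsolete=5)
manifest = write_fixture_set(spec, OUT)
(OUT / "ground_truth.json").write_text(
    json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")

n_leaves = [c["n_leaves"] for c in manifest["categories"]]
print(f"wrote {manifest['n_terms']} terms, {len(n_leaves)} categories -> {OUT}")
print(f"leaves per category: min {min(n_leaves)}, max {max(n_leaves)}, "
      f"total {sum(n_leaves)}")
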