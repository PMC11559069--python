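"""The published category profile of the Human Phenotype Ontology.

A 2024 clinician-led survey of the 23 HPO categories directly under
"Phenotypic abnormality" (HP:0000118) downloaded each category's leaf-term
list via TogoDX and manually curated 16 of the 23 categories against the
four-attribute schema.  The two tables it printed — per-category leaf counts,
and per-category Symptoms-and-Findings counts — are embedded here verbatim
(including the survey's own label spellings) as reference inputs: the
pipeline's statistics functions recompute every derived cell (percentages,
mean/min/max) from these raw counts.

The absolute counts are a snapshot: they depend on the HPO release and on
TogoDX's leaf extraction, so a fresh HPO download will not reproduce them
exactly.  The arithmetic on top of them is exactly reproducible and is what
the acceptance checks exercise.
"""

from __future__ import annotations

#: per-category leaf-term counts, all 23 categories (label spellings verbatim)
CATEGORY_LEAF_COUNTS: tuple[tuple[str, int], ...] = (
    ("Abnormality of the genitourinary system", 1039),
    ("Abnormal cellular phenotyp", 191),
    ("Abnormality of blood and blood-forming tissues", 570),
    ("Abnormality of head and neck", 961),
    ("Abnormality of limbs", 1688),
    ("Abnormality of metabolism/homeostasis", 1219),
    ("Abnormality of prenatal development or birth", 192),
    ("Abnormality of the breast", 24),
    ("Abnormality of the cardiovascular system", 957),
    ("Abnormality of the digestive system", 496),
    ("Abnormality of the ear", 213),
    ("Abnormality of the endocrine system", 273),
    ("Abnormality of the eye", 777),
    ("Abnormality of the immune system", 871),
    ("Abnormality of the integument", 713),
    ("Abnormality of the muscleskeletal system", 2743),
    ("Abnormality of the nervous system", 1586),
    ("Abnormality of the respiratory system", 445),
    ("Abnormality of the thoracic cavity", 4),
    ("Abnormality of the voice", 21),
    ("Constitutional symptom", 81),
    ("Growth abnormality", 68),
    ("Neoplasm", 435),
)

#: (label, total leaves, leaves curated as Symptoms and Findings, printed %)
#: for the 16 curated categories
SYMPTOMS_FINDINGS_CURATION: tuple[tuple[str, int, int, float], ...] = (
    ("Abnormal cellular phenotyp", 191, 0, 0.0),
    ("Abnormality of blood and blood-forming tissues", 570, 26, 4.6),
    ("Abnormality of head and neck", 961, 895, 93.1),
    ("Abnormality of prenatal development or birth", 192, 33, 17.2),
    ("Abnormality of the breast", 24, 19, 79.2),
    ("Abnormality of the digestive system", 496, 92, 18.5),
    ("Abnormality of the ear", 213, 154, 72.3),
    ("Abnormality of the endocrine system", 273, 5, 1.8),
    ("Abnormality of the immune system", 871, 31, 3.6),
    ("Abnormality of the integument", 713, 603, 84.6),
    ("Abnormality of the respiratory system", 445, 67, 15.1),
    ("Abnormality of the thoracic cavity", 4, 0, 0.0),
    ("Abnormality of the voice", 21, 16, 76.2),
    ("Constitutional symptom", 81, 77, 95.1),
    ("Growth abnormality", 68, 63, 92.6),
    ("Neoplasm", 435, 0, 0.0),
)


def symptoms_findings_fractions() -> list[float]:
    """Curated Symptoms-and-Findings proportions (flagged/total), 16 values."""
    return [k / n for _, n, k, _ in SYMPTOMS_FINDINGS_CURATION]
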