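"""The multi-cohort study design the synthetic generator emulates.

Nine whole-blood / sorted-cell SLE case-control expression datasets split
into three discovery and six validation cohorts. The per-dataset sample
sizes below seed the default dimensions of the synthetic generator and the
discovery/validation bookkeeping of the pipeline.
"""

from __future__ import annotations

import pandas as pd

#: (dataset id, sample type, total sample size, role)
STUDY_COHORTS: list[tuple[str, str, int, str]] = [
    ("GSE65391", "Whole Blood", 996, "discovery"),
    ("GSE49454", "Whole Blood", 177, "discovery"),
    ("GSE50635", "Whole Blood", 49, "discovery"),
    ("GSE10325", "CD4 T cells, CD19 B cells", 67, "validation"),
    ("GSE30153", "B cells", 26, "validation"),
    ("GSE37356", "Monocytes", 72, "validation"),
    ("GSE27427", "Neutrophils", 47, "validation"),
    ("GSE39088", "Whole Blood", 142, "validation"),
    ("GSE11909", "Whole Blood", 115, "validation"),
]

#: Approximate case fraction used when splitting a total into cases/controls.
#: The source study reports only totals per dataset; the split is a
#: package-level default, not a published fact.
DEFAULT_CASE_FRACTION = 0.55


def study_table() -> pd.DataFrame:
    """Return the study design as a DataFrame (dataset, sample_type, n, role)."""
    return pd.DataFrame(
        STUDY_COHORTS, columns=["dataset", "sample_type", "n", "role"]
    )


def total_samples(role: str) -> int:
    """Sum of per-dataset sample sizes for one role ('discovery'/'validation')."""
    return int(sum(n for _, _, n, r in STUDY_COHORTS if r == role))
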