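"""Marker-based immune-cell quantification and case/control comparison.

Each cell type is quantified separately as the arithmetic mean of the log2
expression of its marker genes (MCP-counter-style scoring). Scores are
relative abundances in arbitrary log2 units: they support within-cell-type
comparisons between sample groups but NOT comparisons between different cell
types. Group differences are tested per cell type with a two-sided Wilcoxon
rank-sum test, Benjamini-Hochberg corrected across cell types.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .errors import InputError
from .evaluation import wilcoxon_scores
from .expression_io import ExpressionCohort
from .meta_effects import benjamini_hochberg

logger = logging.getLogger(__name__)

MarkerPanel = dict[str, list[str]]


def load_panel(path: str | Path) -> MarkerPanel:
    """Load a marker panel from YAML/JSON: {cell type: [marker gene ids]}."""
    with open(path) as fh:
        panel = yaml.safe_load(fh)
    validate_panel(panel)
    return panel


def validate_panel(panel: MarkerPanel) -> None:
    if not isinstance(panel, dict) or not panel:
        raise InputError("marker panel must be a non-empty mapping")
    for cell, markers in panel.items():
        if not isinstance(markers, list) or not markers:
            raise InputError(f"cell type {cell!r} has an empty marker list")


def cell_scores(cohort: ExpressionCohort, panel: MarkerPanel) -> pd.DataFrame:
    """Per-sample cell-type scores: mean log2 expression of present markers.

    Markers absent from the cohort are dropped with a warning; a cell type
    with no present markers is excluded (logged). Returns a cell-type ×
    sample DataFrame.
    """
    validate_panel(panel)
    present = set(cohort.gene_ids)
    rows = {}
    for cell, markers in panel.items():
        found = [m for m in dict.fromkeys(markers) if m in present]
        absent = [m for m in markers if m not in present]
        if absent:
            logger.warning(
                "%s: markers for %s absent from cohort: %s",
                cohort.cohort_id,
                cell,
                absent,
            )
        if not found:
            logger.warning("%s: cell type %s has no present markers; excluded", cohort.cohort_id, cell)
            continue
        rows[cell] = cohort.values.loc[found].mean(axis=0)
    if not rows:
        raise InputError(f"{cohort.cohort_id}: no cell type has any present marker")
    out = pd.DataFrame(rows).T
    out.index.name = "cell_type"
    return out


def compare_groups(scores: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Case/control comparison per cell type.

    Returns one row per cell type with the group means, two-sided Wilcoxon p,
    BH q across cell types, the direction of the shift, and significance
    stars ('*' q < 0.05, '**' q < 0.01).
    """
    labels = labels.reindex(scores.columns)
    case_mask = (labels == "case").to_numpy()
    if case_mask.all() or not case_mask.any():
        raise InputError("compare_groups requires both classes")
    rows = []
    for cell in scores.index:
        s = scores.loc[cell].to_numpy(dtype=float)
        case, control = s[case_mask], s[~case_mask]
        rows.append(
            {
                "cell_type": cell,
                "mean_case": case.mean(),
                "mean_control": control.mean(),
                "p": wilcoxon_scores(case, control),
            }
        )
    out = pd.DataFrame(rows).set_index("cell_type")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["direction"] = ["case" if c > t else "control" for c, t in zip(out["mean_case"], out["mean_control"])]
    out["stars"] = ["**" if q < 0.01 else "*" if q < 0.05 else "" for q in out["q"]]
    return out
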