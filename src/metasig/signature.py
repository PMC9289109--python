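"""Greedy forward-search gene signatures and the per-sample disease score.

A signature is an ordered pair of gene sets: genes up-regulated in cases and
genes down-regulated in cases. The per-sample disease score is

    score = mean(expression of up genes) - mean(expression of down genes),

in log2-expression units. Forward search grows the signature one gene at a
time from the candidates surviving the differential-expression filter: at
each step every unselected candidate is provisionally added to its
sign-matched side (pooled effect > 0 → up, < 0 → down) and the candidate
giving the largest gain in the objective — the sample-size-weighted mean of
per-cohort AUCs over the discovery cohorts — is kept. The search stops when
the best gain no longer exceeds ``min_improvement`` (default 0: any strict
gain is accepted) or ``max_genes`` is reached. Ties are broken by smaller
FDR q, then larger |pooled effect|, then lexicographic gene id, which makes
the result independent of candidate input order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .evaluation import auc
from .expression_io import ExpressionCohort

logger = logging.getLogger(__name__)


@dataclass
class Signature:
    """Ordered up/down gene sets with the greedy selection trace."""

    up_genes: list[str]
    down_genes: list[str]
    #: per selection step: (gene added, objective value after adding it)
    trace: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise InputError(f"up/down gene sets overlap: {sorted(overlap)}")
        if not self.up_genes and not self.down_genes:
            raise InputError("signature must contain at least one gene")

    @property
    def genes(self) -> list[str]:
        return list(self.up_genes) + list(self.down_genes)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "up": self.up_genes,
                    "down": self.down_genes,
                    "trace": [[g, v] for g, v in self.trace],
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "Signature":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            up_genes=list(d["up"]),
            down_genes=list(d["down"]),
            trace=[(g, float(v)) for g, v in d.get("trace", [])],
        )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def compute_scores(cohort: ExpressionCohort, signature: Signature) -> pd.DataFrame:
    """Per-sample disease score: mean(up genes) - mean(down genes).

    Signature genes absent from the cohort are dropped from the relevant
    mean (warned); a side with no present genes contributes 0. Returns a
    DataFrame indexed by sample id with columns ``class`` and ``score``.
    """
    present = set(cohort.gene_ids)
    up = [g for g in signature.up_genes if g in present]
    down = [g for g in signature.down_genes if g in present]
    missing = [g for g in signature.genes if g not in present]
    if missing:
        logger.warning(
            "%s: signature genes absent from cohort: %s", cohort.cohort_id, missing
        )
    if not up and not down:
        raise InputError(
            f"{cohort.cohort_id}: no signature genes present in cohort"
        )
    up_part = cohort.values.loc[up].mean(axis=0) if up else 0.0
    down_part = cohort.values.loc[down].mean(axis=0) if down else 0.0
    score = pd.Series(up_part - down_part, index=cohort.sample_ids)
    return pd.DataFrame({"class": cohort.labels, "score": score})


def score_cohorts(
    cohorts: list[ExpressionCohort], signature: Signature
) -> dict[str, pd.DataFrame]:
    """Score several cohorts; cohorts with no signature genes are skipped with a warning."""
    tables = {}
    for cohort in cohorts:
        try:
            tables[cohort.cohort_id] = compute_scores(cohort, signature)
        except InputError as exc:
            logger.warning("skipping cohort %s: %s", cohort.cohort_id, exc)
    return tables


# ---------------------------------------------------------------------------
# forward search
# ---------------------------------------------------------------------------


def _weighted_objective(
    per_cohort_scores: list[np.ndarray],
    case_masks: list[np.ndarray],
    weights: np.ndarray,
) -> float:
    """Sample-size-weighted mean of per-cohort AUCs for one candidate scoring."""
    aucs = np.array(
        [auc(s[m], s[~m]) for s, m in zip(per_cohort_scores, case_masks)]
    )
    return float(np.average(aucs, weights=weights))


def forward_search(
    cohorts: list[ExpressionCohort],
    candidates: pd.DataFrame,
    min_improvement: float = 0.0,
    max_genes: int | None = None,
    weighted: bool = True,
) -> Signature:
    """Greedy forward selection of the most parsimonious up/down signature.

    Parameters
    ----------
    cohorts:
        Discovery cohorts (each must contain both classes).
    candidates:
        Filtered pooled-effect table indexed by gene id with columns ``mu``
        and ``q`` (output of :func:`metasig.meta_effects.filter_significant`).
    min_improvement:
        Minimum strict gain in the objective required to keep adding genes.
    max_genes:
        Optional hard cap on signature size.
    weighted:
        Weight per-cohort AUCs by cohort sample size (default) or uniformly.
    """
    if len(candidates) == 0:
        raise InputError("forward_search requires at least one candidate gene")
    for cohort in cohorts:
        if cohort.n_case == 0 or cohort.n_control == 0:
            raise InputError(
                f"{cohort.cohort_id}: discovery cohort lacks one class"
            )

    # restrict to candidates measured in every discovery cohort
    usable = [
        g for g in candidates.index if all(g in c.gene_ids for c in cohorts)
    ]
    dropped = set(candidates.index) - set(usable)
    if dropped:
        logger.warning(
            "dropping %d candidates absent from some discovery cohort: %s",
            len(dropped),
            sorted(dropped),
        )
    if not usable:
        raise InputError("no candidate gene is present in all discovery cohorts")
    candidates = candidates.loc[usable]

    # deterministic evaluation order: q asc, |mu| desc, gene id asc.
    # combined with strict ">" in the argmax this realizes the tie-break rule.
    order = (
        candidates.assign(_abs_mu=candidates["mu"].abs())
        .reset_index(names="gene_id")
        .sort_values(by=["q", "_abs_mu", "gene_id"], ascending=[True, False, True], kind="stable")
    )
    cand_genes = order["gene_id"].tolist()
    cand_sign = {g: 1 if m > 0 else -1 for g, m in zip(order["gene_id"], order["mu"])}

    case_masks = [c.case_mask for c in cohorts]
    weights = (
        np.array([c.n_samples for c in cohorts], dtype=float)
        if weighted
        else np.ones(len(cohorts))
    )
    # per cohort: gene -> expression row (aligned sample order)
    expr = [
        {g: c.values.loc[g].to_numpy(dtype=float) for g in cand_genes} for c in cohorts
    ]

    up: list[str] = []
    down: list[str] = []
    trace: list[tuple[str, float]] = []
    # running sums of the selected genes' expression per cohort
    up_sums = [np.zeros(c.n_samples) for c in cohorts]
    down_sums = [np.zeros(c.n_samples) for c in cohorts]
    current_objective = 0.5  # empty signature is uninformative

    remaining = list(cand_genes)
    while remaining and (max_genes is None or len(up) + len(down) < max_genes):
        best_gene = None
        best_obj = -np.inf
        for g in remaining:
            sign = cand_sign[g]
            n_up = len(up) + (1 if sign > 0 else 0)
            n_down = len(down) + (1 if sign < 0 else 0)
            scores = []
            for ci in range(len(cohorts)):
                u = up_sums[ci] + (expr[ci][g] if sign > 0 else 0.0)
                d = down_sums[ci] + (expr[ci][g] if sign < 0 else 0.0)
                s = (u / n_up if n_up else 0.0) - (d / n_down if n_down else 0.0)
                scores.append(s)
            obj = _weighted_objective(scores, case_masks, weights)
            if obj > best_obj:
                best_obj, best_gene = obj, g

        gain = best_obj - current_objective
        if trace and gain <= min_improvement:
            break
        if not trace and best_obj <= 0.5:
            logger.warning(
                "no candidate improves over AUC 0.5; returning best single gene %s",
                best_gene,
            )
        # commit the best gene
        sign = cand_sign[best_gene]
        (up if sign > 0 else down).append(best_gene)
        for ci in range(len(cohorts)):
            if sign > 0:
                up_sums[ci] = up_sums[ci] + expr[ci][best_gene]
            else:
                down_sums[ci] = down_sums[ci] + expr[ci][best_gene]
        remaining.remove(best_gene)
        current_objective = best_obj
        trace.append((best_gene, best_obj))
        if not remaining:
            break
        # after the first forced step, stop as soon as no strict gain remains
        # (handled at the top of the loop on the next iteration)

    return Signature(up_genes=up, down_genes=down, trace=trace)
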