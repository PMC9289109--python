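"""Diagnostic performance: ROC/AUC, bootstrap CIs, pooled summary AUC.

AUC is computed in its Mann-Whitney form — the probability that a randomly
chosen case scores above a randomly chosen control, ties counting 1/2.
Per-cohort confidence intervals come from a stratified percentile bootstrap.
The cross-cohort summary AUC pools per-cohort AUCs on the logit scale with
DerSimonian-Laird random effects, using the Hanley-McNeil variance of each
AUC mapped to the logit scale by the delta method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InputError
from .meta_effects import dersimonian_laird

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# score-table helpers
# ---------------------------------------------------------------------------


def _split_scores(score_table: pd.DataFrame):
    """Split a score table (columns ``class``, ``score``) into case/control arrays."""
    cls = score_table["class"].to_numpy()
    s = score_table["score"].to_numpy(dtype=float)
    case, control = s[cls == "case"], s[cls == "control"]
    if case.size == 0 or control.size == 0:
        raise InputError("score table must contain both classes")
    return case, control


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def auc(case_scores, control_scores) -> float:
    """Mann-Whitney AUC: P(case score > control score) + 0.5 P(tie)."""
    case = np.asarray(case_scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    if case.size == 0 or control.size == 0:
        raise InputError("auc requires both classes")
    ranks = stats.rankdata(np.concatenate([case, control]))
    r1 = ranks[: case.size].sum()
    u = r1 - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * control.size))


def auc_from_table(score_table: pd.DataFrame) -> float:
    case, control = _split_scores(score_table)
    return auc(case, control)


def roc_points(case_scores, control_scores) -> pd.DataFrame:
    """ROC coordinates (FPR, TPR) at every distinct score threshold."""
    y = np.r_[np.ones(len(case_scores)), np.zeros(len(control_scores))]
    s = np.r_[case_scores, control_scores]
    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})


def auc_ci(
    case_scores, control_scores, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI of the AUC.

    Resampling is stratified within class (so every resample keeps both
    classes). Deterministic for a fixed seed.
    """
    case = np.asarray(case_scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    n1, n2 = case.size, control.size
    if n1 < 2 or n2 < 2:
        raise InputError("auc_ci requires >=2 samples per class")
    rng = np.random.default_rng(seed)
    case_b = case[rng.integers(0, n1, size=(n_boot, n1))]
    control_b = control[rng.integers(0, n2, size=(n_boot, n2))]
    ranks = stats.rankdata(np.concatenate([case_b, control_b], axis=1), axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    aucs = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------


def wilcoxon_scores(case_scores, control_scores) -> float:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum p-value.

    Exact enumeration when n_case*n_control <= 400 and the data are tie-free;
    otherwise the normal approximation with tie correction. Fully tied data
    (zero rank variance) return p = 1.
    """
    case = np.asarray(case_scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    if case.size == 0 or control.size == 0:
        raise InputError("wilcoxon_scores requires both classes")
    combined = np.concatenate([case, control])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = np.unique(combined).size < combined.size
    small = case.size * control.size <= 400
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(case, control, alternative="two-sided", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# summary AUC across cohorts
# ---------------------------------------------------------------------------


def hanley_mcneil_variance(a: float, n_case: int, n_control: int) -> float:
    """Hanley-McNeil variance of an empirical AUC."""
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    return (
        a * (1 - a) + (n_case - 1) * (q1 - a**2) + (n_control - 1) * (q2 - a**2)
    ) / (n_case * n_control)


def summary_auc(per_cohort: pd.DataFrame) -> tuple[float, float, float]:
    """Pool per-cohort AUCs into one summary AUC with 95% CI.

    ``per_cohort`` needs columns ``auc``, ``n_case``, ``n_control`` and — for
    the single-cohort passthrough — ``ci_low``/``ci_high``. AUCs are pooled by
    DerSimonian-Laird random effects on the logit scale with Hanley-McNeil
    variances; boundary AUCs (0 or 1) are clipped into [1/(4n), 1 - 1/(4n)]
    before the logit, n being the cohort's total sample size.
    """
    if len(per_cohort) == 0:
        raise InputError("summary_auc requires at least one cohort")
    if len(per_cohort) == 1:
        row = per_cohort.iloc[0]
        return float(row["auc"]), float(row.get("ci_low", np.nan)), float(row.get("ci_high", np.nan))

    a = per_cohort["auc"].to_numpy(dtype=float).copy()
    n1 = per_cohort["n_case"].to_numpy(dtype=int)
    n2 = per_cohort["n_control"].to_numpy(dtype=int)
    n_tot = n1 + n2
    lo_bound = 1.0 / (4.0 * n_tot)
    clipped = (a <= lo_bound) | (a >= 1 - lo_bound)
    if clipped.any():
        logger.info("clipping %d boundary AUCs before logit transform", int(clipped.sum()))
        a = np.clip(a, lo_bound, 1.0 - lo_bound)

    var_a = np.array([hanley_mcneil_variance(ai, c, t) for ai, c, t in zip(a, n1, n2)])
    logit_a = np.log(a / (1.0 - a))
    var_logit = var_a / (a * (1.0 - a)) ** 2  # delta method
    mu, se, _, _, _ = dersimonian_laird(logit_a[None, :], var_logit[None, :])
    expit = lambda z: 1.0 / (1.0 + np.exp(-z))
    return (
        float(expit(mu[0])),
        float(expit(mu[0] - 1.96 * se[0])),
        float(expit(mu[0] + 1.96 * se[0])),
    )


# ---------------------------------------------------------------------------
# cohort-level evaluation
# ---------------------------------------------------------------------------


@dataclass
class RocSummary:
    """Per-cohort ROC statistics plus the pooled summary AUC."""

    per_cohort: pd.DataFrame  # cohort_id, auc, ci_low, ci_high, wilcoxon_p, n_case, n_control
    summary_auc: float
    summary_ci_low: float
    summary_ci_high: float

    def to_frame(self) -> pd.DataFrame:
        df = self.per_cohort.copy()
        summary = pd.DataFrame(
            [
                {
                    "cohort_id": "summary",
                    "auc": self.summary_auc,
                    "ci_low": self.summary_ci_low,
                    "ci_high": self.summary_ci_high,
                    "wilcoxon_p": np.nan,
                    "n_case": int(df["n_case"].sum()),
                    "n_control": int(df["n_control"].sum()),
                }
            ]
        )
        return pd.concat([df, summary], ignore_index=True)


def evaluate_cohorts(
    score_tables: dict[str, pd.DataFrame], n_boot: int = 2000, seed: int = 0
) -> RocSummary:
    """Per-cohort AUC with bootstrap CI and Wilcoxon p, plus the summary AUC.

    ``score_tables`` maps cohort id to a per-sample score table with columns
    ``class`` and ``score``. Bootstrap seeds are derived deterministically
    from ``seed`` per cohort.
    """
    if not score_tables:
        raise InputError("no score tables supplied")
    rows = []
    child_seeds = np.random.SeedSequence(seed).generate_state(len(score_tables)) % (2**31)
    for (cid, table), s in zip(sorted(score_tables.items()), child_seeds):
        case, control = _split_scores(table)
        a = auc(case, control)
        lo, hi = auc_ci(case, control, n_boot=n_boot, seed=int(s))
        rows.append(
            {
                "cohort_id": cid,
                "auc": a,
                "ci_low": lo,
                "ci_high": hi,
                "wilcoxon_p": wilcoxon_scores(case, control),
                "n_case": case.size,
                "n_control": control.size,
            }
        )
    per_cohort = pd.DataFrame(rows)
    s_auc, s_lo, s_hi = summary_auc(per_cohort)
    return RocSummary(per_cohort, s_auc, s_lo, s_hi)
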