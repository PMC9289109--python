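"""Per-gene effect sizes and DerSimonian-Laird random-effects pooling.

For each gene and cohort the case/control contrast is summarized by Hedges'
g, the standardized mean difference with the small-sample bias correction

    J = 1 - 3 / (4(n1 + n2) - 9),        g = J * (m1 - m2) / s_pooled,
    var(g) = (n1 + n2)/(n1 n2) + g^2 / (2 (n1 + n2)).

Per-gene effects are combined across cohorts with the DerSimonian-Laird
method-of-moments random-effects estimator: Cochran's Q under fixed-effect
weights w_i = 1/v_i yields

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),

random-effect weights w*_i = 1/(v_i + tau^2), pooled mean mu = sum(w* g)/sum(w*)
with standard error (sum w*)^{-1/2} and a two-sided normal z-test p-value.
Significance is controlled by Benjamini-Hochberg FDR across genes, and the
differential-expression filter keeps genes with q below an FDR ceiling and
|mu| above an effect-size floor (defaults: q < 0.01, |mu| > 0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .expression_io import ExpressionCohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PooledEffect:
    """Random-effects summary of one gene across cohorts."""

    gene_id: str
    mu: float
    se_mu: float
    tau2: float
    Q: float
    k: int
    p: float


# ---------------------------------------------------------------------------
# Hedges' g
# ---------------------------------------------------------------------------


def hedges_g(case_values, control_values):
    """Hedges' g and its sampling variance for one gene.

    Accepts 1-D arrays (per-group samples). Returns ``(g, var_g)``; both are
    NaN when the pooled standard deviation is zero (degenerate gene, excluded
    from pooling upstream).
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    n1, n2 = case.size, control.size
    if n1 < 2 or n2 < 2:
        raise InputError(f"hedges_g requires >=2 samples per group, got {n1}/{n2}")
    g, var_g = _hedges_g_rows(case[None, :], control[None, :])
    return float(g[0]), float(var_g[0])


def _hedges_g_rows(case: np.ndarray, control: np.ndarray):
    """Vectorized Hedges' g over rows (genes). NaN where pooled SD is zero."""
    n1, n2 = case.shape[1], control.shape[1]
    m1 = case.mean(axis=1)
    m2 = control.mean(axis=1)
    s1 = case.var(axis=1, ddof=1)
    s2 = control.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    sp = np.sqrt(sp2)
    n = n1 + n2
    j = 1.0 - 3.0 / (4.0 * n - 9.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = j * (m1 - m2) / sp
    g = np.where(sp > 0, g, np.nan)
    var_g = n / (n1 * n2) + g**2 / (2.0 * n)
    return g, var_g


def cohort_effects(cohort: ExpressionCohort) -> pd.DataFrame:
    """Per-gene Hedges' g (case vs control) for one cohort.

    Returns a DataFrame indexed by gene id with columns ``g``, ``var_g``,
    ``n_case``, ``n_control``. Degenerate genes (zero pooled SD) carry NaN
    and are logged.
    """
    mask = cohort.case_mask
    x = cohort.values.to_numpy(dtype=float)
    g, var_g = _hedges_g_rows(x[:, mask], x[:, ~mask])
    n_bad = int(np.isnan(g).sum())
    if n_bad:
        logger.info("%s: %d genes with zero pooled SD flagged degenerate", cohort.cohort_id, n_bad)
    return pd.DataFrame(
        {
            "g": g,
            "var_g": var_g,
            "n_case": cohort.n_case,
            "n_control": cohort.n_control,
        },
        index=cohort.gene_ids,
    )


# ---------------------------------------------------------------------------
# DerSimonian-Laird pooling
# ---------------------------------------------------------------------------


def dersimonian_laird(g: np.ndarray, var_g: np.ndarray):
    """DL pooling of effect arrays; returns (mu, se, tau2, Q, k).

    Core estimator, shared by the scalar and the matrix entry points and by
    the summary-AUC pooling in :mod:`metasig.evaluation`.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    var_g = np.atleast_2d(np.asarray(var_g, dtype=float))
    k = g.shape[1]
    w = 1.0 / var_g
    sw = w.sum(axis=1)
    g_fe = (w * g).sum(axis=1) / sw
    q = (w * (g - g_fe[:, None]) ** 2).sum(axis=1)
    if k > 1:
        denom = sw - (w**2).sum(axis=1) / sw
        tau2 = np.maximum(0.0, (q - (k - 1)) / denom)
    else:
        tau2 = np.zeros_like(q)
    w_star = 1.0 / (var_g + tau2[:, None])
    sw_star = w_star.sum(axis=1)
    mu = (w_star * g).sum(axis=1) / sw_star
    se = 1.0 / np.sqrt(sw_star)
    return mu, se, tau2, q, k


def pool_dersimonian_laird(effects: pd.DataFrame | list) -> PooledEffect:
    """Pool one gene's per-cohort effects by DerSimonian-Laird.

    ``effects`` is a DataFrame with columns ``g`` and ``var_g`` (one row per
    cohort) or a list of ``(g, var_g)`` pairs. NaN (degenerate) rows must be
    removed by the caller; an empty input raises.
    """
    if isinstance(effects, pd.DataFrame):
        gene_id = str(effects.index.name or "")
        g = effects["g"].to_numpy(dtype=float)
        v = effects["var_g"].to_numpy(dtype=float)
    else:
        gene_id = ""
        arr = np.asarray(effects, dtype=float)
        if arr.size == 0:
            raise InputError("pool_dersimonian_laird: empty effect list")
        g, v = arr[:, 0], arr[:, 1]
    if g.size == 0:
        raise InputError("pool_dersimonian_laird: empty effect list")
    if np.isnan(g).any() or (v <= 0).any():
        raise InputError("pool_dersimonian_laird: NaN effects or non-positive variances")
    mu, se, tau2, q, k = dersimonian_laird(g[None, :], v[None, :])
    p = 2.0 * stats.norm.sf(abs(mu[0] / se[0]))
    return PooledEffect(
        gene_id=gene_id,
        mu=float(mu[0]),
        se_mu=float(se[0]),
        tau2=float(tau2[0]),
        Q=float(q[0]),
        k=int(k),
        p=float(p),
    )


def pool_cohort_effects(
    effects_by_cohort: dict[str, pd.DataFrame], min_cohorts: int | None = None
) -> pd.DataFrame:
    """Pool per-cohort effect tables across all genes.

    Parameters
    ----------
    effects_by_cohort:
        ``{cohort_id: cohort_effects(...) output}``.
    min_cohorts:
        Minimum number of cohorts a gene must have a non-degenerate effect in
        to be pooled. Default: all cohorts (a strict common gene universe).

    Returns
    -------
    DataFrame indexed by gene id with columns ``k, mu, se, tau2, Q, p, q``.
    ``q`` is the Benjamini-Hochberg adjusted p-value across the pooled genes.
    """
    if not effects_by_cohort:
        raise InputError("no cohort effect tables supplied")
    n_cohorts = len(effects_by_cohort)
    if min_cohorts is None:
        min_cohorts = n_cohorts

    g_wide = pd.DataFrame({cid: df["g"] for cid, df in effects_by_cohort.items()})
    v_wide = pd.DataFrame({cid: df["var_g"] for cid, df in effects_by_cohort.items()})
    available = g_wide.notna().sum(axis=1)
    keep = available >= min_cohorts
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropping %d genes present in fewer than %d cohorts", n_dropped, min_cohorts
        )
    g_wide, v_wide = g_wide.loc[keep], v_wide.loc[keep]

    genes = g_wide.index
    full = g_wide.notna().all(axis=1).to_numpy()
    mu = np.empty(len(genes))
    se = np.empty(len(genes))
    tau2 = np.empty(len(genes))
    q_stat = np.empty(len(genes))
    kk = np.empty(len(genes), dtype=int)

    if full.any():
        m, s, t, qq, k = dersimonian_laird(
            g_wide.to_numpy()[full], v_wide.to_numpy()[full]
        )
        mu[full], se[full], tau2[full], q_stat[full], kk[full] = m, s, t, qq, k
    if (~full).any():
        # genes missing from some cohorts: pool over the cohorts they appear in
        for i in np.flatnonzero(~full):
            row_g = g_wide.iloc[i].dropna()
            row_v = v_wide.iloc[i].loc[row_g.index]
            m, s, t, qq, k = dersimonian_laird(
                row_g.to_numpy()[None, :], row_v.to_numpy()[None, :]
            )
            mu[i], se[i], tau2[i], q_stat[i], kk[i] = m[0], s[0], t[0], qq[0], k

    p = 2.0 * stats.norm.sf(np.abs(mu / se))
    out = pd.DataFrame(
        {"k": kk, "mu": mu, "se": se, "tau2": tau2, "Q": q_stat, "p": p},
        index=genes,
    )
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# multiple testing and filtering
# ---------------------------------------------------------------------------


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Order is preserved against the input indexing.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_significant(
    pooled: pd.DataFrame, fdr_max: float = 0.01, effect_min: float = 0.8
) -> pd.DataFrame:
    """Differential-expression filter: q < fdr_max and |mu| > effect_min.

    The effect threshold applies to the pooled standardized mean difference
    (Hedges' g scale). Result is sorted by |mu| descending, ties broken by q
    ascending then gene id.
    """
    kept = pooled[(pooled["q"] < fdr_max) & (pooled["mu"].abs() > effect_min)].copy()
    kept["_abs_mu"] = kept["mu"].abs()
    idx_name = kept.index.name or "gene_id"
    kept = (
        kept.reset_index(names=idx_name)
        .sort_values(by=["_abs_mu", "q", idx_name], ascending=[False, True, True], kind="stable")
        .set_index(idx_name)
    )
    return kept.drop(columns="_abs_mu")


def forest_data(
    effects_by_cohort: dict[str, pd.DataFrame], pooled: pd.DataFrame, gene_id: str
) -> pd.DataFrame:
    """Forest-plot rows for one gene: per-cohort g with 95% CI plus the pooled row."""
    rows = []
    for cid, df in effects_by_cohort.items():
        if gene_id in df.index and np.isfinite(df.at[gene_id, "g"]):
            g = df.at[gene_id, "g"]
            se = np.sqrt(df.at[gene_id, "var_g"])
            rows.append((cid, g, g - 1.96 * se, g + 1.96 * se))
    mu = pooled.at[gene_id, "mu"]
    se = pooled.at[gene_id, "se"]
    rows.append(("pooled", mu, mu - 1.96 * se, mu + 1.96 * se))
    return pd.DataFrame(rows, columns=["cohort_id", "effect", "ci_low", "ci_high"])
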