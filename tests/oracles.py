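"""Independent brute-force reference implementations.

Each function here is written directly from the defining formula or by
exhaustive enumeration, deliberately kept separate from the package's
vectorized implementations so the two can be compared as independent routes.
"""

import itertools
import math

import numpy as np


def hedges_g_brute(case, control):
    """Hedges' g straight from the defining formula, scalar arithmetic only."""
    n1, n2 = len(case), len(control)
    m1 = sum(case) / n1
    m2 = sum(control) / n2
    s1 = sum((x - m1) ** 2 for x in case) / (n1 - 1)
    s2 = sum((x - m2) ** 2 for x in control) / (n2 - 1)
    sp = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    j = 1 - 3 / (4 * (n1 + n2) - 9)
    g = j * (m1 - m2) / sp
    var = (n1 + n2) / (n1 * n2) + g**2 / (2 * (n1 + n2))
    return g, var


def dl_pool_brute(gs, vs):
    """DerSimonian-Laird pooling with plain loops: (mu, se, tau2, Q)."""
    k = len(gs)
    ws = [1.0 / v for v in vs]
    sw = sum(ws)
    g_fe = sum(w * g for w, g in zip(ws, gs)) / sw
    q = sum(w * (g - g_fe) ** 2 for w, g in zip(ws, gs))
    if k > 1:
        tau2 = max(0.0, (q - (k - 1)) / (sw - sum(w**2 for w in ws) / sw))
    else:
        tau2 = 0.0
    wstar = [1.0 / (v + tau2) for v in vs]
    mu = sum(w * g for w, g in zip(wstar, gs)) / sum(wstar)
    se = 1.0 / math.sqrt(sum(wstar))
    return mu, se, tau2, q


def bh_brute(p_values):
    """BH step-up from the definition: q_i = min_{p_(j) >= p_(i)} p_(j) * m / j."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(indexed, start=1):
        candidates = []
        for other_pos, jdx in enumerate(indexed, start=1):
            if p_values[jdx] >= p_values[i] - 1e-15:
                candidates.append(min(1.0, p_values[jdx] * m / other_pos))
        q[i] = min(candidates)
    return q


def auc_brute(case, control):
    """AUC by exhaustive pair counting (ties count 1/2)."""
    wins = 0.0
    for c in case:
        for t in control:
            if c > t:
                wins += 1.0
            elif c == t:
                wins += 0.5
    return wins / (len(case) * len(control))


def wilcoxon_exact_brute(case, control):
    """Two-sided exact rank-sum p by enumerating all case-rank assignments."""
    pooled = list(case) + list(control)
    n1 = len(case)
    ranks = _average_ranks(pooled)
    observed = sum(ranks[:n1])
    stats = [
        sum(ranks[i] for i in combo)
        for combo in itertools.combinations(range(len(pooled)), n1)
    ]
    mean = sum(stats) / len(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(observed - mean) - 1e-12)
    return extreme / len(stats)


def _average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def summary_auc_brute(aucs, n_cases, n_controls):
    """DL pooling of logit AUCs with Hanley-McNeil variances, scalar arithmetic."""
    logits, variances = [], []
    for a, n1, n2 in zip(aucs, n_cases, n_controls):
        n = n1 + n2
        a = min(max(a, 1 / (4 * n)), 1 - 1 / (4 * n))
        q1 = a / (2 - a)
        q2 = 2 * a**2 / (1 + a)
        v = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n2 - 1) * (q2 - a**2)) / (n1 * n2)
        logits.append(math.log(a / (1 - a)))
        variances.append(v / (a * (1 - a)) ** 2)
    mu, se, _, _ = dl_pool_brute(logits, variances)
    expit = lambda z: 1 / (1 + math.exp(-z))
    return expit(mu), expit(mu - 1.96 * se), expit(mu + 1.96 * se)


def exhaustive_best_single_gene(cohorts_expr, case_masks, weights, genes, signs):
    """Best single-gene signature by trying every candidate exhaustively.

    cohorts_expr: list of {gene: per-sample np.array}; signs: {gene: +1/-1}.
    Returns (best objective, set of genes attaining it).
    """
    best = {}
    for g in genes:
        objs = []
        for expr, mask, w in zip(cohorts_expr, case_masks, weights):
            s = expr[g] * signs[g]
            objs.append((auc_brute(list(s[mask]), list(s[~mask])), w))
        obj = sum(a * w for a, w in objs) / sum(w for _, w in objs)
        best[g] = obj
    top = max(best.values())
    return top, {g for g, v in best.items() if abs(v - top) < 1e-12}
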