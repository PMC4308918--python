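"""Two-group differential abundance.

Per-feature Wilcoxon rank-sum tests with Benjamini-Hochberg correction and
fold-change calls on an MA parameterization (M = log ratio of group means,
A = mean average log expression).  Includes the one-vs-each pan-cancer
comparison used to define B-cell-enriched features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix


@dataclass
class DEResult:
    feature_id: str
    m_value: float  # log2 fold change, group A over group B
    a_value: float  # mean average log2 expression
    p_value: float
    q_value: float = np.nan
    call: str = "none"  # up / down / none


def wilcoxon_rank_sum(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test.

    Uses the exact null distribution for small tie-free samples
    (n_a + n_b <= 20), and the normal approximation with tie-corrected
    variance and continuity correction otherwise.  Returns (U statistic of
    group A, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * n / j, clipped at 1; input order preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def log2_fold_change(
    m: ExpressionMatrix,
    group_a,
    group_b,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-feature M (log2 ratio of group means) and A (mean average log2).

    M = log2((mean_a + c) / (mean_b + c));
    A = 0.5 * log2((mean_a + c) * (mean_b + c)), with pseudocount c.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    mean_a = m.values[group_a].mean(axis=1)
    mean_b = m.values[group_b].mean(axis=1)
    if pseudocount <= 0 and ((mean_a == 0).any() or (mean_b == 0).any()):
        raise ValueError("pseudocount <= 0 with zero group means")
    mm = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    aa = 0.5 * np.log2((mean_a + pseudocount) * (mean_b + pseudocount))
    return pd.DataFrame({"m_value": mm, "a_value": aa})


def differential_expression(
    m: ExpressionMatrix,
    group_a,
    group_b,
    pseudocount: float = 1.0,
    q_max: float = 0.05,
    abs_m_min: float = 2.0,
) -> list[DEResult]:
    """Full two-group screen: Wilcoxon per feature, BH across features,
    fold-change calls at (q < q_max, |M| > abs_m_min), strict inequalities."""
    group_a, group_b = list(group_a), list(group_b)
    ma = log2_fold_change(m, group_a, group_b, pseudocount)
    va = m.values[group_a].to_numpy()
    vb = m.values[group_b].to_numpy()
    pvals = np.array(
        [wilcoxon_rank_sum(va[i], vb[i])[1] for i in range(m.values.shape[0])]
    )
    results = [
        DEResult(fid, float(ma["m_value"].iloc[i]), float(ma["a_value"].iloc[i]), float(pvals[i]))
        for i, fid in enumerate(m.feature_ids)
    ]
    qvals = bh_adjust(pvals)
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    call_differential(results, q_max=q_max, abs_m_min=abs_m_min)
    return results


def call_differential(de: list[DEResult], q_max: float = 0.05, abs_m_min: float = 2.0) -> list[DEResult]:
    """Assign up/down/none calls in place: up iff q < q_max and M > abs_m_min;
    down iff q < q_max and M < -abs_m_min (strict inequalities)."""
    for r in de:
        if r.q_value < q_max and r.m_value > abs_m_min:
            r.call = "up"
        elif r.q_value < q_max and r.m_value < -abs_m_min:
            r.call = "down"
        else:
            r.call = "none"
    return de


def de_to_frame(de: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in de],
            "m_value": [r.m_value for r in de],
            "a_value": [r.a_value for r in de],
            "p_value": [r.p_value for r in de],
            "q_value": [r.q_value for r in de],
            "call": [r.call for r in de],
        }
    ).set_index("feature_id")


def bcell_enriched(
    bcell: ExpressionMatrix,
    others: list[tuple[str, ExpressionMatrix]],
    q_max: float = 0.05,
    abs_m_min: float = 3.0,
    pseudocount: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Features consistently enriched (or depleted) in the B-cell matrix
    relative to *each* comparison cancer type.

    A feature is enriched iff it is called up (q < q_max, M > abs_m_min) in
    every pairwise B-cell-vs-type comparison, with BH applied within each
    comparison across features; depleted symmetrically.
    """
    if not others:
        raise ValueError("at least one comparison matrix required")
    features = bcell.feature_ids
    for ctype, mat in others:
        missing = set(features) - set(mat.feature_ids)
        if missing:
            raise ValueError(f"features missing from {ctype}: {sorted(missing)[:5]}")
    enriched = set(features)
    depleted = set(features)
    for ctype, mat in others:
        combined = pd.concat([bcell.values, mat.values.loc[features]], axis=1)
        merged = ExpressionMatrix(values=combined, unit=bcell.unit)
        de = differential_expression(
            merged, bcell.sample_ids, mat.sample_ids,
            pseudocount=pseudocount, q_max=q_max, abs_m_min=abs_m_min,
        )
        up = {r.feature_id for r in de if r.call == "up"}
        down = {r.feature_id for r in de if r.call == "down"}
        enriched &= up
        depleted &= down
    return enriched, depleted
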