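"""Group-level inference: permutation tests, BH-FDR, link follow-ups,
inclusion-frequency chi-square tests and clinical correlations.

The primary comparison is a two-sided label-permutation test on the
difference of group means: labels are reshuffled (preserving group sizes)
either exhaustively, when the number of distinct assignments is small, or by
Monte-Carlo sampling, and the observed difference is ranked within the
resulting null distribution.  Nodal results are corrected with the
Benjamini-Hochberg step-up procedure across ROIs (one family per metric per
band); global results across the three global metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityMatrix
from .tree import SpanningTree, mst_membership

#: Exhaustive enumeration triggers when C(n_a + n_b, n_a) is at most this.
EXHAUSTIVE_LIMIT = 20_000
_TIE_TOL = 1e-12


@dataclass
class PermutationTestResult:
    metric_id: str
    observed_diff: float
    p_raw: float
    p_fdr: float
    n_permutations: int
    seed: int
    two_sided: bool = True
    exhaustive: bool = False


@dataclass
class InclusionFrequencyResult:
    link_id: str
    counts: np.ndarray  # 2x2: rows included/excluded, columns group A/B
    chi2: float
    p_raw: float
    p_fdr: float


@dataclass
class CorrelationResult:
    metric_id: str
    score_id: str
    r: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# core permutation engine
# ---------------------------------------------------------------------------

def _batch_perm_pvalues(
    values: np.ndarray, n_a: int, n_perm: int, seed: int
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Two-sided permutation p-values for many hypotheses sharing subjects.

    ``values`` is (n_hyp, n_subjects) with the first ``n_a`` columns in group
    A.  Returns (observed mean differences, p-values, draws used, exhaustive).

    The permutation null depends only on the pooled multiset of each row, so
    rows are sorted before reshuffling; this makes Monte-Carlo p-values
    invariant to the input ordering of subjects (including swapping the two
    group blocks when group sizes are equal).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    n_b = n - n_a
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    obs = values[:, :n_a].mean(axis=1) - values[:, n_a:].mean(axis=1)
    abs_obs = np.abs(obs)

    if math.comb(n, n_a) <= EXHAUSTIVE_LIMIT:
        idx_sets = np.array(list(combinations(range(n), n_a)))
        total = idx_sets.shape[0]
        a_means = values[:, idx_sets].mean(axis=2)  # (n_hyp, total)
        sums = values.sum(axis=1, keepdims=True)
        b_means = (sums - a_means * n_a) / n_b
        diffs = np.abs(a_means - b_means)
        b_counts = (diffs >= abs_obs[:, None] - _TIE_TOL).sum(axis=1)
        return obs, b_counts / total, total, True

    rng = np.random.default_rng(seed)
    pooled = np.sort(values, axis=1)
    b_counts = np.zeros(values.shape[0], dtype=int)
    chunk = max(1, min(n_perm, 50_000_000 // (values.shape[0] * n + 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(np.arange(n), (m, 1)), axis=1)
        a_idx = perms[:, :n_a]  # (m, n_a)
        a_means = pooled[:, a_idx].mean(axis=2)  # (n_hyp, m)
        sums = pooled.sum(axis=1, keepdims=True)
        b_means = (sums - a_means * n_a) / n_b
        diffs = np.abs(a_means - b_means)
        b_counts += (diffs >= abs_obs[:, None] - _TIE_TOL).sum(axis=1)
        done += m
    return obs, (b_counts + 1) / (n_perm + 1), n_perm, False


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    metric_id: str = "",
) -> PermutationTestResult:
    """Two-sided permutation test on the difference of group means.

    Exhaustive enumeration of all label assignments is used automatically
    when feasible; otherwise ``n_perm`` Monte-Carlo reshuffles with the
    conservative (b+1)/(n+1) p-value estimator.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("missing or non-finite values")
    values = np.concatenate([a, b])[None, :]
    obs, p, n_used, exhaustive = _batch_perm_pvalues(values, a.size, n_perm, seed)
    return PermutationTestResult(
        metric_id=metric_id,
        observed_diff=float(obs[0]),
        p_raw=float(p[0]),
        p_fdr=float(p[0]),
        n_permutations=n_used,
        seed=seed,
        exhaustive=exhaustive,
    )


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    adj = np.maximum(adj, p[order])  # guard the p_adj >= p bound against rounding
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# metric-table comparisons
# ---------------------------------------------------------------------------

GLOBAL_METRICS = ("leaf_fraction", "tree_hierarchy", "degree_divergence")
NODAL_METRICS = ("degree", "betweenness_centrality", "eccentricity")


def _pivot(table: pd.DataFrame, band: str, metric: str, node) -> tuple[np.ndarray, int, list]:
    """Per-hypothesis value rows ordered (group A subjects, group B subjects)."""
    sel = table[(table["band"] == band) & (table["metric"] == metric)]
    if node is not None:
        sel = sel[sel["node"] == node]
    piv = sel.pivot_table(index="node", columns=["group", "subject"], values="value")
    if piv.isna().any().any():
        raise ValueError(f"incomplete metric table for band={band!r} metric={metric!r}")
    groups = piv.columns.get_level_values(0)
    a_cols = piv.columns[groups == "A"]
    b_cols = piv.columns[groups == "B"]
    if len(a_cols) == 0 or len(b_cols) == 0:
        raise ValueError("both groups must be present")
    ordered = piv[list(a_cols) + list(b_cols)]
    return ordered.to_numpy(), len(a_cols), list(piv.index)


def compare_groups(
    table: pd.DataFrame,
    scope: str,
    band: str,
    metric: str | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[PermutationTestResult]:
    """Permutation tests per band: 3 global metrics (FDR across the 3) or one
    test per ROI for a nodal metric (FDR across all ROIs).  Results sorted by
    adjusted p-value."""
    if scope == "global":
        metrics = [metric] if metric else list(GLOBAL_METRICS)
        rows, ids = [], []
        n_a = None
        for m in metrics:
            vals, n_a, _nodes = _pivot(table, band, m, "global")
            rows.append(vals[0])
            ids.append(m)
        values = np.vstack(rows)
    elif scope == "nodal":
        if metric is None:
            raise ValueError("nodal scope requires a metric name")
        values, n_a, nodes = _pivot(table, band, metric, None)
        mask = [n != "global" for n in nodes]
        values = values[np.array(mask)]
        ids = [f"{metric}:{n}" for n, keep in zip(nodes, mask) if keep]
    else:
        raise ValueError(f"scope must be 'global' or 'nodal', got {scope!r}")

    obs, p_raw, n_used, exhaustive = _batch_perm_pvalues(values, n_a, n_perm, seed)
    p_adj = fdr_bh(p_raw)
    results = [
        PermutationTestResult(
            metric_id=mid,
            observed_diff=float(o),
            p_raw=float(pr),
            p_fdr=float(pf),
            n_permutations=n_used,
            seed=seed,
            exhaustive=exhaustive,
        )
        for mid, o, pr, pf in zip(ids, obs, p_raw, p_adj)
    ]
    return sorted(results, key=lambda r: (r.p_fdr, r.metric_id))


def compare_incident_links(
    matrices_a: list[ConnectivityMatrix],
    matrices_b: list[ConnectivityMatrix],
    node: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[PermutationTestResult]:
    """Permutation tests on the PLI of every link incident on ``node``
    (N-1 links), FDR-corrected across those links."""
    labels = matrices_a[0].roi_labels
    if node not in labels:
        raise ValueError(f"unknown node label {node!r}")
    v = labels.index(node)
    others = [k for k in range(len(labels)) if k != v]
    vals_a = np.array([[m.values[v, k] for m in matrices_a] for k in others])
    vals_b = np.array([[m.values[v, k] for m in matrices_b] for k in others])
    values = np.hstack([vals_a, vals_b])
    obs, p_raw, n_used, exhaustive = _batch_perm_pvalues(values, vals_a.shape[1], n_perm, seed)
    p_adj = fdr_bh(p_raw)
    results = [
        PermutationTestResult(
            metric_id=f"pli:{node}-{labels[k]}",
            observed_diff=float(o),
            p_raw=float(pr),
            p_fdr=float(pf),
            n_permutations=n_used,
            seed=seed,
            exhaustive=exhaustive,
        )
        for k, o, pr, pf in zip(others, obs, p_raw, p_adj)
    ]
    return sorted(results, key=lambda r: (r.p_fdr, r.metric_id))


def chi_square_2x2(counts: np.ndarray, continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square (1 df) for a 2x2 table; degenerate margins give
    (0, 1) by convention."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        return 0.0, 1.0
    res = stats.chi2_contingency(counts, correction=continuity)
    return float(res.statistic), float(res.pvalue)


def inclusion_frequency_test(
    trees_a: list[SpanningTree],
    trees_b: list[SpanningTree],
    node: str,
    continuity: bool = False,
) -> list[InclusionFrequencyResult]:
    """Chi-square comparison of how often each link incident on ``node`` is a
    member of subjects' MSTs, per group, FDR-corrected across links."""
    labels = trees_a[0].node_labels
    if node not in labels:
        raise ValueError(f"unknown node label {node!r}")
    v = labels.index(node)
    n = trees_a[0].n_nodes
    iu, ju = np.triu_indices(n, k=1)
    incident = [(k, int(iu[k]), int(ju[k])) for k in range(len(iu)) if v in (iu[k], ju[k])]
    memb_a = np.array([mst_membership(t) for t in trees_a])
    memb_b = np.array([mst_membership(t) for t in trees_b])
    results = []
    for k, i, j in incident:
        inc_a, inc_b = int(memb_a[:, k].sum()), int(memb_b[:, k].sum())
        counts = np.array(
            [[inc_a, inc_b], [len(trees_a) - inc_a, len(trees_b) - inc_b]], dtype=float
        )
        chi2, p = chi_square_2x2(counts, continuity=continuity)
        other = labels[j] if i == v else labels[i]
        results.append(
            InclusionFrequencyResult(f"mst:{node}-{other}", counts, chi2, p, np.nan)
        )
    p_adj = fdr_bh([r.p_raw for r in results])
    for r, pf in zip(results, p_adj):
        r.p_fdr = float(pf)
    return sorted(results, key=lambda r: (r.p_fdr, r.link_id))


def pearson_correlation(
    x, y, metric_id: str = "", score_id: str = ""
) -> CorrelationResult:
    """Sample Pearson r with the two-sided t-distribution p (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(metric_id, score_id, float(res.statistic), float(res.pvalue), x.size)


def welch_t_test(values_a, values_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.std(a) == 0 and np.std(b) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
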