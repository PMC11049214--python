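"""Small-sample nonparametric group comparisons and per-group summaries.

With 3–5 replicate spectra per variant, the Mann–Whitney U test is the
appropriate two-sample comparison; at these sizes the exact null distribution
of U — obtained by enumerating every assignment of ranks to the two groups —
is used rather than the normal approximation.  Comparison results carry the
figure-annotation markers used in this field: ``#``/``##`` for a mutant
against the wild-type reference (p < 0.05 / p < 0.01) and ``*``/``**`` for
mutant-vs-mutant pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "mann_whitney_exact",
    "compare_all",
    "summarize",
]

#: total sample size up to which the exact enumeration is used (tie-free data)
EXACT_LIMIT = 16


@lru_cache(maxsize=64)
def _exact_u_counts(n: int, m: int) -> tuple[np.ndarray, int]:
    """Null distribution of U_x by full enumeration.

    Enumerates all C(n+m, n) ways of assigning the ranks 1..n+m to the first
    sample and counts the resulting U_x values.  Returns (counts over
    U = 0..n*m, total number of arrangements).
    """
    total_ranks = range(1, n + m + 1)
    offset = n * (n + 1) // 2
    counts = np.zeros(n * m + 1, dtype=np.int64)
    n_arr = 0
    for ranks in combinations(total_ranks, n):
        u = sum(ranks) - offset
        counts[u] += 1
        n_arr += 1
    return counts, n_arr


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test, exact for small tie-free samples.

    Returns ``(U_x, p)`` where ``U_x`` is the rank-sum statistic of the first
    sample (``0 ≤ U_x ≤ n_x·n_y``; with ties it may be half-integer).  When
    ``n_x + n_y ≤ 16`` and the pooled data contain no ties, the p-value is
    exact: ``2 · min(P(U ≤ u), P(U ≥ u))`` under the enumerated null, capped
    at 1.  Otherwise the normal approximation with tie and continuity
    corrections is used; fully degenerate data (every pooled value equal)
    give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2)
    has_ties = np.unique(pooled).size < pooled.size

    if n + m <= EXACT_LIMIT and not has_ties:
        counts, total = _exact_u_counts(n, m)
        u_int = int(round(u_x))
        cdf = counts[: u_int + 1].sum() / total
        sf = counts[u_int:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return u_x, float(p)

    # normal approximation with tie correction and continuity correction
    N = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))) if N > 1 else 0.0
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return u_x, 1.0
    z = (abs(u_x - n * m / 2.0) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    return u_x, float(min(1.0, 2.0 * norm.sf(z)))


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group comparison of one metric."""

    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    marker: str  # "ns", "#", "##" (vs reference), "*", "**" (pairwise)
    vs_reference: bool
    p_holm: float | None = None


def _marker(p: float, vs_reference: bool) -> str:
    if p < 0.01:
        return "##" if vs_reference else "**"
    if p < 0.05:
        return "#" if vs_reference else "*"
    return "ns"


def compare_all(
    metrics_table: pd.DataFrame,
    reference: str = "WT",
    holm: bool = False,
) -> list[ComparisonResult]:
    """Every mutant-vs-reference and mutant-vs-mutant comparison per metric.

    ``metrics_table`` is tidy with at least columns ``variant``, ``metric``,
    ``value`` (replicates as rows).  Raw per-comparison p-values are reported;
    ``holm=True`` additionally fills ``p_holm`` (Holm step-down within each
    metric family).
    """
    if "variant" not in metrics_table or "metric" not in metrics_table or "value" not in metrics_table:
        raise ValueError("metrics_table needs columns variant, metric, value")
    variants = list(dict.fromkeys(metrics_table["variant"]))
    if reference not in variants:
        raise ValueError(f"reference variant {reference!r} absent from table")
    mutants = [v for v in variants if v != reference]
    results: list[ComparisonResult] = []
    for metric, sub in metrics_table.groupby("metric", sort=False):
        groups = {v: g["value"].to_numpy(dtype=float) for v, g in sub.groupby("variant", sort=False)}
        pairs = [(m, reference, True) for m in mutants if m in groups]
        pairs += [(a, b, False) for a, b in combinations([m for m in mutants if m in groups], 2)]
        metric_results = []
        for a, b, vs_ref in pairs:
            u, p = mann_whitney_exact(groups[a], groups[b])
            metric_results.append(
                ComparisonResult(
                    metric=str(metric),
                    group_a=a,
                    group_b=b,
                    n_a=len(groups[a]),
                    n_b=len(groups[b]),
                    u_statistic=u,
                    p_value=p,
                    marker=_marker(p, vs_ref),
                    vs_reference=vs_ref,
                )
            )
        if holm and metric_results:
            adj = multipletests([r.p_value for r in metric_results], method="holm")[1]
            metric_results = [
                ComparisonResult(**{**r.__dict__, "p_holm": float(q)})
                for r, q in zip(metric_results, adj)
            ]
        results.extend(metric_results)
    return results


def comparisons_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tabulate comparison results for export."""
    return pd.DataFrame([r.__dict__ for r in results])


def summarize(metrics_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(variant, metric) mean, standard error of the mean, and n.

    SEM is the sample standard deviation (ddof = 1) over √n; undefined for a
    single replicate and reported as missing.
    """
    def _agg(g: pd.Series) -> pd.Series:
        vals = g.to_numpy(dtype=float)
        n = vals.size
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        return pd.Series({"mean": float(vals.mean()), "sem": sem, "n": n})

    out = (
        metrics_table.groupby(["variant", "metric"], sort=False)["value"]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
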