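"""Paired cohort comparison of planning strategies.

Reproduces the comparison-table machinery used to validate automated
planning: per metric and strategy pair, the mean paired difference with one
sample SD, the mean relative percentage difference, win counts, and a
paired two-sided Wilcoxon signed-rank p-value (exact null enumeration for
small samples, normal approximation with tie correction above).

Conventions:
* ``compare_pair(a, b)``: dmean = mean(a - b); positive dmean means the
  second cohort is superior (lower values). The win tuple is
  ``(count b < a, count a < b)`` — first element counts plans where the
  second cohort is strictly lower; ties are counted separately, not split.
* Zero paired differences are removed before ranking; if all differences
  are zero the p-value is 1.0 by convention.
* No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .evaluate import PlanMetrics

__all__ = ["ComparisonReport", "paired_wilcoxon", "compare_pair", "comparison_table"]

#: largest sample (after zero removal) for which the exact null is enumerated
EXACT_N_MAX = 25

ALPHA = 0.05


def paired_wilcoxon(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Exact for n <= 25 after zero-difference removal: the null distribution
    of the positive-rank sum W+ over all 2^n sign assignments (mid-ranks for
    tied magnitudes) is built by convolution, and the two-sided p-value is
    P(|W+ - n(n+1)/4| >= |w_obs - n(n+1)/4|) — the null is symmetric about
    its mean even under ties. Above 25, a normal approximation with tie
    correction is used. Returns p in (0, 1].
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("need at least one pair")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))           # mid-ranks
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0

    if n <= EXACT_N_MAX:
        # doubled ranks are integers even with mid-rank ties
        r2 = np.round(2.0 * ranks).astype(np.int64)
        total = int(r2.sum())
        # distribution of 2*W+ over sign assignments, by convolution
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = dist + shifted
        dist /= 2.0 ** n
        support = np.arange(total + 1)
        dev = np.abs(support - 2.0 * mu)
        obs_dev = abs(2.0 * w_plus - 2.0 * mu)
        p = float(dist[dev >= obs_dev - 1e-9].sum())
        return min(max(p, np.nextafter(0, 1)), 1.0)

    # normal approximation with tie correction (no continuity correction)
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return 1.0
    z = (w_plus - mu) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def _values(metrics: list[PlanMetrics] | np.ndarray, metric: str | None) -> np.ndarray:
    seq = list(metrics) if not isinstance(metrics, np.ndarray) else metrics
    if metric is not None and len(seq) and hasattr(seq[0], "get"):
        return np.array([m.get(metric) for m in seq], dtype=float)
    return np.asarray(metrics, dtype=float)


def compare_pair(metrics_a, metrics_b, metric: str | None = None) -> pd.Series:
    """One report row for a paired strategy comparison on a single metric.

    Accepts lists of :class:`PlanMetrics` plus a metric id, or two plain
    numeric arrays. Returns dmean (mean(a-b)), sample SD, percentage
    difference (100 * dmean / mean(a)), win counts, ties and the p-value.
    """
    a = _values(metrics_a, metric)
    b = _values(metrics_b, metric)
    if a.size == 0 or b.size == 0:
        raise ValueError("cohorts must be nonempty")
    if a.size != b.size:
        raise ValueError(f"cohort sizes differ: {a.size} vs {b.size}")
    diff = a - b
    dmean = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    mean_a = float(a.mean())
    pct = 100.0 * dmean / mean_a if mean_a != 0 else np.nan
    p = paired_wilcoxon(a, b)
    return pd.Series({
        "metric": metric,
        "dmean": dmean,
        "sd": sd,
        "pct_diff": pct,
        "wins_second": int(np.sum(b < a)),
        "wins_first": int(np.sum(a < b)),
        "ties": int(np.sum(a == b)),
        "p_value": p,
        "significant": bool(p < ALPHA),
        "n": int(a.size),
    })


@dataclass
class ComparisonReport:
    """All pairwise strategy comparisons over a set of metrics."""

    strategies: list[str]
    metrics: list[str]
    table: pd.DataFrame     # long form: one row per (pair, metric)

    def row(self, first: str, second: str, metric: str) -> pd.Series:
        t = self.table
        sel = (t["first"] == first) & (t["second"] == second) & (t["metric"] == metric)
        if not sel.any():
            sel = (t["first"] == second) & (t["second"] == first) & (t["metric"] == metric)
            if not sel.any():
                raise KeyError(f"no comparison for ({first}, {second}, {metric})")
            r = t[sel].iloc[0].copy()
            r["first"], r["second"] = first, second
            r["dmean"] = -r["dmean"]
            r["pct_diff"] = np.nan
            r["wins_first"], r["wins_second"] = r["wins_second"], r["wins_first"]
            return r
        return t[sel].iloc[0]

    def render(self) -> str:
        """Text rendering in the classic matrix layout: mean differences
        (dmean ± SD, percentage) below the diagonal, p-values and win counts
        above. Win counts (n|m): n plans where the row strategy is lower."""
        lines = []
        for metric in self.metrics:
            lines.append(f"== {metric} ==")
            header = "".join(f"{s:>26}" for s in self.strategies)
            lines.append(" " * 12 + header)
            for i, si in enumerate(self.strategies):
                cells = []
                for j, sj in enumerate(self.strategies):
                    if i == j:
                        cells.append(f"{'-':>26}")
                        continue
                    r = self.row(si, sj, metric)
                    if i > j:
                        cells.append(f"{r['dmean']:+.2f}±{r['sd']:.2f}".rjust(26))
                    else:
                        p = r["p_value"]
                        ptxt = "NS" if p >= ALPHA else (f"{p:.3f}" if p >= 0.001 else "<0.001")
                        wins = f"({int(r['wins_first']):02d}|{int(r['wins_second']):02d})"
                        cells.append(f"{ptxt} {wins}".rjust(26))
                lines.append(f"{si:>12}" + "".join(cells))
            lines.append("")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def comparison_table(cohorts: dict[str, list[PlanMetrics]],
                     metrics: list[str]) -> ComparisonReport:
    """All unordered strategy pairs x metrics, in deterministic order.

    ``cohorts`` maps strategy name to its list of evaluated plans; cohort
    sizes must match (the comparisons are paired).
    """
    names = list(cohorts)
    if len(names) < 2:
        raise ValueError("need at least 2 strategies")
    sizes = {name: len(v) for name, v in cohorts.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"cohort sizes differ: {sizes}")
    rows = []
    for first, second in combinations(names, 2):
        for metric in metrics:
            r = compare_pair(cohorts[first], cohorts[second], metric)
            r["first"], r["second"] = first, second
            rows.append(r)
    table = pd.DataFrame(rows).reset_index(drop=True)
    cols = ["first", "second", "metric", "dmean", "sd", "pct_diff",
            "wins_second", "wins_first", "ties", "p_value", "significant", "n"]
    return ComparisonReport(strategies=names, metrics=list(metrics), table=table[cols])
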