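"""Nonparametric dose-response statistics.

The statistical layer of the readouts: Kruskal–Wallis across >=3 groups
with Dunn's pairwise post hoc on the pooled mid-ranks, Mann–Whitney for two
groups, and the two summary modes used for reporting (mean ± SEM over FoVs;
median with 1st/3rd quartiles over nuclei).  Significance stars follow the
usual convention (* <0.05, ** <0.01, *** <0.001, **** <0.0001).

Kruskal–Wallis uses the tie-corrected H with a chi-square reference
regardless of group size (as standard packages do; small groups are
flagged).  Dunn's z for pair (i, j) is

    z = (R̄_i - R̄_j) / sqrt[(N(N+1)/12 - ΣT/(12(N-1))) (1/n_i + 1/n_j)]

with T = t³ - t summed over tied values, two-sided normal p, and
Bonferroni-style adjustment (Holm available).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    for cut, stars in STAR_LEVELS:
        if p < cut:
            return stars
    return "ns"


@dataclass
class StatResult:
    """One hypothesis test outcome."""

    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    adjustment: str | None = None
    n_per_group: tuple[int, ...] = ()
    flags: tuple[str, ...] = ()

    @property
    def stars(self) -> str:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return significance_stars(p)

    def as_row(self) -> dict:
        return {
            "test": self.test, "groups": " vs ".join(self.groups),
            "statistic": self.statistic, "p_value": self.p_value,
            "p_adjusted": self.p_adjusted, "adjustment": self.adjustment,
            "n_per_group": ";".join(map(str, self.n_per_group)),
            "stars": self.stars, "flags": ";".join(self.flags),
        }


def _as_groups(groups: Sequence[Sequence[float]], labels=None):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 1 for a in arrays):
        raise ValueError("each group needs at least one value")
    if sum(len(a) for a in arrays) < 3:
        raise ValueError("need at least three values in total")
    labels = tuple(labels) if labels else tuple(f"g{i+1}" for i in range(len(arrays)))
    return arrays, labels


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   labels: Sequence[str] | None = None) -> StatResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p (k-1 df).

    All-identical data (tie correction degenerate) is reported as H = 0,
    p = 1 with a flag rather than an error.
    """
    arrays, labels = _as_groups(groups, labels)
    pooled = np.concatenate(arrays)
    flags = tuple(f for f in ["small-group"] if any(len(a) < 5 for a in arrays))
    if np.ptp(pooled) == 0:
        return StatResult("kruskal-wallis", labels, 0.0, 1.0,
                          n_per_group=tuple(map(len, arrays)),
                          flags=flags + ("degenerate-all-ties",))
    h, p = sps.kruskal(*arrays)
    return StatResult("kruskal-wallis", labels, float(h), float(p),
                      n_per_group=tuple(map(len, arrays)), flags=flags)


def dunns_posthoc(
    groups: Sequence[Sequence[float]],
    comparisons: Sequence[tuple[int, int]] | None = None,
    adjustment: str = "bonferroni",
    labels: Sequence[str] | None = None,
) -> list[StatResult]:
    """Dunn's pairwise comparisons on the pooled mid-ranks.

    ``comparisons`` lists 0-based group-index pairs (default: all pairs).
    Adjusted p is min(1, m·p) for Bonferroni or the Holm step-down variant.
    """
    arrays, labels = _as_groups(groups, labels)
    if adjustment not in ("bonferroni", "holm"):
        raise ValueError("adjustment must be 'bonferroni' or 'holm'")
    if comparisons is None:
        comparisons = list(itertools.combinations(range(len(arrays)), 2))
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    degenerate = np.ptp(pooled) == 0
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(float(ranks[start:start + len(a)].mean()))
        start += len(a)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    results: list[StatResult] = []
    raw = []
    for (i, j) in comparisons:
        ni, nj = len(arrays[i]), len(arrays[j])
        if i == j or degenerate or var_base <= 0:
            z, p = 0.0, 1.0
        else:
            se = np.sqrt(var_base * (1.0 / ni + 1.0 / nj))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = float(2.0 * sps.norm.sf(abs(z)))
        raw.append((z, p, (labels[i], labels[j]), (ni, nj)))
    m = len(raw)
    if adjustment == "bonferroni":
        adj = [min(1.0, m * p) for _, p, _, _ in raw]
    else:  # holm step-down
        order = np.argsort([p for _, p, _, _ in raw])
        adj = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw[idx][1])
            adj[idx] = min(1.0, running)
    for (z, p, pair, ns), pa in zip(raw, adj):
        flags = ("degenerate-all-ties",) if degenerate else ()
        results.append(StatResult("dunn", pair, float(z), p, pa, adjustment,
                                  ns, flags))
    return results


def mann_whitney(group1: Sequence[float], group2: Sequence[float],
                 labels: Sequence[str] | None = None,
                 method: str = "auto") -> StatResult:
    """Two-sided Mann–Whitney U (U of the first group reported).

    Exact p by enumeration for n1+n2 <= 20 without ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 1 or len(g2) < 1:
        raise ValueError("both groups need at least one value")
    labels = tuple(labels) if labels else ("g1", "g2")
    pooled = np.concatenate([g1, g2])
    ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(g1, g2, alternative="two-sided", method=method,
                           use_continuity=True)
    flags = ("ties",) if ties else ()
    return StatResult("mann-whitney", labels, float(res.statistic),
                      float(res.pvalue), n_per_group=(len(g1), len(g2)),
                      flags=flags + (f"method-{method}",))


def summarize_distribution(values: Sequence[float], mode: str = "quartiles"
                           ) -> dict:
    """Summary in the two reporting modes.

    ``quartiles``: median with 1st/3rd quartiles by linear-interpolation
    order statistics (the type-7 convention).  ``sem``: mean with sd/sqrt(n)
    (ddof=1; a single value reports SEM 0 with a flag).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 1:
        raise ValueError("need at least one value")
    if mode == "quartiles":
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3),
                "n": len(v)}
    if mode == "sem":
        sem = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        return {"mean": float(np.mean(v)), "sem": sem, "n": len(v),
                **({"flags": "n=1"} if len(v) == 1 else {})}
    raise ValueError("mode must be 'quartiles' or 'sem'")
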