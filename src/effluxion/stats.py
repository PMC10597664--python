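"""Nonparametric group comparisons: Mann-Whitney U, Kruskal-Wallis, Dunn's.

Matches the usual pharmacology-report conventions: exact two-sided
Mann-Whitney p-values by full enumeration for small untied samples and a
tie-corrected normal approximation otherwise; tie-corrected Kruskal-Wallis H
against chi-squared; Dunn's post hoc z from pooled-rank mean differences with
a configurable comparison family and multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "PairwiseResult",
    "mann_whitney",
    "kruskal_wallis",
    "dunns",
]

EXACT_MAX_N = 14  # combined sample size up to which the exact MW p is used


class StatsError(ValueError):
    pass


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float


@dataclass
class ComparisonResult:
    statistic: float  # U or H
    p_value: float
    method: str
    notes: str = ""
    pairwise: list[PairwiseResult] = field(default_factory=list)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    ``mode='auto'`` uses the exact enumeration distribution when the combined
    sample size is <= 14 and there are no ties, and the tie-corrected normal
    approximation (with continuity correction) otherwise; ``'exact'`` and
    ``'asymptotic'`` force either route.  Completely degenerate input (every
    value identical in both samples) returns p = 1 with a note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return ComparisonResult(
            statistic=x.size * y.size / 2.0, p_value=1.0,
            method="degenerate", notes="all values identical; no separation",
        )
    has_ties = np.unique(combined).size < combined.size
    if mode == "auto":
        use_exact = (x.size + y.size <= EXACT_MAX_N) and not has_ties
    elif mode == "exact":
        use_exact = True
    elif mode == "asymptotic":
        use_exact = False
    else:
        raise StatsError(f"unknown mode {mode!r}")
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    notes = "tie-corrected normal approximation" if not use_exact else "full enumeration"
    if has_ties and use_exact:
        notes = "exact method forced despite ties"
    return ComparisonResult(float(res.statistic), float(res.pvalue), method, notes)


def kruskal_wallis(groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None) -> ComparisonResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared p (k-1 df).

    A two-group input is redirected to :func:`mann_whitney` with a note.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise StatsError("all groups must be non-empty")
    if len(arrays) < 2:
        raise StatsError("need at least two groups")
    if len(arrays) == 2:
        res = mann_whitney(arrays[0], arrays[1])
        res.notes = ("two groups: redirected to Mann-Whitney U; " + res.notes).strip()
        return res
    combined = np.concatenate(arrays)
    if np.all(combined == combined[0]):
        return ComparisonResult(0.0, 1.0, "kruskal-wallis", "all values identical")
    h, p = sps.kruskal(*arrays)
    return ComparisonResult(float(h), float(p), "kruskal-wallis", "tie-corrected H")


def _adjust(p_raw: np.ndarray, method: str) -> np.ndarray:
    m = p_raw.size
    if method == "bonferroni":
        return np.minimum(p_raw * m, 1.0)
    if method == "holm":
        order = np.argsort(p_raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adj[idx] = min(running, 1.0)
        return adj
    if method == "none":
        return p_raw.copy()
    raise StatsError(f"unknown adjustment {method!r}")


def dunns(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    comparisons: str | Sequence[tuple[str, str]] = "control",
    adjustment: str = "bonferroni",
) -> list[PairwiseResult]:
    """Dunn's multiple-comparison z tests on pooled ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12 (N - 1)).  ``comparisons`` is either
    ``"control"`` (each group vs the first label, the k-1 family used for
    concentration series vs solvent), ``"all"`` (all pairs), or an explicit
    list of label pairs.  Raw two-sided normal p-values are adjusted over the
    declared family (Bonferroni default; Holm and none available).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise StatsError("all groups must be non-empty")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    labels = list(map(str, labels))
    if len(labels) != len(arrays):
        raise StatsError("labels must match groups")
    index = {lab: i for i, lab in enumerate(labels)}

    pooled = np.concatenate(arrays)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = np.array([a.size for a in arrays])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))]
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    if comparisons == "all":
        pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    elif comparisons == "control":
        pairs = [(labels[0], lab) for lab in labels[1:]]
    else:
        pairs = list(comparisons)

    zs, ps = [], []
    for a, b in pairs:
        if a not in index or b not in index:
            raise StatsError(f"comparison involves unknown group {a!r} or {b!r}")
        i, j = index[a], index[b]
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))
    adj = _adjust(np.asarray(ps), adjustment)
    return [
        PairwiseResult(a, b, float(z), float(p), float(pa))
        for (a, b), z, p, pa in zip(pairs, zs, ps, adj)
    ]
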