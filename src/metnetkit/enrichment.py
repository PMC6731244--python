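"""Pathway over-representation analysis and PCA-loading quartile selection."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pathway_db import Pathway

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "enrich_pathways",
    "select_loading_quartiles",
]


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    k: int  # overlap: selected ∩ pathway (within universe)
    K: int  # pathway size within universe
    n: int  # selected-set size within universe
    N: int  # universe size
    p_value: float
    q_value: float


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K marked, n drawn).

    Computed as an exact sum of probability masses accumulated in log
    space (log-sum-exp), so tiny tails keep full relative precision.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError(f"K ({K}) and n ({n}) must not exceed N ({N})")
    if k > min(n, K):
        raise ValueError(f"k ({k}) exceeds min(n, K) = {min(n, K)}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    logpmf = stats.hypergeom.logpmf(support, N, K, n)
    total = float(np.exp(logpmf - logpmf.max()).sum())
    return float(min(1.0, np.exp(logpmf.max()) * total))


def enrich_pathways(
    selected: Iterable[str],
    pathways: Sequence[Pathway] | Mapping[str, Sequence[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """One-sided over-representation test of *selected* in each pathway.

    Pathway memberships are intersected with *universe* before counting;
    pathways empty within the universe are dropped.  q-values are
    Benjamini-Hochberg across the tested pathways.  Output is sorted by
    (p, pathway_id) and invariant to input ordering.
    """
    universe_set = frozenset(universe)
    selected_set = frozenset(selected)
    if not universe_set:
        raise ValueError("universe must be non-empty")
    if not selected_set:
        raise ValueError("selected set must be non-empty")
    if not selected_set <= universe_set:
        extra = sorted(selected_set - universe_set)
        raise ValueError(f"selected ids outside universe: {extra[:5]}")

    if isinstance(pathways, Mapping):
        membership = {pid: frozenset(m) for pid, m in pathways.items()}
    else:
        membership = {p.id: frozenset(p.compound_ids) for p in pathways}

    N = len(universe_set)
    n = len(selected_set)
    rows: list[tuple[str, int, int, float]] = []
    for pid in sorted(membership):
        members = membership[pid] & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected_set)
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append((pid, k, K, p))
    if not rows:
        return []
    pvals = np.array([r[3] for r in rows])
    q = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(pid, k, K, n, N, p, max(p, float(qv)))
        for (pid, k, K, p), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def select_loading_quartiles(
    loadings: Mapping[str, float]
) -> tuple[set[str], set[str]]:
    """Split compounds into top (>= 75th pct) and bottom (<= 25th pct) sets.

    Percentiles use linear interpolation.  Requires >= 4 finite loadings
    and distinct quartile thresholds, otherwise the split is undefined.
    """
    finite = {c: float(v) for c, v in loadings.items() if np.isfinite(v)}
    if len(finite) < 4:
        raise ValueError("need at least 4 compounds with finite loadings")
    values = np.array(list(finite.values()))
    lo, hi = np.percentile(values, [25.0, 75.0])
    if lo == hi:
        raise ValueError("quartile thresholds coincide; quartiles undefined")
    top = {c for c, v in finite.items() if v >= hi}
    bottom = {c for c, v in finite.items() if v <= lo}
    assert not top & bottom
    return top, bottom
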