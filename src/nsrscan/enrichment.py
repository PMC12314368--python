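"""Exact hypergeometric enrichment/depletion with Benjamini-Hochberg FDR.

Tail probabilities are exact sums of hypergeometric log-probabilities
(logsumexp), so extreme depletions/enrichments keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    feature_id: Hashable
    k: int  # feature members in nSR
    n: int  # feature members total
    K: int  # all items in nSR
    N: int  # all items
    p_enrich: float
    p_deplete: float
    q: float
    tail: str


def hypergeom_tail(k: int, n: int, K: int, N: int, tail: str = "upper") -> float:
    """Exact tail probability for drawing ``k`` marked items in a sample.

    Parameterisation: ``N`` items total, ``K`` marked (e.g. in nSR), a
    sample of size ``n`` (the feature's members); ``X`` = marked items in
    the sample.  lower = P(X <= k), upper = P(X >= k).
    """
    if not (0 <= k <= n <= N) or not (0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k > K:
        raise ValueError(f"k={k} exceeds K={K}")
    if tail not in ("upper", "lower"):
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    lo = max(0, n + K - N)
    hi = min(n, K)
    if tail == "lower":
        ks = np.arange(lo, min(k, hi) + 1)
    else:
        ks = np.arange(max(k, lo), hi + 1)
    if ks.size == 0:
        return 0.0
    logp = hypergeom.logpmf(ks, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def enrich_features(
    feature_map: Mapping[Hashable, Iterable[Hashable]],
    in_nsr: Mapping[Hashable, bool],
    tail: str = "upper",
    alpha: float = 0.05,
    min_count: int = 5,
) -> list[EnrichmentResult]:
    """One exact test per feature, BH-adjusted within the tested family.

    ``feature_map`` maps item -> feature(s) (a single feature or an
    iterable); an item counts once per distinct feature.  Every item must
    appear in ``in_nsr``.  Features with fewer than ``min_count`` members
    are not tested.  Results are sorted by (q, p, feature).
    """
    if tail not in ("upper", "lower"):
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    items = list(feature_map.keys())
    missing = [i for i in items if i not in in_nsr]
    if missing:
        raise ValueError(f"items without nSR flag: {missing[:5]}")
    N = len(items)
    K = sum(1 for i in items if in_nsr[i])
    members: dict[Hashable, set] = {}
    for item, feats in feature_map.items():
        if isinstance(feats, (str, bytes)) or not isinstance(feats, Iterable):
            feats = [feats]
        for f in set(feats):
            members.setdefault(f, set()).add(item)
    tested = {f: mem for f, mem in members.items() if len(mem) >= min_count}
    if not tested:
        return []
    rows = []
    for f, mem in sorted(tested.items(), key=lambda kv: str(kv[0])):
        n = len(mem)
        k = sum(1 for i in mem if in_nsr[i])
        p_up = hypergeom_tail(k, n, K, N, "upper")
        p_lo = hypergeom_tail(k, n, K, N, "lower")
        rows.append((f, k, n, p_up, p_lo))
    primary = [r[3] if tail == "upper" else r[4] for r in rows]
    qs = bh_adjust(primary)
    results = [
        EnrichmentResult(f, k, n, K, N, p_up, p_lo, q, tail)
        for (f, k, n, p_up, p_lo), q in zip(rows, qs)
    ]
    results.sort(key=lambda r: (r.q, r.p_enrich if tail == "upper" else r.p_deplete, str(r.feature_id)))
    return results
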