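"""Set-overlap enrichment and GO over-representation statistics.

The overlap between a query protein list and a curated set, both drawn from
a background universe of size N, follows a hypergeometric distribution under
the null of independent membership. The one-sided Fisher's exact test on the
2x2 contingency table (the GeneOverlap convention) is identical to the
hypergeometric upper tail, which is what :func:`hypergeom_upper` computes.
Over-representation analysis (ORA) runs that same test per annotation term
and controls the FDR across terms with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables_io import ProteinKey  # noqa: F401  (typed set elements)

__all__ = [
    "OverlapResult",
    "OraResult",
    "hypergeom_upper",
    "overlap_test",
    "run_ora",
    "bh_adjust",
    "scan_universe",
]


@dataclass
class OverlapResult:
    """One-sided 2x2 set-overlap test (counts, odds ratio, upper-tail p)."""

    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    odds_ratio: float
    p: float
    dropped_a: int = 0
    dropped_b: int = 0


@dataclass
class OraResult:
    term_id: str
    term_name: str
    k: int  # query hits in term
    K: int  # term size in universe
    n: int  # query size
    N: int  # universe size
    fold_enrichment: float
    p: float
    q: float = field(default=float("nan"))


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Probability of drawing at least ``k`` members of a ``K``-sized class when
    sampling ``n`` items without replacement from a universe of ``N``.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"impossible table: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    # Haldane 0.5 correction only when some cell is zero
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def overlap_test(set_a: set, set_b: set, universe: set) -> OverlapResult:
    """Enrichment test of two sets against a common universe.

    Elements outside the universe are dropped with their counts recorded on
    the result; p is the hypergeometric upper tail of the observed overlap.
    """
    if not universe:
        raise ValueError("empty universe")
    a = set_a & universe
    b = set_b & universe
    overlap = len(a & b)
    N, nA, nB = len(universe), len(a), len(b)
    p = hypergeom_upper(overlap, nB, nA, N)
    orr = _odds_ratio(overlap, nA - overlap, nB - overlap, N - nA - nB + overlap)
    return OverlapResult(
        n_universe=N,
        n_set_a=nA,
        n_set_b=nB,
        n_overlap=overlap,
        odds_ratio=orr,
        p=p,
        dropped_a=len(set_a) - nA,
        dropped_b=len(set_b) - nB,
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, preserving input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def run_ora(
    query_set: set,
    annotation: Mapping[str, set],
    universe: set,
    q_threshold: float = 0.05,
    top: int | None = None,
    min_hits: int = 1,
    term_names: Mapping[str, str] | None = None,
) -> list[OraResult]:
    """GO-style over-representation analysis of a query against term sets.

    Terms are restricted to the universe; terms with fewer than ``min_hits``
    query hits are excluded before BH adjustment. Results are filtered at
    ``q < q_threshold``, sorted by q then descending fold enrichment, and
    optionally truncated to the ``top`` best terms.
    """
    if not universe:
        raise ValueError("empty universe")
    query = query_set & universe
    if not query:
        raise ValueError("query outside background")
    n, N = len(query), len(universe)
    results: list[OraResult] = []
    for term, members in annotation.items():
        members = members & universe
        k = len(query & members)
        K = len(members)
        if k < max(min_hits, 1) or K == 0:
            continue
        results.append(
            OraResult(
                term_id=term,
                term_name=(term_names or {}).get(term, term),
                k=k,
                K=K,
                n=n,
                N=N,
                fold_enrichment=(k / n) / (K / N),
                p=hypergeom_upper(k, K, n, N),
            )
        )
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = q
    kept = [r for r in results if r.q < q_threshold]
    kept.sort(key=lambda r: (r.q, -r.fold_enrichment))
    return kept[:top] if top is not None else kept


def scan_universe(
    n_overlap: int,
    n_set_a: int,
    n_set_b: int,
    candidates: Iterable[int],
    target_p: float,
) -> list[tuple[int, float]]:
    """Which background size reproduces a published overlap p-value?

    Published overlap tests often omit the universe they used. Given the
    observed counts and a target p, this scans candidate universe sizes and
    returns ``(N, p)`` pairs sorted by closeness to the target on the log10
    scale (best first).
    """
    out = []
    for N in candidates:
        p = hypergeom_upper(n_overlap, n_set_b, n_set_a, N)
        out.append((N, p))
    out.sort(key=lambda t: abs(np.log10(t[1]) - np.log10(target_p)))
    return out
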