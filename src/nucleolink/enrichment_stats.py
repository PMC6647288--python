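"""Overlap-enrichment statistics for gene sets and region sets.

The central quantity is the observed/expected ratio of an overlap between a
query set (size ``n``) and a category (size ``K``) drawn from a universe of
size ``N``: ``obs_exp = k / (n * K / N)``, with an upper-tail hypergeometric
p-value ``P(X >= k)`` for enrichment and the lower tail ``P(X <= k)`` for
depletion.  The universe size is always an explicit argument, never
inferred, since it fixes the expectation of every test.

Also provides the 2x2 chi-square used to compare altered-nucleosome
proportions between genotypes, and per-region-class enrichment of altered
nucleosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "hypergeometric_overlap",
    "depletion_pvalue",
    "enrichment_matrix",
    "chi_square_two_proportions",
    "region_alteration_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """A single overlap test: universe N, category K, query n, overlap k."""

    N: int
    K: int
    n: int
    k: int
    obs_exp: float
    pvalue: float  # upper tail, P(X >= k)

    @property
    def expected(self) -> float:
        return self.n * self.K / self.N


def _check_bounds(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N; got N={N} K={K} n={n}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"require 0 <= k <= min(n, K); got k={k} n={n} K={K}")


def hypergeometric_overlap(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Upper-tail hypergeometric test of an overlap, with obs/exp ratio.

    The reported p includes the observed count: ``P(X >= k)``.  scipy
    evaluates the tail in log space internally, so extreme overlaps do not
    underflow before the tail sum.
    """
    _check_bounds(N, K, n, k)
    pvalue = float(stats.hypergeom.sf(k - 1, N, K, n))
    expected = n * K / N
    obs_exp = k / expected if expected > 0 else np.nan
    return EnrichmentResult(N=N, K=K, n=n, k=k, obs_exp=obs_exp, pvalue=pvalue)


def depletion_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Lower-tail hypergeometric p, ``P(X <= k)``; reported for obs/exp < 1."""
    _check_bounds(N, K, n, k)
    return float(stats.hypergeom.cdf(k, N, K, n))


def enrichment_matrix(
    query_sets: dict[str, set[str]],
    category_map,
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """Full (query x category) table of overlap tests over one universe.

    ``category_map`` is a :class:`~nucleolink.genome_model.GeneCategoryMap`.
    Cells with enrichment p below ``alpha`` are flagged (the highlighting
    threshold used when such matrices are reported).
    """
    universe = set(category_map.universe)
    N = category_map.n
    for qname, qset in query_sets.items():
        extra = set(qset) - universe
        if extra:
            raise ValueError(
                f"query {qname!r} has members outside the universe: "
                f"{sorted(extra)[:5]}"
            )
    rows = []
    for qname, qset in query_sets.items():
        for cname, cset in category_map.categories.items():
            k = len(set(qset) & cset)
            res = hypergeometric_overlap(N, len(cset), len(qset), k)
            dep = depletion_pvalue(N, len(cset), len(qset), k)
            rows.append(
                {
                    "query": qname,
                    "category": cname,
                    "N": N,
                    "K": len(cset),
                    "n": len(qset),
                    "k": k,
                    "obs_exp": res.obs_exp,
                    "pvalue": res.pvalue,
                    "depletion_pvalue": dep,
                    "flagged": min(res.pvalue, dep) < alpha,
                }
            )
    return pd.DataFrame(rows)


def chi_square_two_proportions(
    k1: int, n1: int, k2: int, n2: int, correction: bool = False
) -> tuple[float, float]:
    """Two-tailed chi-square comparing proportions k1/n1 vs k2/n2 (df=1).

    Continuity correction is off by default (plain 2x2 Pearson chi-square).
    """
    if n1 <= 0 or n2 <= 0 or k1 > n1 or k2 > n2 or min(k1, k2) < 0:
        raise ValueError("require 0 <= k <= n and n > 0 for both samples")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate 2x2 table (zero margin)")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def region_alteration_enrichment(
    altered_by_class: dict[str, int],
    totals_by_class: dict[str, int],
) -> pd.DataFrame:
    """Per-region-class altered-nucleosome percentages with hypergeometric p.

    For each class: N = genome-wide nucleosome total, K = nucleosomes in the
    class, n = altered nucleosomes genome-wide, k = altered in the class.
    Classes with zero nucleosomes are skipped.
    """
    N = sum(totals_by_class.values())
    n = sum(altered_by_class.get(c, 0) for c in totals_by_class)
    rows = []
    for cls, K in totals_by_class.items():
        if K == 0:
            continue
        k = altered_by_class.get(cls, 0)
        res = hypergeometric_overlap(N, K, n, k)
        rows.append(
            {
                "region_class": cls,
                "nucleosomes": K,
                "altered": k,
                "percent_altered": 100.0 * k / K,
                "obs_exp": res.obs_exp,
                "enrichment_pvalue": res.pvalue,
                "depletion_pvalue": depletion_pvalue(N, K, n, k),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["genome_total"] = N
    out.attrs["genome_altered"] = n
    return out
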