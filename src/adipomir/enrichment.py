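"""Right-tailed Fisher's exact enrichment of a gene list against gene sets.

For a query of n genes drawn from a universe of N, a set of m genes, and an
observed overlap k, the enrichment p-value is the right tail of the
hypergeometric distribution, P(X ≥ k).  The universe must be supplied
explicitly: all four counts (k, n, m, N) are reported so any universe
convention can be audited.  Symbol matching is case-insensitive and exact
(no alias resolution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int           # overlap
    n: int           # query size (within universe)
    m: int           # set size (within universe)
    N: int           # universe size
    p: float
    genes: tuple[str, ...]  # overlapping gene symbols

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.n, self.m):
            raise ValueError(f"{self.term}: inconsistent overlap k={self.k}")
        if not 0 < self.p <= 1:
            raise ValueError(f"{self.term}: p out of (0, 1]: {self.p}")


def fisher_right(k: int, n: int, m: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, m, n)."""
    if not (0 <= k <= n <= N and k <= m <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, m={m}, N={N}")
    if k > min(n, m):
        raise ValueError(f"overlap k={k} exceeds min(n={n}, m={m})")
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def enrich(query: list[str], gene_sets: dict[str, list[str]],
           universe: list[str], alpha: float = 0.05, bh: bool = False,
           ) -> list[EnrichmentResult]:
    """Test every gene set for over-representation in the query.

    Gene sets are intersected with the universe before testing; query genes
    outside the universe are dropped with a warning.  Results come back
    sorted by ascending p.  Significance is flagged on raw p by default;
    ``bh=True`` applies Benjamini–Hochberg across the tested sets (see
    :func:`enrichment_table`).
    """
    if not universe:
        raise ValueError("empty universe")
    uni = {g.strip().upper() for g in universe if g.strip()}
    q = {g.strip().upper() for g in query if g.strip()}
    outside = sorted(q - uni)
    if outside:
        logger.warning("query gene(s) outside universe dropped: %s", outside)
    q &= uni

    results = []
    for term in sorted(gene_sets):
        members = {g.strip().upper() for g in gene_sets[term]} & uni
        overlap = sorted(q & members)
        results.append(EnrichmentResult(
            term=term,
            k=len(overlap),
            n=len(q),
            m=len(members),
            N=len(uni),
            p=fisher_right(len(overlap), len(q), len(members), len(uni)),
            genes=tuple(overlap),
        ))
    results.sort(key=lambda r: (r.p, r.term))
    return results


def enrichment_table(results: list[EnrichmentResult], alpha: float = 0.05,
                     bh: bool = False) -> pd.DataFrame:
    """TSV-ready table with −log10(p) and a significance flag."""
    df = pd.DataFrame([{
        "term": r.term, "k": r.k, "n": r.n, "m": r.m, "N": r.N,
        "p": r.p, "neglog10p": -np.log10(r.p), "genes": ",".join(r.genes),
    } for r in results])
    if df.empty:
        return df
    if bh:
        from statsmodels.stats.multitest import multipletests
        reject, p_adj, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
        df["p_adj"] = p_adj
        df["significant"] = reject
    else:
        df["significant"] = df["p"] < alpha
    return df
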