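"""Hypergeometric term enrichment with BH-adjusted q-values.

For each term with K annotated genes in a population of size N, the
one-sided upper-tail p-value of observing k annotated genes in a study set
of size n is P(X >= k) under Hypergeometric(N, K, n).  Significance is
flagged on raw p <= 0.05 (the stated criterion); BH q-values are reported
alongside.  Terms annotating no population gene are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Set, Tuple

from scipy import stats

from .diff_expression import bh_adjust

DEFAULT_ALPHA = 0.05


@dataclass
class TermMap:
    """term_id -> annotated gene-id set, with optional display names."""

    terms: Dict[str, Set[str]]
    names: Dict[str, str]

    def __init__(
        self,
        terms: Mapping[str, Iterable[str]],
        names: Mapping[str, str] | None = None,
    ):
        self.terms = {t: set(genes) for t, genes in terms.items()}
        self.names = dict(names or {})

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "TermMap":
        terms: Dict[str, Set[str]] = {}
        for term_id, gene_id in pairs:
            terms.setdefault(term_id, set()).add(gene_id)
        return cls(terms)

    def all_genes(self) -> Set[str]:
        out: Set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return out


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # study hits
    K: int  # population annotated
    n: int  # study size
    N: int  # population size
    pvalue: float
    qvalue: float
    significant: bool


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def enrich(
    study: Set[str],
    population: Set[str],
    terms: TermMap,
    alpha: float = DEFAULT_ALPHA,
) -> List[EnrichmentResult]:
    """Test every term with >= 1 annotated population gene."""
    if not population:
        raise ValueError("population is empty")
    missing = sorted(study - population)
    if missing:
        raise ValueError(f"study genes absent from population: {missing}")
    N, n = len(population), len(study)
    tested: List[Tuple[str, int, int, float]] = []
    for term_id in sorted(terms.terms):
        annotated = terms.terms[term_id] & population
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & study)
        tested.append((term_id, k, K, hypergeom_upper_tail(k, N, K, n)))
    qvalues = bh_adjust([p for _, _, _, p in tested])
    return [
        EnrichmentResult(
            term_id=term_id,
            k=k,
            K=K,
            n=n,
            N=N,
            pvalue=p,
            qvalue=q,
            significant=p <= alpha,
        )
        for (term_id, k, K, p), q in zip(tested, qvalues)
    ]
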