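"""Differential expression between unreplicated pooled libraries.

With one pooled library per stage no replicate variance is estimable, so
calls rest on an exact conditional count test: conditional on the total
t = x + y, x is Binomial(t, Na/(Na+Nb)) under the null of equal relative
abundance.  The two-sided p-value sums the probabilities of all outcomes
no more likely than the observed one.  Benjamini-Hochberg adjustment is
applied within each contrast, and a transcript is called differentially
expressed iff q <= fdr AND |log2 fold change| >= the threshold — both
boundaries inclusive.  Fold change is FPKM-based with a pseudocount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .annotation_io import ExpressionTable

DEFAULT_FDR = 0.05
DEFAULT_MIN_ABS_LOG2FC = 1.0
DEFAULT_PSEUDOCOUNT = 0.01

# relative tolerance when comparing pmf masses to the observed mass; guards
# against float noise promoting "equal" masses out of the tail sum
_PMF_RTOL = 1e-12


@dataclass(frozen=True)
class DEResult:
    transcript_id: str
    contrast: Tuple[str, str]
    count_a: int
    count_b: int
    depth_a: int
    depth_b: int
    log2fc: float
    pvalue: float
    qvalue: float
    call: str  # up | down | ns


def exact_count_test(x: int, y: int, depth_a: int, depth_b: int) -> float:
    """Two-sided exact conditional binomial p-value for one count pair."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("library depths must be positive")
    t = x + y
    if t == 0:
        return 1.0
    p_null = depth_a / (depth_a + depth_b)
    k = np.arange(t + 1)
    pmf = stats.binom.pmf(k, t, p_null)
    observed = pmf[x]
    p = float(pmf[pmf <= observed * (1.0 + _PMF_RTOL)].sum())
    # extreme outcomes underflow the double-precision pmf; keep p in (0, 1]
    return min(1.0, max(p, float(observed), 1e-300))


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def call_de(
    expr: ExpressionTable,
    contrasts: Sequence[Tuple[str, str]] = (("E", "P"), ("E", "L"), ("P", "L")),
    fdr: float = DEFAULT_FDR,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> List[DEResult]:
    """Per-contrast exact tests with BH correction and conjunctive calls."""
    results: List[DEResult] = []
    tids = expr.transcript_ids()
    depths: Dict[str, int] = {lib: expr.library_depth(lib) for lib in expr.libraries}
    for lib_a, lib_b in contrasts:
        for lib in (lib_a, lib_b):
            if lib not in expr.libraries:
                raise ValueError(f"contrast library {lib!r} missing from table")
        na, nb = depths[lib_a], depths[lib_b]
        pvals: List[float] = []
        records: List[Tuple[str, int, int, float]] = []
        for tid in tids:
            row_a = expr.get(tid, lib_a)
            row_b = expr.get(tid, lib_b)
            pvals.append(exact_count_test(row_a.read_count, row_b.read_count, na, nb))
            log2fc = math.log2(
                (row_b.fpkm + pseudocount) / (row_a.fpkm + pseudocount)
            )
            records.append((tid, row_a.read_count, row_b.read_count, log2fc))
        qvals = bh_adjust(pvals)
        for (tid, ca, cb, log2fc), p, q in zip(records, pvals, qvals):
            if q <= fdr and abs(log2fc) >= min_abs_log2fc:
                call = "up" if log2fc > 0 else "down"
            else:
                call = "ns"
            results.append(
                DEResult(
                    transcript_id=tid,
                    contrast=(lib_a, lib_b),
                    count_a=ca,
                    count_b=cb,
                    depth_a=na,
                    depth_b=nb,
                    log2fc=log2fc,
                    pvalue=p,
                    qvalue=q,
                    call=call,
                )
            )
    return results


def de_transcripts(results: Sequence[DEResult]) -> set:
    """Ids called up or down in at least one contrast."""
    return {r.transcript_id for r in results if r.call != "ns"}
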