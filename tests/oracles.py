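"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (exhaustive enumeration, quadratic
scans, exact rational arithmetic) and shares no code with the package
paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Dict, List, Optional, Sequence, Set, Tuple

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# -- six-frame ORF enumeration ----------------------------------------------

def longest_orf_aa(seq: str) -> int:
    best = 0
    for s in (seq, revcomp(seq)):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            for i, codon in enumerate(codons):
                if codon != "ATG":
                    continue
                for j in range(i + 1, len(codons)):
                    if codons[j] in _STOPS:
                        best = max(best, j - i)
                        break
    return best


# -- exact conditional binomial test by rational enumeration ----------------

def exact_test_enumeration(x: int, y: int, na: int, nb: int) -> Fraction:
    t = x + y
    if t == 0:
        return Fraction(1)
    p = Fraction(na, na + nb)

    def mass(k: int) -> Fraction:
        return comb(t, k) * p**k * (1 - p) ** (t - k)

    observed = mass(x)
    return sum(mass(k) for k in range(t + 1) if mass(k) <= observed)


# -- BH step-up by direct definition ----------------------------------------

def bh_stepup(pvalues: Sequence[float]) -> List[float]:
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        val = min(prev, pvalues[i] * m / rank)
        q[i] = val
        prev = val
    return q


# -- hypergeometric upper tail by subset counting ---------------------------

def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> Fraction:
    total = comb(N, n)
    hits = sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(max(k, 0), min(K, n) + 1)
    )
    return Fraction(hits, total)


# -- local alignment DP oracles ---------------------------------------------

def duplex_pair_score(x: str, y: str, gc=3, at=2, wobble=1, mismatch=-2) -> int:
    pair = x + y
    if pair in ("GC", "CG"):
        return gc
    if pair in ("AT", "TA"):
        return at
    if pair in ("GT", "TG"):
        return wobble
    return mismatch


def duplex_local_dp(a: str, b: str, gap_open=-3, gap_extend=-1, **scores) -> int:
    """Best local affine-gap score of a paired against b (Gotoh, naive).

    b is traversed reverse-complement-wise by pairing a[i] directly with
    b-bases in reverse order, which is equivalent to aligning a against
    revcomp(b) under the pair-score model.
    """
    brc = revcomp(b)
    n, m = len(a), len(brc)
    NEG = float("-inf")
    best = 0
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in brc (vertical)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            s = duplex_pair_score(a[i - 1], _COMP[brc[j - 1]], **scores)
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def sw_linear_dp(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    """Plain Smith-Waterman best score with linear gap penalties."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(
                0, H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap
            )
            best = max(best, H[i][j])
    return best


# -- classifier oracle -------------------------------------------------------

def classify_oracle(
    lnc_exons: List[Tuple[int, int]],
    lnc_strand: str,
    lnc_span: Tuple[int, int],
    genes: List[dict],
    window: int = 1000,
) -> str:
    """Exhaustive pairwise re-derivation of the five-way classification.

    ``genes`` entries: {gene_id, strand, span=(s,e), tss, coding_exons:
    [(s,e)], introns: [(s,e)], is_coding}.
    """

    def exons_overlap(strand_match: bool) -> bool:
        for g in genes:
            if not g["is_coding"]:
                continue
            if (g["strand"] == lnc_strand) != strand_match:
                continue
            for gs, ge in g["coding_exons"]:
                for ls, le in lnc_exons:
                    if ls < ge and gs < le:
                        return True
        return False

    if exons_overlap(True):
        return "sense"
    if exons_overlap(False):
        return "antisense"
    s0, e0 = lnc_span
    for g in genes:
        if not g["is_coding"]:
            continue
        for is_, ie in g["introns"]:
            if is_ <= s0 and e0 <= ie:
                return "intronic"
    overlaps_any = any(
        g["span"][0] < e0 and s0 < g["span"][1] for g in genes
    )
    if not overlaps_any:
        lnc_tss = s0 if lnc_strand == "+" else e0 - 1
        for g in genes:
            if not g["is_coding"] or g["strand"] == lnc_strand:
                continue
            if lnc_strand == "-":
                minus_tss, plus_tss = lnc_tss, g["tss"]
            else:
                minus_tss, plus_tss = g["tss"], lnc_tss
            if minus_tss <= plus_tss and abs(lnc_tss - g["tss"]) <= window:
                return "bidirectional"
    return "intergenic"


def apc_oracle(
    lnc_span: Tuple[int, int],
    lnc_strand: str,
    genes: List[dict],
    window: int = 10000,
) -> Dict[str, Tuple[str, int]]:
    """Nearest coding gene per side by linear scan; {side: (gene_id, gap)}."""
    s0, e0 = lnc_span
    sides: Dict[str, Tuple[str, int]] = {}
    for genomic_side in ("left", "right"):
        best: Optional[Tuple[int, str]] = None
        for g in genes:
            if not g["is_coding"]:
                continue
            gs, ge = g["span"]
            if genomic_side == "left" and ge <= s0:
                gap = s0 - ge
            elif genomic_side == "right" and gs >= e0:
                gap = gs - e0
            else:
                continue
            if 0 < gap <= window:
                cand = (gap, g["gene_id"])
                if best is None or cand < best:
                    best = cand
        if best is not None:
            if lnc_strand == "+":
                side = "upstream" if genomic_side == "left" else "downstream"
            else:
                side = "downstream" if genomic_side == "left" else "upstream"
            sides[side] = (best[1], best[0])
    return sides


# -- ceRNA network relational join oracle -----------------------------------

def network_oracle(
    lnc_reads: Dict[str, int],
    lnc_links: Dict[str, Set[Tuple[str, str]]],  # lnc -> {(mrna, kind)}
    de_mrnas: Set[str],
    mrna_ids: Set[str],
    targets: List[Tuple[str, str]],
    precursors: List[Tuple[str, str]],  # (lnc, mirna)
    min_reads: int = 10,
) -> Tuple[Set[str], Set[str], Set[str], Set[Tuple[str, str, str]]]:
    lnc_nodes = {
        l
        for l, reads in lnc_reads.items()
        if reads > min_reads and {(m, k) for m, k in lnc_links.get(l, set())
                                  if m in mrna_ids}
    }
    mir_lnc = {}
    mir_mrna = {}
    for mir, tgt in targets:
        if tgt in lnc_reads:
            mir_lnc.setdefault(mir, set()).add(tgt)
        elif tgt in mrna_ids:
            mir_mrna.setdefault(mir, set()).add(tgt)
    prec = {}
    for lnc, mir in precursors:
        prec.setdefault(mir, set()).add(lnc)
    lnc_side_mirs = {
        m
        for m in set(mir_lnc) | set(prec)
        if (mir_lnc.get(m, set()) & lnc_nodes) or (prec.get(m, set()) & lnc_nodes)
    }
    linked = {
        mrna
        for l in lnc_nodes
        for mrna, _k in lnc_links.get(l, set())
        if mrna in mrna_ids
    }
    reachable = {t for m in lnc_side_mirs for t in mir_mrna.get(m, set())}
    mrna_nodes = de_mrnas & (linked | reachable)
    mir_nodes = set()
    for m in set(mir_lnc) | set(mir_mrna) | set(prec):
        if (
            (mir_lnc.get(m, set()) & lnc_nodes)
            or (prec.get(m, set()) & lnc_nodes)
            or (mir_mrna.get(m, set()) & mrna_nodes)
        ):
            mir_nodes.add(m)
    edges: Set[Tuple[str, str, str]] = set()
    for l in lnc_nodes:
        for mrna, kind in lnc_links.get(l, set()):
            if mrna in mrna_nodes:
                edges.add((l, mrna, kind))
    for m in mir_nodes:
        for l in mir_lnc.get(m, set()) & lnc_nodes:
            edges.add((m, l, "mirna_targets_lncrna"))
        for t in mir_mrna.get(m, set()) & mrna_nodes:
            edges.add((m, t, "mirna_targets_mrna"))
        for l in prec.get(m, set()) & lnc_nodes:
            edges.add((l, m, "lncrna_precursor_of_mirna"))
    return lnc_nodes, mir_nodes, mrna_nodes, edges
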