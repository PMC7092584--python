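"""Antisense duplex scoring and miRNA hairpin-precursor matching.

Both operations are explicitly parameterized local alignments (Smith-
Waterman style) so results are reproducible bit-for-bit:

- ``duplex_score`` aligns a sequence against the reverse complement of its
  partner with base-pair scores GC=+3, AT=+2, G·U wobble=+1, mismatch=-2
  and affine gaps (open -3, extend -1; a length-k gap costs
  3 + (k-1)).  A hit is reported iff the best local score reaches the
  threshold (default 40).

- ``match_precursors`` aligns each lncRNA against each hairpin (as given
  and reverse-complemented) with match +1 / mismatch -1 / gap -2, and
  reports a hit iff identity >= 0.90 (matches over aligned columns,
  gap columns included) and hairpin coverage > 0.90 (aligned hairpin
  positions over hairpin length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .annotation_io import SequenceSet
from .filter_cascade import reverse_complement

DEFAULT_DUPLEX_THRESHOLD = 40
PRECURSOR_MIN_IDENTITY = 0.90   # inclusive: identity >= 90%
PRECURSOR_MIN_COVERAGE = 0.90   # strict: coverage > 90%

_PAIR_SCORES = {"GC": 3, "CG": 3, "AT": 2, "TA": 2, "GT": 1, "TG": 1}


@dataclass
class DuplexParams:
    gc: int = 3
    at: int = 2
    wobble: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1
    threshold: int = DEFAULT_DUPLEX_THRESHOLD


@dataclass(frozen=True)
class DuplexHit:
    lnc_id: str
    mrna_id: str
    score: int
    region_a: Tuple[int, int]  # on the lncRNA
    region_b: Tuple[int, int]  # on the mRNA, original orientation


@dataclass(frozen=True)
class PrecursorHit:
    lnc_id: str
    hairpin_id: str
    identity: float
    coverage: float
    lnc_region: Tuple[int, int]
    hairpin_region: Tuple[int, int]
    orientation: str  # "+" hairpin as given, "-" reverse complement

    def __post_init__(self) -> None:
        if self.identity < PRECURSOR_MIN_IDENTITY:
            raise ValueError("precursor hit below identity threshold")
        if self.coverage <= PRECURSOR_MIN_COVERAGE:
            raise ValueError("precursor hit below coverage threshold")


def pair_score(x: str, y: str, params: DuplexParams) -> int:
    """Score of base x paired opposite base y in the duplex."""
    s = _PAIR_SCORES.get(x + y)
    if s == 3:
        return params.gc
    if s == 2:
        return params.at
    if s == 1:
        return params.wobble
    return params.mismatch


def _duplex_aligner(params: DuplexParams) -> Align.PairwiseAligner:
    # a is aligned against revcomp(b); a letter z of revcomp(b) stands for
    # base complement(z) of b, so "x aligned to z" scores pair (x, comp(z)).
    # That collapses Watson-Crick pairs onto the diagonal and the two
    # wobble pairs onto (G,A) and (T,C).
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for z in alphabet:
            comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[z]
            mat[x, z] = pair_score(x, comp, params)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def duplex_score(
    a: str,
    b: str,
    params: DuplexParams | None = None,
    lnc_id: str = "a",
    mrna_id: str = "b",
) -> Optional[DuplexHit]:
    """Best local complementarity segment of a against b, or None."""
    if not a or not b:
        raise ValueError("duplex_score requires non-empty sequences")
    params = params or DuplexParams()
    aligner = _duplex_aligner(params)
    rc_b = reverse_complement(b)
    score = int(aligner.score(a, rc_b))
    if score < params.threshold:
        return None
    aln = next(iter(aligner.align(a, rc_b)))
    blocks_a, blocks_rc = aln.aligned
    a_start, a_end = int(blocks_a[0][0]), int(blocks_a[-1][1])
    rc_start, rc_end = int(blocks_rc[0][0]), int(blocks_rc[-1][1])
    # map the revcomp(b) segment back to b coordinates
    b_start, b_end = len(b) - rc_end, len(b) - rc_start
    return DuplexHit(lnc_id, mrna_id, score, (a_start, a_end), (b_start, b_end))


def _precursor_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2  # linear gap model
    return aligner


def _align_one(
    aligner: Align.PairwiseAligner, lnc_seq: str, hp_seq: str
) -> Tuple[int, float, float, Tuple[int, int], Tuple[int, int]]:
    aln = next(iter(aligner.align(lnc_seq, hp_seq)))
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    blocks_l, blocks_h = aln.aligned
    hp_aligned = sum(int(e) - int(s) for s, e in blocks_h)
    coverage = hp_aligned / len(hp_seq)
    lnc_region = (int(blocks_l[0][0]), int(blocks_l[-1][1]))
    hp_region = (int(blocks_h[0][0]), int(blocks_h[-1][1]))
    return int(aln.score), identity, coverage, lnc_region, hp_region


def match_precursors(
    lncs: SequenceSet, hairpins: SequenceSet
) -> List[PrecursorHit]:
    """All (lncRNA, hairpin) pairs passing the identity/coverage screen."""
    if len(hairpins) == 0:
        raise ValueError("hairpin set is empty")
    aligner = _precursor_aligner()
    hits: List[PrecursorHit] = []
    for lnc_id, lnc_seq in lncs.items():
        for hp_id, hp_seq in hairpins.items():
            best = None
            for orientation, seq in (
                ("+", hp_seq),
                ("-", reverse_complement(hp_seq)),
            ):
                res = _align_one(aligner, lnc_seq, seq)
                if best is None or res[0] > best[1][0]:
                    best = (orientation, res)
            orientation, (score, identity, coverage, lnc_region, hp_region) = best
            if identity >= PRECURSOR_MIN_IDENTITY and coverage > PRECURSOR_MIN_COVERAGE:
                if orientation == "-":
                    n = len(hp_seq)
                    hp_region = (n - hp_region[1], n - hp_region[0])
                hits.append(
                    PrecursorHit(
                        lnc_id, hp_id, identity, coverage,
                        lnc_region, hp_region, orientation,
                    )
                )
    hits.sort(key=lambda h: (h.lnc_id, h.hairpin_id))
    return hits
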