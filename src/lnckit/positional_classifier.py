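"""Positional classification of retained lncRNAs and apcGene search.

Each lncRNA gets exactly one of five classes, decided by a fixed priority:

  sense > antisense > intronic > bidirectional > intergenic

- sense:         >= 1 bp exon overlap with a coding exon, same strand
- antisense:     >= 1 bp exon overlap with a coding exon, opposite strand
- intronic:      span fully inside one intron of a coding transcript
                 (either strand)
- bidirectional: no span overlap with any gene, TSS within a window
                 (default 1000 bp) of a coding TSS on the opposite strand
                 in divergent head-to-head orientation
- intergenic:    everything else

Ties within a rule break to the lexicographically smallest gene_id.

apcGenes are the nearest non-overlapping coding genes on each side of a
lncRNA with a span-to-span gap in (0, window]; the window is inclusive at
exactly 10 kb.  Sides are reported in the lncRNA's reading orientation
(5' neighbour = upstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Tuple

from .annotation_io import Annotation, GeneModel, GenomicInterval, TranscriptModel

DEFAULT_BIDIRECTIONAL_WINDOW = 1000
DEFAULT_APC_WINDOW = 10000


class LncClass(str, Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"
    INTRONIC = "intronic"
    BIDIRECTIONAL = "bidirectional"
    INTERGENIC = "intergenic"


@dataclass
class ClassifiedLnc:
    transcript: TranscriptModel
    lnc_class: LncClass
    evidence_gene_id: Optional[str] = None
    # overlapped exon/intron interval for sense/antisense/intronic,
    # TSS distance (bp) for bidirectional
    evidence_interval: Optional[GenomicInterval] = None
    evidence_tss_distance: Optional[int] = None

    def __post_init__(self) -> None:
        has_gene = self.evidence_gene_id is not None
        if (self.lnc_class == LncClass.INTERGENIC) == has_gene:
            raise ValueError(
                "evidence_gene_id must be present iff class != intergenic"
            )

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


@dataclass(frozen=True)
class ApcLink:
    lnc_id: str
    gene_id: str
    side: str  # upstream | downstream, in the lncRNA's orientation
    gap_bp: int

    def __post_init__(self) -> None:
        if self.side not in ("upstream", "downstream"):
            raise ValueError(f"invalid side {self.side!r}")
        if self.gap_bp <= 0:
            raise ValueError("apc gap must be positive (no overlap allowed)")


def _exon_overlap(
    lnc: TranscriptModel, gene: GeneModel, same_strand: bool
) -> Optional[GenomicInterval]:
    """First (leftmost) coding-exon interval overlapping a lnc exon."""
    best: Optional[GenomicInterval] = None
    for ct in gene.transcripts:
        if ct.biotype != "coding":
            continue
        if (ct.strand == lnc.strand) != same_strand:
            continue
        for ce in ct.exons:
            for e in lnc.exons:
                if e.start < ce.end and ce.start < e.end:
                    if best is None or (ce.start, ce.end) < (best.start, best.end):
                        best = ce
    return best


def _containing_intron(
    lnc: TranscriptModel, gene: GeneModel
) -> Optional[GenomicInterval]:
    for ct in gene.transcripts:
        if ct.biotype != "coding":
            continue
        for intron in ct.introns():
            if intron.start <= lnc.start and lnc.end <= intron.end:
                return intron
    return None


def _divergent_tss_distance(
    lnc: TranscriptModel, gene: GeneModel, window: int
) -> Optional[int]:
    """TSS distance if the pair is head-to-head divergent within the window."""
    if gene.strand == lnc.strand:
        return None
    # Divergent: transcription proceeds away on both sides, i.e. the minus
    # partner sits at or left of the plus partner's TSS.
    if lnc.strand == "-":
        minus_tss, plus_tss = lnc.tss, gene.tss
    else:
        minus_tss, plus_tss = gene.tss, lnc.tss
    if minus_tss > plus_tss:
        return None
    d = abs(lnc.tss - gene.tss)
    return d if d <= window else None


def classify(
    lnc: TranscriptModel,
    annotation: Annotation,
    bidirectional_window: int = DEFAULT_BIDIRECTIONAL_WINDOW,
) -> ClassifiedLnc:
    """Assign the single positional class of one lncRNA."""
    if lnc.chrom not in annotation.scaffold_lengths:
        raise ValueError(f"lncRNA {lnc.transcript_id!r} on unknown scaffold {lnc.chrom!r}")

    overlapping = annotation.query(lnc.chrom, lnc.start, lnc.end, coding_only=True)
    overlapping.sort(key=lambda g: g.gene_id)

    for same_strand, cls in ((True, LncClass.SENSE), (False, LncClass.ANTISENSE)):
        for gene in overlapping:
            hit = _exon_overlap(lnc, gene, same_strand)
            if hit is not None:
                return ClassifiedLnc(lnc, cls, gene.gene_id, evidence_interval=hit)

    for gene in overlapping:
        intron = _containing_intron(lnc, gene)
        if intron is not None:
            return ClassifiedLnc(
                lnc, LncClass.INTRONIC, gene.gene_id, evidence_interval=intron
            )

    # bidirectional requires NO span overlap with any gene at all
    # (the lncRNA's own gene record, if annotated, is not "another" gene)
    any_overlap = [
        g
        for g in annotation.query(lnc.chrom, lnc.start, lnc.end, coding_only=False)
        if g.gene_id != lnc.gene_id
    ]
    if not any_overlap:
        window = bidirectional_window
        # a gene's TSS lies inside its span, so a span query around the lnc
        # TSS catches every gene with a TSS within the window
        lo = max(0, min(lnc.start, lnc.tss - window))
        hi = max(lnc.end, lnc.tss + window + 1)
        nearby = annotation.query(lnc.chrom, lo, hi, coding_only=True)
        candidates: List[Tuple[int, str, GeneModel]] = []
        for gene in nearby:
            d = _divergent_tss_distance(lnc, gene, window)
            if d is not None:
                candidates.append((d, gene.gene_id, gene))
        if candidates:
            candidates.sort(key=lambda c: c[1])  # smallest gene_id breaks ties
            d, gid, _ = candidates[0]
            return ClassifiedLnc(
                lnc, LncClass.BIDIRECTIONAL, gid, evidence_tss_distance=d
            )

    return ClassifiedLnc(lnc, LncClass.INTERGENIC)


def classify_all(
    lncs: List[TranscriptModel],
    annotation: Annotation,
    bidirectional_window: int = DEFAULT_BIDIRECTIONAL_WINDOW,
) -> List[ClassifiedLnc]:
    return [classify(t, annotation, bidirectional_window) for t in lncs]


def find_apc_genes(
    lnc: TranscriptModel,
    annotation: Annotation,
    window_bp: int = DEFAULT_APC_WINDOW,
) -> List[ApcLink]:
    """Nearest non-overlapping coding gene on each side within the window.

    At most one link per side; gap measured between spans; a gap of exactly
    ``window_bp`` still links, ``window_bp + 1`` does not.  Genes touching
    or overlapping the lncRNA are never apcGenes.
    """
    left_best: Optional[Tuple[int, str, GeneModel]] = None
    right_best: Optional[Tuple[int, str, GeneModel]] = None
    # a gene abutting the window edge still qualifies (gap == window_bp)
    lo = max(0, lnc.start - window_bp - 1)
    hi = lnc.end + window_bp + 1
    for gene in annotation.query(lnc.chrom, lo, hi, coding_only=True):
        if gene.end <= lnc.start:
            gap = lnc.start - gene.end
            if 0 < gap <= window_bp:
                key = (gap, gene.gene_id, gene)
                if left_best is None or key[:2] < left_best[:2]:
                    left_best = key
        elif gene.start >= lnc.end:
            gap = gene.start - lnc.end
            if 0 < gap <= window_bp:
                key = (gap, gene.gene_id, gene)
                if right_best is None or key[:2] < right_best[:2]:
                    right_best = key
        # overlapping / abutting genes: ignored

    links: List[ApcLink] = []
    for genomic_side, best in (("left", left_best), ("right", right_best)):
        if best is None:
            continue
        gap, gid, _ = best
        if lnc.strand == "+":
            side = "upstream" if genomic_side == "left" else "downstream"
        else:
            side = "downstream" if genomic_side == "left" else "upstream"
        links.append(ApcLink(lnc.transcript_id, gid, side, gap))
    links.sort(key=lambda l: (l.side, l.gene_id))
    return links
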