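"""Seven-step candidate-lncRNA filter cascade.

Steps run in a fixed order; each removed transcript is attributed to the
first rule it fails.  Each rule is a pure predicate, so the retained SET is
invariant under step reordering — only the per-step attribution counts
depend on the order.  Boundary semantics follow the strict-inequality
removal criteria: length 200 bp, coverage 0.8, FPKM 0.1 and a 100-aa ORF
are all retained; transcripts closer than 2000 bp to a scaffold end are
removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Sequence, Set, Tuple

from .annotation_io import (
    Annotation,
    ExpressionTable,
    SequenceSet,
    TranscriptModel,
)

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_longest_orf(seq: str) -> int:
    """Longest ORF over all six reading frames, in amino acids.

    An ORF is ATG ... in-frame stop; the returned length counts codons from
    the ATG up to but excluding the stop.  Open-ended runs (no stop before
    the sequence end) are not counted.  Codons containing N never match
    either ATG or a stop, so they extend a candidate ORF without
    terminating it.
    """
    best = 0
    for s in (seq, reverse_complement(seq)):
        n = len(s)
        for frame in range(3):
            starts: List[int] = []  # codon indices of open ATGs
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon == "ATG":
                    starts.append(pos)
                elif codon in _STOPS:
                    if starts:
                        # first (leftmost) open ATG gives the longest ORF here
                        best = max(best, (pos - starts[0]) // 3)
                    starts = []
    return best


@dataclass
class FilterConfig:
    min_length_bp: int = 200
    min_exons: int = 2
    min_coverage: float = 0.8
    min_fpkm: float = 0.1
    max_orf_aa: int = 100
    scaffold_end_margin_bp: int = 2000
    drop_sense_exon_overlap: bool = True
    evidence_ids: FrozenSet[str] = field(default_factory=frozenset)
    polya_required: bool = False
    polya_ids: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in ("min_length_bp", "min_exons", "min_coverage", "min_fpkm",
                     "max_orf_aa", "scaffold_end_margin_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.evidence_ids = frozenset(self.evidence_ids)
        self.polya_ids = frozenset(self.polya_ids)


STEP_NAMES = (
    "sense_exon_overlap",
    "min_length",
    "min_exons",
    "min_coverage",
    "min_fpkm",
    "orf",
    "protein_evidence",
    "scaffold_end",
    "polya",
)


@dataclass
class FilterReport:
    steps: Tuple[str, ...]
    removed_per_step: Dict[str, int]
    fate: Dict[str, str]  # transcript_id -> first failing step, or "retained"

    @property
    def n_input(self) -> int:
        return len(self.fate)

    @property
    def n_retained(self) -> int:
        return sum(1 for v in self.fate.values() if v == "retained")

    def check_conservation(self) -> None:
        if self.n_input != self.n_retained + sum(self.removed_per_step.values()):
            raise AssertionError("filter report counts do not conserve")

    def rows(self) -> List[Tuple[str, int]]:
        return [(s, self.removed_per_step[s]) for s in self.steps]


def _sense_overlaps_coding_exon(t: TranscriptModel, annotation: Annotation) -> bool:
    for gene in annotation.query(t.chrom, t.start, t.end, coding_only=True):
        for ct in gene.transcripts:
            if ct.biotype != "coding" or ct.strand != t.strand:
                continue
            if ct.transcript_id == t.transcript_id:
                continue
            for ce in ct.exons:
                for e in t.exons:
                    if e.start < ce.end and ce.start < e.end:
                        return True
    return False


def build_step_predicates(
    annotation: Annotation,
    expr: ExpressionTable,
    seqs: SequenceSet,
    config: FilterConfig,
) -> List[Tuple[str, Callable[[TranscriptModel], bool]]]:
    """(step name, fails-predicate) pairs in cascade order.

    Predicates are pure: each inspects only the transcript and the shared
    inputs, never the outcome of another step.
    """

    def fail_sense(t: TranscriptModel) -> bool:
        if not config.drop_sense_exon_overlap:
            return False
        if t.biotype == "known_lncRNA":  # known lncRNAs bypass the overlap screen
            return False
        return _sense_overlaps_coding_exon(t, annotation)

    def fail_length(t: TranscriptModel) -> bool:
        return t.length < config.min_length_bp

    def fail_exons(t: TranscriptModel) -> bool:
        return t.n_exons < config.min_exons

    def fail_coverage(t: TranscriptModel) -> bool:
        return expr.max_over_libraries(t.transcript_id, "coverage") < config.min_coverage

    def fail_fpkm(t: TranscriptModel) -> bool:
        return expr.max_over_libraries(t.transcript_id, "fpkm") < config.min_fpkm

    def fail_orf(t: TranscriptModel) -> bool:
        return scan_longest_orf(seqs[t.transcript_id]) > config.max_orf_aa

    def fail_evidence(t: TranscriptModel) -> bool:
        return t.transcript_id in config.evidence_ids

    def fail_margin(t: TranscriptModel) -> bool:
        if t.chrom not in annotation.scaffold_lengths:
            raise ValueError(f"unknown scaffold {t.chrom!r} for {t.transcript_id}")
        slen = annotation.scaffold_lengths[t.chrom]
        m = config.scaffold_end_margin_bp
        return t.start < m or (slen - t.end) < m

    def fail_polya(t: TranscriptModel) -> bool:
        if not config.polya_required:
            return False
        return t.transcript_id not in config.polya_ids

    return [
        ("sense_exon_overlap", fail_sense),
        ("min_length", fail_length),
        ("min_exons", fail_exons),
        ("min_coverage", fail_coverage),
        ("min_fpkm", fail_fpkm),
        ("orf", fail_orf),
        ("protein_evidence", fail_evidence),
        ("scaffold_end", fail_margin),
        ("polya", fail_polya),
    ]


def apply_filter_cascade(
    transcripts: Sequence[TranscriptModel],
    annotation: Annotation,
    expr: ExpressionTable,
    seqs: SequenceSet,
    config: FilterConfig | None = None,
) -> Tuple[List[str], FilterReport]:
    """Run the cascade; returns (retained ids sorted, report)."""
    config = config or FilterConfig()

    for t in transcripts:
        if t.transcript_id not in seqs:
            raise ValueError(f"transcript {t.transcript_id!r} missing from sequences")
        if t.transcript_id not in expr:
            raise ValueError(f"transcript {t.transcript_id!r} missing from expression")

    predicates = build_step_predicates(annotation, expr, seqs, config)
    removed_per_step = {name: 0 for name, _ in predicates}
    fate: Dict[str, str] = {}
    retained: List[str] = []

    for t in transcripts:
        for name, fails in predicates:
            if fails(t):
                removed_per_step[name] += 1
                fate[t.transcript_id] = name
                break
        else:
            fate[t.transcript_id] = "retained"
            retained.append(t.transcript_id)

    report = FilterReport(
        steps=tuple(name for name, _ in predicates),
        removed_per_step=removed_per_step,
        fate=fate,
    )
    report.check_conservation()
    return sorted(retained), report
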