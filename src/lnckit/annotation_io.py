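"""Shared genomic data model and parsers/serializers for the pipeline formats.

Internal coordinates are 0-based half-open throughout.  GTF (1-based,
inclusive) and BED (0-based, half-open) conventions are converted only at the
I/O boundary.  Transcripts without a definite strand never enter the
pipeline: every positional rule downstream is strand-defined.
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Set, Tuple

from Bio.SeqIO.FastaIO import SimpleFastaParser

LIBRARIES = ("E", "P", "L")

VALID_STRANDS = ("+", "-")


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open interval on one scaffold."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """Stranded multi-exon structure of one transcript.

    Exons are kept sorted by start and must be pairwise disjoint on a single
    chrom/strand.  Introns are the gaps between consecutive exons.
    """

    transcript_id: str
    gene_id: str
    exons: List[GenomicInterval]
    biotype: str = "candidate_noncoding"  # coding | candidate_noncoding | known_lncRNA

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons span multiple chroms/strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Strand-aware 5' position (coordinate of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> List[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class GeneModel:
    gene_id: str
    transcripts: List[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene needs >= 1 transcript")
        if len({t.chrom for t in self.transcripts}) != 1:
            raise ValueError(f"{self.gene_id}: transcripts on multiple chroms")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def is_coding(self) -> bool:
        return any(t.biotype == "coding" for t in self.transcripts)


class _ChromIndex:
    """Sorted-start interval list with a running max-end, for window queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._genes = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
        self._starts = [g.start for g in self._genes]
        self._maxend = []
        m = 0
        for g in self._genes:
            m = max(m, g.end)
            self._maxend.append(m)

    def query(self, start: int, end: int) -> List[GeneModel]:
        """All genes whose span intersects [start, end)."""
        hi = bisect_right(self._starts, end - 1)
        out = []
        # walk left; the running max-end bound lets us stop early
        for i in range(hi - 1, -1, -1):
            if self._maxend[i] <= start:
                break
            g = self._genes[i]
            if g.end > start:
                out.append(g)
        out.reverse()
        return out


@dataclass
class Annotation:
    """Gene collection with scaffold lengths and an interval index."""

    scaffold_lengths: Dict[str, int]
    genes: Dict[str, GeneModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes.values():
            self._check_bounds(g)
        self._rebuild_index()

    def _check_bounds(self, gene: GeneModel) -> None:
        if gene.chrom not in self.scaffold_lengths:
            raise ValueError(f"gene {gene.gene_id} on unknown scaffold {gene.chrom}")
        if gene.end > self.scaffold_lengths[gene.chrom]:
            raise ValueError(
                f"gene {gene.gene_id} exceeds scaffold {gene.chrom} length"
            )

    def _rebuild_index(self) -> None:
        by_chrom: Dict[str, List[GeneModel]] = {}
        for g in self.genes.values():
            by_chrom.setdefault(g.chrom, []).append(g)
        self._index = {c: _ChromIndex(gs) for c, gs in by_chrom.items()}

    def coding_genes(self) -> List[GeneModel]:
        return [self.genes[gid] for gid in sorted(self.genes)
                if self.genes[gid].is_coding]

    def query(self, chrom: str, start: int, end: int,
              coding_only: bool = False) -> List[GeneModel]:
        """Genes whose span intersects the window [start, end)."""
        idx = self._index.get(chrom)
        if idx is None:
            return []
        hits = idx.query(start, end)
        if coding_only:
            hits = [g for g in hits if g.is_coding]
        return hits

    def query_brute(self, chrom: str, start: int, end: int,
                    coding_only: bool = False) -> List[GeneModel]:
        """Linear-scan reference for the index (kept for verification)."""
        out = [
            g
            for g in self.genes.values()
            if g.chrom == chrom and g.start < end and g.end > start
            and (not coding_only or g.is_coding)
        ]
        return sorted(out, key=lambda g: (g.start, g.end, g.gene_id))


@dataclass
class ExpressionRow:
    read_count: int
    fpkm: float
    coverage: float

    def __post_init__(self) -> None:
        if self.read_count < 0 or self.fpkm < 0 or not (0 <= self.coverage <= 1):
            raise ValueError("invalid expression row")
        if self.fpkm == 0 and self.read_count != 0:
            raise ValueError("read_count must be 0 when fpkm is 0")


class ExpressionTable:
    """Per-transcript, per-library read counts, FPKM and coverage fraction."""

    def __init__(self, libraries: Sequence[str] = LIBRARIES):
        self.libraries = tuple(libraries)
        self._rows: Dict[Tuple[str, str], ExpressionRow] = {}

    def set(self, transcript_id: str, library: str, row: ExpressionRow) -> None:
        if library not in self.libraries:
            raise KeyError(f"unknown library {library!r}")
        self._rows[(transcript_id, library)] = row

    def get(self, transcript_id: str, library: str) -> ExpressionRow:
        try:
            return self._rows[(transcript_id, library)]
        except KeyError:
            raise KeyError(
                f"no expression row for transcript {transcript_id!r} "
                f"in library {library!r}"
            ) from None

    def __contains__(self, transcript_id: str) -> bool:
        return all((transcript_id, lib) in self._rows for lib in self.libraries)

    def transcript_ids(self) -> List[str]:
        return sorted({tid for tid, _ in self._rows})

    def max_over_libraries(self, transcript_id: str, attr: str) -> float:
        return max(
            getattr(self.get(transcript_id, lib), attr) for lib in self.libraries
        )

    def library_depth(self, library: str) -> int:
        return sum(
            row.read_count
            for (_, lib), row in self._rows.items()
            if lib == library
        )


class SequenceSet:
    """id -> uppercase nucleotide string over {A, C, G, T, N}."""

    _ALPHABET = set("ACGTN")

    def __init__(self, sequences: Mapping[str, str] | None = None):
        self._seqs: Dict[str, str] = {}
        if sequences:
            for sid, seq in sequences.items():
                self.add(sid, seq)

    def add(self, seq_id: str, seq: str) -> None:
        if seq_id in self._seqs:
            raise ValueError(f"duplicate sequence id {seq_id!r}")
        seq = seq.upper()
        if set(seq) - self._ALPHABET:
            bad = sorted(set(seq) - self._ALPHABET)
            raise ValueError(f"sequence {seq_id!r} has invalid characters {bad}")
        self._seqs[seq_id] = seq

    def __getitem__(self, seq_id: str) -> str:
        try:
            return self._seqs[seq_id]
        except KeyError:
            raise KeyError(f"no sequence for id {seq_id!r}") from None

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def ids(self) -> List[str]:
        return sorted(self._seqs)

    def items(self) -> Iterator[Tuple[str, str]]:
        return iter(sorted(self._seqs.items()))


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(raw: str, lineno: int) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(
    path: str | Path,
    scaffold_lengths: Mapping[str, int],
    biotypes: Mapping[str, str] | None = None,
) -> Tuple[Annotation, List[TranscriptModel], int]:
    """Parse exon features from a GTF into the internal model.

    GTF 1-based inclusive coordinates become 0-based half-open.  Exons are
    grouped per transcript (sorted by start) and transcripts per gene.
    ``biotypes`` maps transcript_id to a biotype; the GTF's own
    ``transcript_biotype`` attribute is honoured when present, default
    ``coding``.  Records with strand '.' are rejected (counted, warning left
    to the caller via the returned count).

    Returns (annotation, transcripts ordered by id, n_rejected_strandless).
    """
    exons_by_tx: Dict[str, List[GenomicInterval]] = {}
    gene_of_tx: Dict[str, str] = {}
    biotype_of_tx: Dict[str, str] = {}
    n_rejected = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, raw = fields
            if feature != "exon":
                continue
            if strand == ".":
                n_rejected += 1
                continue
            if strand not in VALID_STRANDS:
                raise GtfParseError(f"line {lineno}: invalid strand {strand!r}")
            if chrom not in scaffold_lengths:
                raise GtfParseError(f"line {lineno}: unknown scaffold {chrom!r}")
            attrs = _parse_gtf_attributes(raw, lineno)
            for required in ("transcript_id", "gene_id"):
                if required not in attrs:
                    raise GtfParseError(
                        f"line {lineno}: missing required attribute {required!r}"
                    )
            tid = attrs["transcript_id"]
            start = int(start_s) - 1  # to 0-based half-open
            end = int(end_s)
            exons_by_tx.setdefault(tid, []).append(
                GenomicInterval(chrom, start, end, strand)
            )
            gene_of_tx[tid] = attrs["gene_id"]
            if "transcript_biotype" in attrs:
                biotype_of_tx[tid] = attrs["transcript_biotype"]

    transcripts = []
    for tid in sorted(exons_by_tx):
        biotype = biotype_of_tx.get(tid, "coding")
        if biotypes and tid in biotypes:
            biotype = biotypes[tid]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_of_tx[tid],
                exons=exons_by_tx[tid],
                biotype=biotype,
            )
        )

    by_gene: Dict[str, List[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    genes = {gid: GeneModel(gid, txs) for gid, txs in by_gene.items()}
    annotation = Annotation(dict(scaffold_lengths), genes)
    return annotation, transcripts, n_rejected


def write_gtf(path: str | Path, transcripts: Iterable[TranscriptModel]) -> None:
    """Serialize exon features back to GTF (the read_gtf inverse)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: t.transcript_id):
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'transcript_biotype "{t.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [
                            e.chrom,
                            "lnckit",
                            "exon",
                            str(e.start + 1),  # back to 1-based inclusive
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Scaffold lengths, FASTA
# ---------------------------------------------------------------------------

def read_scaffold_lengths(path: str | Path) -> Dict[str, int]:
    """Two-column TSV (chrom, length); .fai-style extra columns are ignored."""
    out: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"scaffold lengths line {lineno}: need 2 columns")
            out[fields[0]] = int(fields[1])
    return out


def write_scaffold_lengths(path: str | Path, lengths: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(lengths):
            fh.write(f"{chrom}\t{lengths[chrom]}\n")


def read_fasta(path: str | Path) -> SequenceSet:
    """Plain FASTA; the id is the first whitespace token of the header."""
    seqs = SequenceSet()
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            seqs.add(header.split()[0], seq)
    return seqs


def write_fasta(path: str | Path, seqs: SequenceSet, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Expression table and generic TSV
# ---------------------------------------------------------------------------

_EXPR_HEADER = ["transcript_id", "library", "read_count", "fpkm", "coverage"]


def read_expression_table(
    path: str | Path, libraries: Sequence[str] = LIBRARIES
) -> ExpressionTable:
    table = ExpressionTable(libraries)
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _EXPR_HEADER:
            raise ValueError(
                f"expression table header must be {_EXPR_HEADER}, "
                f"got {reader.fieldnames}"
            )
        for rec in reader:
            table.set(
                rec["transcript_id"],
                rec["library"],
                ExpressionRow(
                    read_count=int(rec["read_count"]),
                    fpkm=float(rec["fpkm"]),
                    coverage=float(rec["coverage"]),
                ),
            )
    return table


def write_expression_table(path: str | Path, table: ExpressionTable) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_EXPR_HEADER) + "\n")
        for tid in table.transcript_ids():
            for lib in table.libraries:
                row = table.get(tid, lib)
                fh.write(
                    f"{tid}\t{lib}\t{row.read_count}\t"
                    f"{row.fpkm:.6g}\t{row.coverage:.6g}\n"
                )


def write_tsv(path: str | Path, header: Sequence[str],
              rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_tsv(path: str | Path) -> Tuple[List[str], List[List[str]]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.rstrip("\n")]
    if not lines:
        raise ValueError(f"{path}: empty TSV")
    header = lines[0].split("\t")
    return header, [ln.split("\t") for ln in lines[1:]]


def read_id_set(path: str | Path, column: str = "transcript_id") -> Set[str]:
    """First-column id set from a headered TSV (e.g. protein-evidence list)."""
    header, rows = read_tsv(path)
    if column not in header:
        raise ValueError(f"{path}: missing column {column!r}")
    i = header.index(column)
    return {row[i] for row in rows}


def read_pair_table(path: str | Path, col_a: str, col_b: str) -> List[Tuple[str, str]]:
    """Two named columns from a headered TSV, row order preserved."""
    header, rows = read_tsv(path)
    for col in (col_a, col_b):
        if col not in header:
            raise ValueError(f"{path}: missing column {col!r}")
    ia, ib = header.index(col_a), header.index(col_b)
    return [(row[ia], row[ib]) for row in rows]


# ---------------------------------------------------------------------------
# BED output for classified lncRNAs
# ---------------------------------------------------------------------------

def write_classified_bed(path: str | Path, records: Iterable) -> None:
    """BED6: one line per transcript, ``id|class`` in the name field, score 0.

    ``records`` are (TranscriptModel, class_name) pairs or objects with
    ``transcript`` and ``lnc_class`` attributes.
    """
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                t, cls = rec
            else:
                t, cls = rec.transcript, rec.lnc_class
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t"
                f"{t.transcript_id}|{cls}\t0\t{t.strand}\n"
            )
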