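"""Synthetic dataset generator with machine-readable planted ground truth.

Lays out multi-exon coding genes in fixed-width territories on several
scaffolds and plants, per territory, at most one lncRNA of a known
positional class plus (in a separate zone) transcripts that each violate
exactly one filter rule.  Planting respects the classifier's decision
margins, so the true class of every planted lncRNA is unambiguous:

- sense/antisense lncRNAs overlap one coding exon on the same/opposite
  strand (sense plants carry the ``known_lncRNA`` biotype so they survive
  the sense-overlap filter step);
- intronic lncRNAs sit fully inside the first intron;
- bidirectional lncRNAs start divergently 200-900 bp from the gene TSS;
- intergenic lncRNAs sit 1100-6000 bp downstream of the gene span (> 1 kb
  from every TSS, inside the 10-kb apcGene window).

Three pooled stage libraries (E/P/L) get Poisson counts around
depth-scaled expected abundances; planted fold changes multiply the
expected abundance of the second library of the contrast.  Hairpins are
embedded verbatim (and with 12/80 evenly spread substitutions as planted
negatives) into host lncRNAs; a miRNA-target table wires planted ceRNA
triples and one high-degree hub miRNA.

One seed, one byte stream: all randomness flows from a single
``numpy.random.default_rng(seed)`` and every output is written in sorted
order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .annotation_io import (
    Annotation,
    ExpressionRow,
    ExpressionTable,
    GenomicInterval,
    SequenceSet,
    TranscriptModel,
    write_expression_table,
    write_fasta,
    write_gtf,
    write_scaffold_lengths,
    write_tsv,
)
from .filter_cascade import reverse_complement, scan_longest_orf

CLASS_NAMES = ("sense", "antisense", "intronic", "bidirectional", "intergenic")

FAILURE_RULES = (
    "sense_exon_overlap",
    "min_length",
    "min_exons",
    "min_coverage",
    "min_fpkm",
    "orf",
    "protein_evidence",
    "scaffold_end",
)

_SCAFFOLD_MARGIN = 5000
_GENE_OFFSET = 12000       # gene start within its territory
_FAILURE_ZONE = 26000      # failure transcripts live past this offset
_MIN_TERRITORY = 29000

# 12 substitution positions spread so every >=73-nt window of an 80-nt
# hairpin keeps >= 10 mismatches (identity stays below 0.90 even after
# local-alignment end trimming)
_MUTATION_POSITIONS = (3, 10, 16, 23, 29, 36, 42, 49, 55, 62, 68, 75)

_BASES = np.array(list("ACGT"))
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


class GeometryError(ValueError):
    """Planted geometry impossible for the requested configuration."""


@dataclass
class SimConfig:
    seed: int = 1
    n_scaffolds: int = 4
    scaffold_length: int = 300_000
    n_coding_genes: int = 40
    planted_class_counts: Dict[str, int] = field(
        default_factory=lambda: {
            "sense": 4,
            "antisense": 6,
            "intronic": 6,
            "bidirectional": 4,
            "intergenic": 8,
        }
    )
    n_de_lncrnas: int = 6
    n_de_mrnas: int = 10
    de_log2fc: float = 2.0
    library_depths: Dict[str, int] = field(
        default_factory=lambda: {"E": 200_000, "P": 200_000, "L": 200_000}
    )
    n_hairpins_embedded: int = 4
    n_hairpins_mutated: int = 3
    n_hairpin_decoys: int = 3
    hairpin_length: int = 80
    n_cerna_triples: int = 6
    n_filter_failures_per_rule: int = 3

    def __post_init__(self) -> None:
        for name in CLASS_NAMES:
            self.planted_class_counts.setdefault(name, 0)
        numeric = [
            self.n_scaffolds, self.scaffold_length, self.n_coding_genes,
            self.n_de_lncrnas, self.n_de_mrnas, self.n_hairpins_embedded,
            self.n_hairpins_mutated, self.n_hairpin_decoys,
            self.hairpin_length, self.n_cerna_triples,
            self.n_filter_failures_per_rule,
        ] + list(self.planted_class_counts.values()) + list(
            self.library_depths.values()
        )
        if any(v < 0 for v in numeric):
            raise ValueError("all config counts must be >= 0")
        if abs(self.de_log2fc) < 1:
            raise ValueError("planted |log2fc| must be >= 1")
        if set(self.planted_class_counts) != set(CLASS_NAMES):
            raise ValueError(f"unknown planted class in {self.planted_class_counts}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            name: getattr(self, name) for name in sorted(self.__dataclass_fields__)
        }


@dataclass
class _Plant:
    transcript: TranscriptModel
    lnc_class: Optional[str] = None       # planted positional class
    failure_rule: Optional[str] = None    # planted first-failing filter rule
    territory_gene: Optional[str] = None


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _long_orf(rng: np.random.Generator, n_codons: int = 150) -> str:
    codons = [
        _NON_STOP_CODONS[i]
        for i in rng.integers(0, len(_NON_STOP_CODONS), n_codons)
    ]
    return "ATG" + "".join(codons) + "TAA"


def _orf_safe_seq(
    rng: np.random.Generator,
    length: int,
    embed: Sequence[Tuple[int, str]] = (),
    max_orf_aa: int = 100,
    max_tries: int = 200,
) -> str:
    """Random sequence with fixed embedded segments and no large ORF."""
    for _ in range(max_tries):
        seq = list(_rand_seq(rng, length))
        for offset, segment in embed:
            seq[offset : offset + len(segment)] = segment
        out = "".join(seq)
        if scan_longest_orf(out) <= max_orf_aa:
            return out
    raise GeometryError("could not draw an ORF-free sequence")


def _mutate(rng: np.random.Generator, seq: str,
            positions: Sequence[int]) -> str:
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


class _Simulator:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.scaffold_lengths = {
            f"scaffold{i + 1}": config.scaffold_length
            for i in range(config.n_scaffolds)
        }
        self.transcripts: List[TranscriptModel] = []
        self.plants: List[_Plant] = []
        self.sequences: Dict[str, str] = {}
        self.ground_truth: dict = {}

    # -- geometry ----------------------------------------------------------

    def _territories(self) -> List[Tuple[str, int, int]]:
        cfg = self.cfg
        per = -(-cfg.n_coding_genes // cfg.n_scaffolds)  # ceil
        usable = cfg.scaffold_length - 2 * _SCAFFOLD_MARGIN
        width = usable // per if per else usable
        if width < _MIN_TERRITORY:
            raise GeometryError(
                f"territory width {width} < {_MIN_TERRITORY}; enlarge "
                "scaffolds or reduce gene count"
            )
        out = []
        i = 0
        for s in range(cfg.n_scaffolds):
            chrom = f"scaffold{s + 1}"
            for j in range(per):
                if i >= cfg.n_coding_genes:
                    break
                out.append((chrom, _SCAFFOLD_MARGIN + j * width, width))
                i += 1
        return out

    def _make_gene(self, idx: int, chrom: str, t0: int) -> TranscriptModel:
        rng = self.rng
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        n_ex = 3
        exon_lens = rng.integers(300, 601, n_ex)
        intron_lens = rng.integers(1600, 2401, n_ex - 1)
        pos = t0 + _GENE_OFFSET
        exons = []
        for k in range(n_ex):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand))
            pos += int(exon_lens[k])
            if k < n_ex - 1:
                pos += int(intron_lens[k])
        gid = f"gene{idx:03d}"
        return TranscriptModel(f"{gid}.t1", gid, exons, biotype="coding")

    def _lnc_exons(
        self, chrom: str, strand: str, start: int,
        lens: Tuple[int, int] = (300, 300), gap: int = 200,
    ) -> List[GenomicInterval]:
        a = GenomicInterval(chrom, start, start + lens[0], strand)
        b = GenomicInterval(
            chrom, start + lens[0] + gap, start + lens[0] + gap + lens[1], strand
        )
        return [a, b]

    def _plant_lnc(self, lnc_class: str, idx: int,
                   gene: TranscriptModel) -> TranscriptModel:
        rng = self.rng
        chrom = gene.chrom
        tid = f"lnc_{lnc_class}_{idx:02d}"
        gid = f"G_{tid}"
        other = "-" if gene.strand == "+" else "+"
        if lnc_class in ("sense", "antisense"):
            strand = gene.strand if lnc_class == "sense" else other
            # first exon overlaps the gene's middle exon by ~150 bp
            mid = gene.exons[1]
            start = mid.start - 150
            exons = self._lnc_exons(chrom, strand, start)
        elif lnc_class == "intronic":
            intron = gene.introns()[0]
            strand = gene.strand if rng.integers(0, 2) == 0 else other
            start = intron.start + 200
            exons = self._lnc_exons(chrom, strand, start, lens=(140, 140), gap=60)
            if exons[-1].end >= intron.end:
                raise GeometryError(f"intron too short for {tid}")
        elif lnc_class == "bidirectional":
            d = int(rng.integers(200, 901))
            strand = other
            if gene.strand == "+":
                # lnc on '-', TSS (= end - 1) at gene TSS - d
                end = gene.tss - d + 1
                exons = self._lnc_exons(chrom, strand, end - 800)
            else:
                start = gene.tss + d
                exons = self._lnc_exons(chrom, strand, start)
        elif lnc_class == "intergenic":
            gap = int(rng.integers(1100, 6001))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            exons = self._lnc_exons(chrom, strand, gene.end + gap)
        else:
            raise ValueError(lnc_class)
        biotype = "known_lncRNA" if lnc_class == "sense" else "candidate_noncoding"
        return TranscriptModel(tid, gid, exons, biotype=biotype)

    def _plant_failure(self, rule: str, idx: int, gene: TranscriptModel,
                       t0: int, width: int, slot: int) -> TranscriptModel:
        chrom = gene.chrom
        tid = f"fail_{rule}_{idx:02d}"
        gid = f"G_{tid}"
        zone = t0 + _FAILURE_ZONE + slot * 900
        if zone + 700 > t0 + width:
            raise GeometryError("failure zone exhausted; add genes or scaffolds")
        if rule == "sense_exon_overlap":
            first = gene.exons[0]
            exons = [
                GenomicInterval(chrom, first.start - 50, first.start + 100, gene.strand),
                GenomicInterval(chrom, first.start + 150, first.start + 350, gene.strand),
            ]
        elif rule == "min_length":
            exons = [
                GenomicInterval(chrom, zone, zone + 100, "+"),
                GenomicInterval(chrom, zone + 120, zone + 219, "+"),
            ]
        elif rule == "min_exons":
            exons = [GenomicInterval(chrom, zone, zone + 400, "+")]
        elif rule == "scaffold_end":
            s = 500 + (idx - 1) * 600  # keep same-scaffold plants apart
            if s >= 2000 or s + 500 > _SCAFFOLD_MARGIN:
                raise GeometryError("too many scaffold_end failures to plant")
            exons = [
                GenomicInterval(chrom, s, s + 200, "+"),
                GenomicInterval(chrom, s + 300, s + 500, "+"),
            ]
        else:  # expression-, ORF- or evidence-level failures: normal geometry
            exons = self._lnc_exons(chrom, "+", zone, lens=(250, 250), gap=100)
        return TranscriptModel(tid, gid, exons, biotype="candidate_noncoding")

    # -- main build --------------------------------------------------------

    def build(self) -> None:
        cfg = self.cfg
        n_planted = sum(cfg.planted_class_counts.values())
        if n_planted > cfg.n_coding_genes:
            raise GeometryError(
                f"{n_planted} planted lncRNAs need {n_planted} gene "
                f"territories, only {cfg.n_coding_genes} genes configured"
            )
        if cfg.planted_class_counts["intronic"] and cfg.n_coding_genes == 0:
            raise GeometryError("intronic lncRNAs need coding genes with introns")

        territories = self._territories()
        genes = [
            self._make_gene(i, chrom, t0)
            for i, (chrom, t0, _w) in enumerate(territories)
        ]
        self.transcripts.extend(genes)

        # one planted lncRNA per territory, in declared class order
        plan: List[Tuple[str, int]] = []
        for cls in CLASS_NAMES:
            for k in range(cfg.planted_class_counts[cls]):
                plan.append((cls, k + 1))
        for (cls, k), gene in zip(plan, genes):
            t = self._plant_lnc(cls, k, gene)
            self.transcripts.append(t)
            self.plants.append(
                _Plant(t, lnc_class=cls, territory_gene=gene.gene_id)
            )

        # planted single-rule filter failures, round-robin over territories
        slot_used = [0] * len(territories)
        fail_i = 0
        for rule in FAILURE_RULES:
            for k in range(cfg.n_filter_failures_per_rule):
                ti = fail_i % len(territories)
                chrom, t0, w = territories[ti]
                t = self._plant_failure(
                    rule, k + 1, genes[ti], t0, w, slot_used[ti]
                )
                slot_used[ti] += 1
                fail_i += 1
                self.transcripts.append(t)
                self.plants.append(_Plant(t, failure_rule=rule))

        self._build_wiring(genes)
        self._build_sequences()
        self._build_expression()
        self._build_terms()
        self._finish_ground_truth()

    def _build_wiring(self, genes: List[TranscriptModel]) -> None:
        cfg = self.cfg
        lnc_plants = [p for p in self.plants if p.lnc_class is not None]

        # ceRNA triples: lncRNAs that will carry a link into the network
        eligible = [
            p for p in lnc_plants
            if p.lnc_class in ("antisense", "bidirectional", "intergenic")
        ]
        if cfg.n_cerna_triples > len(eligible):
            raise GeometryError(
                f"{cfg.n_cerna_triples} ceRNA triples need as many "
                f"linkable lncRNAs, only {len(eligible)} planted"
            )
        triples: List[Tuple[str, str, str]] = []
        for i, p in enumerate(eligible[: cfg.n_cerna_triples]):
            mirna = f"mir_{i + 1:03d}"
            triples.append((p.transcript.transcript_id, mirna, p.territory_gene))
        self.triples = triples

        hub_span = min(3, len(triples))
        self.hub_mirna = "mir_hub" if hub_span >= 2 else None

        target_rows: List[Tuple[str, str]] = []
        for lnc, mirna, mrna in triples:
            target_rows.append((mirna, lnc))
            target_rows.append((mirna, mrna))
        if self.hub_mirna:
            for lnc, _m, mrna in triples[:hub_span]:
                target_rows.append((self.hub_mirna, lnc))
                target_rows.append((self.hub_mirna, mrna))
        target_rows.append(("mir_bad", "UNKNOWN_TARGET_1"))
        target_rows.append(("mir_bad", "UNKNOWN_TARGET_2"))
        self.target_rows = sorted(target_rows)
        self.n_bad_target_rows = 2

        # differential expression plan
        de_lncs = [p.transcript.transcript_id for p in lnc_plants[: cfg.n_de_lncrnas]]
        partner_genes = sorted({mrna for _l, _m, mrna in triples})
        if cfg.n_de_mrnas < len(partner_genes):
            raise GeometryError(
                "n_de_mrnas must cover every ceRNA partner gene "
                f"({len(partner_genes)} needed)"
            )
        extra = [
            g.gene_id for g in genes if g.gene_id not in partner_genes
        ][: cfg.n_de_mrnas - len(partner_genes)]
        de_genes = sorted(partner_genes + extra)
        self.de_plan: Dict[str, float] = {}
        for i, tid in enumerate(de_lncs):
            self.de_plan[tid] = cfg.de_log2fc * (1 if i % 2 == 0 else -1)
        for i, gid in enumerate(de_genes):
            self.de_plan[f"{gid}.t1"] = cfg.de_log2fc * (1 if i % 2 == 0 else -1)
        self.de_lncs, self.de_genes = de_lncs, de_genes

        # antisense lncRNAs get a planted complementarity segment against
        # their territory gene's transcript (their only route to a link)
        self.duplex_plan = [
            (p.transcript.transcript_id, f"{p.territory_gene}.t1")
            for p in lnc_plants
            if p.lnc_class == "antisense"
        ]

    def _build_sequences(self) -> None:
        cfg = self.cfg
        rng = self.rng

        for t in self.transcripts:
            if t.biotype == "coding":
                self.sequences[t.transcript_id] = _rand_seq(rng, t.length)

        # hairpins
        self.hairpins: Dict[str, str] = {}
        n_hp = cfg.n_hairpins_embedded + cfg.n_hairpins_mutated
        for i in range(n_hp):
            self.hairpins[f"hp_{i + 1:02d}"] = _rand_seq(rng, cfg.hairpin_length)
        for i in range(cfg.n_hairpin_decoys):
            self.hairpins[f"hp_decoy_{i + 1:02d}"] = _rand_seq(
                rng, cfg.hairpin_length
            )

        lnc_plants = [p for p in self.plants if p.lnc_class is not None]
        n_hosts = n_hp
        if n_hosts > len(lnc_plants):
            raise GeometryError("more hairpin embeddings than planted lncRNAs")
        embeddings: List[dict] = []
        embed_for: Dict[str, Tuple[int, str]] = {}
        for i in range(n_hp):
            hp_id = f"hp_{i + 1:02d}"
            host = lnc_plants[i].transcript
            mutated = i >= cfg.n_hairpins_embedded
            seg = self.hairpins[hp_id]
            if mutated:
                positions = [
                    p for p in _MUTATION_POSITIONS if p < len(seg)
                ]
                seg = _mutate(rng, seg, positions)
            offset = int(
                rng.integers(50, host.length - cfg.hairpin_length - 50)
            )
            embed_for[host.transcript_id] = (offset, seg)
            embeddings.append(
                {
                    "lnc_id": host.transcript_id,
                    "hairpin_id": hp_id,
                    "offset": offset,
                    "mutated": mutated,
                    "n_mutations": len(_MUTATION_POSITIONS) if mutated else 0,
                }
            )
        self.embeddings = embeddings

        duplex_for: Dict[str, Tuple[int, str]] = {}
        duplex_truth: List[dict] = []
        for lnc_id, mrna_tid in self.duplex_plan:
            mseq = self.sequences[mrna_tid]
            mstart = int(rng.integers(0, len(mseq) - 30))
            seg = reverse_complement(mseq[mstart : mstart + 30])
            duplex_truth.append(
                {"lnc_id": lnc_id, "mrna_transcript": mrna_tid,
                 "mrna_offset": mstart, "length": 30}
            )
            duplex_for[lnc_id] = (0, seg)  # offset fixed later
        self.duplex_truth = duplex_truth

        for p in self.plants:
            t = p.transcript
            embed: List[Tuple[int, str]] = []
            if t.transcript_id in embed_for:
                embed.append(embed_for[t.transcript_id])
            if t.transcript_id in duplex_for:
                _, seg = duplex_for[t.transcript_id]
                # keep clear of any hairpin embedding at the front
                offset = t.length - len(seg) - 10
                embed.append((offset, seg))
            if p.failure_rule == "orf":
                self.sequences[t.transcript_id] = _orf_safe_seq(
                    rng, t.length, embed=[(20, _long_orf(rng))], max_orf_aa=10**9
                )
                continue
            self.sequences[t.transcript_id] = _orf_safe_seq(
                rng, t.length, embed=embed
            )

    def _build_expression(self) -> None:
        cfg = self.cfg
        rng = self.rng
        tids = [t.transcript_id for t in self.transcripts]
        weights = rng.lognormal(mean=0.0, sigma=0.5, size=len(tids))
        wsum = float(weights.sum())
        lengths = {t.transcript_id: t.length for t in self.transcripts}
        fate = {
            p.transcript.transcript_id: p.failure_rule
            for p in self.plants
            if p.failure_rule
        }

        table = ExpressionTable(tuple(sorted(cfg.library_depths)))
        counts: Dict[Tuple[str, str], int] = {}
        realized: Dict[str, int] = {}
        for lib in table.libraries:
            depth = cfg.library_depths[lib]
            total = 0
            for tid, w in zip(tids, weights):
                if fate.get(tid) == "min_fpkm":
                    c = 0
                else:
                    fc = 1.0
                    if tid in self.de_plan and lib == "P":
                        fc = 2.0 ** self.de_plan[tid]
                    c = int(rng.poisson(depth * (w / wsum) * fc))
                counts[(tid, lib)] = c
                total += c
            realized[lib] = total

        for tid in tids:
            for lib in table.libraries:
                c = counts[(tid, lib)]
                if c == 0:
                    fpkm = 0.0
                else:
                    fpkm = c / (
                        (lengths[tid] / 1000.0) * (realized[lib] / 1e6)
                    )
                if fate.get(tid) == "min_coverage":
                    cov = float(rng.uniform(0.0, 0.75))
                else:
                    cov = float(rng.uniform(0.85, 1.0))
                table.set(tid, lib, ExpressionRow(c, round(fpkm, 6), round(cov, 6)))
        self.expression = table

    def _build_terms(self) -> None:
        rng = self.rng
        gene_ids = sorted(
            {t.gene_id for t in self.transcripts if t.biotype == "coding"}
        )
        rows: List[Tuple[str, str]] = []
        planted = sorted(self.de_genes)[: min(5, len(self.de_genes))]
        for g in planted:
            rows.append(("TERM_planted", g))
        for i in range(8):
            term = f"TERM_bg_{i + 1:02d}"
            pick = rng.choice(len(gene_ids), size=min(6, len(gene_ids)),
                              replace=False)
            for j in sorted(pick):
                rows.append((term, gene_ids[j]))
        self.term_rows = sorted(set(rows))
        self.enriched_terms = ["TERM_planted"] if planted else []

    def _finish_ground_truth(self) -> None:
        retained = sorted(
            p.transcript.transcript_id
            for p in self.plants
            if p.lnc_class is not None
        )
        self.ground_truth = {
            "classes": {
                p.transcript.transcript_id: p.lnc_class
                for p in self.plants
                if p.lnc_class
            },
            "territory_gene": {
                p.transcript.transcript_id: p.territory_gene
                for p in self.plants
                if p.lnc_class
            },
            "known_lncrna_ids": sorted(
                p.transcript.transcript_id
                for p in self.plants
                if p.transcript.biotype == "known_lncRNA"
            ),
            "filter_failures": {
                p.transcript.transcript_id: p.failure_rule
                for p in self.plants
                if p.failure_rule
            },
            "retained_ids": retained,
            "de": {
                tid: {"contrast": "E:P", "log2fc": lfc}
                for tid, lfc in sorted(self.de_plan.items())
            },
            "de_lncrnas": sorted(self.de_lncs),
            "de_genes": sorted(self.de_genes),
            "hairpin_embeddings": self.embeddings,
            "duplex_segments": self.duplex_truth,
            "triples": [list(t) for t in self.triples],
            "hub_mirna": self.hub_mirna,
            "enriched_terms": self.enriched_terms,
            "n_bad_target_rows": self.n_bad_target_rows,
            "config": self.cfg.to_dict(),
        }

    # -- emission ----------------------------------------------------------

    def write(self, outdir: str | Path) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": outdir / "annotation.gtf",
            "scaffolds": outdir / "scaffolds.tsv",
            "transcripts_fasta": outdir / "transcripts.fa",
            "hairpins_fasta": outdir / "hairpins.fa",
            "expression": outdir / "expression.tsv",
            "evidence": outdir / "evidence.tsv",
            "targets": outdir / "targets.tsv",
            "terms": outdir / "terms.tsv",
            "ground_truth": outdir / "ground_truth.json",
        }
        write_gtf(paths["gtf"], self.transcripts)
        write_scaffold_lengths(paths["scaffolds"], self.scaffold_lengths)
        write_fasta(paths["transcripts_fasta"], SequenceSet(self.sequences))
        write_fasta(paths["hairpins_fasta"], SequenceSet(self.hairpins))
        write_expression_table(paths["expression"], self.expression)
        evidence_ids = sorted(
            p.transcript.transcript_id
            for p in self.plants
            if p.failure_rule == "protein_evidence"
        )
        write_tsv(
            paths["evidence"],
            ["transcript_id", "source"],
            [(tid, "planted") for tid in evidence_ids],
        )
        write_tsv(paths["targets"], ["mirna_id", "target_id"], self.target_rows)
        write_tsv(paths["terms"], ["term_id", "gene_id"], self.term_rows)
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def simulate(config: SimConfig, outdir: str | Path) -> Tuple[Dict[str, Path], dict]:
    """Generate the dataset; nothing is written if generation fails."""
    sim = _Simulator(config)
    sim.build()  # raises GeometryError before any file exists
    paths = sim.write(outdir)
    return paths, sim.ground_truth
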