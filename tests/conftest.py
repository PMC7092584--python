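from __future__ import annotations

import numpy as np
import pytest

from lnckit.annotation_io import (
    Annotation,
    ExpressionRow,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from lnckit.cli import PipelineConfig, run_all
from lnckit.synthetic_data import SimConfig, simulate


def make_transcript(tid, chrom, strand, exons, gene_id=None, biotype="coding"):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id or f"G_{tid}",
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        biotype=biotype,
    )


def make_annotation(transcripts, scaffold_lengths=None):
    if scaffold_lengths is None:
        chroms = {t.chrom for t in transcripts}
        scaffold_lengths = {c: 10_000_000 for c in chroms}
    by_gene = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    genes = {gid: GeneModel(gid, txs) for gid, txs in by_gene.items()}
    return Annotation(scaffold_lengths, genes)


def uniform_expression(transcript_ids, read_count=100, fpkm=5.0, coverage=0.9,
                       libraries=("E", "L", "P")):
    table = ExpressionTable(libraries)
    for tid in transcript_ids:
        for lib in libraries:
            table.set(tid, lib, ExpressionRow(read_count, fpkm, coverage))
    return table


def random_annotation(rng, n_genes=30, chrom_len=500_000, n_chroms=2):
    """Random multi-exon coding genes for index/oracle comparisons."""
    transcripts = []
    for i in range(n_genes):
        chrom = f"c{rng.integers(1, n_chroms + 1)}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        start = int(rng.integers(0, chrom_len - 20_000))
        exons = []
        pos = start
        for _ in range(int(rng.integers(1, 4))):
            length = int(rng.integers(100, 800))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(200, 3000))
        transcripts.append(
            make_transcript(f"g{i:03d}.t1", chrom, strand, exons,
                            gene_id=f"g{i:03d}")
        )
    lengths = {f"c{k}": chrom_len for k in range(1, n_chroms + 1)}
    return make_annotation(transcripts, lengths), transcripts


def gene_dicts(annotation):
    """Annotation re-expressed as plain dicts for the test oracles."""
    out = []
    for gid in sorted(annotation.genes):
        g = annotation.genes[gid]
        coding_exons = []
        introns = []
        for t in g.transcripts:
            if t.biotype == "coding":
                coding_exons.extend((e.start, e.end) for e in t.exons)
                introns.extend((i.start, i.end) for i in t.introns())
        out.append(
            {
                "gene_id": gid,
                "strand": g.strand,
                "span": (g.start, g.end),
                "tss": g.tss,
                "coding_exons": coding_exons,
                "introns": introns,
                "is_coding": g.is_coding,
                "chrom": g.chrom,
            }
        )
    return out


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simdata")
    paths, truth = simulate(SimConfig(seed=1), outdir)
    return paths, truth


@pytest.fixture(scope="session")
def pipeline_run(sim_dataset, tmp_path_factory):
    paths, truth = sim_dataset
    outdir = tmp_path_factory.mktemp("pipeline")
    manifest = run_all(
        paths["gtf"],
        paths["scaffolds"],
        paths["transcripts_fasta"],
        paths["hairpins_fasta"],
        paths["expression"],
        paths["evidence"],
        paths["targets"],
        paths["terms"],
        outdir,
        PipelineConfig(),
    )
    return outdir, manifest, truth
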