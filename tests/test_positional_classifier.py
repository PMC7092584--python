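import numpy as np
import pytest

from lnckit.annotation_io import read_gtf, read_scaffold_lengths
from lnckit.positional_classifier import (
    ApcLink,
    LncClass,
    classify,
    classify_all,
    find_apc_genes,
)
from conftest import gene_dicts, make_annotation, make_transcript
from oracles import apc_oracle, classify_oracle


def _coding(tid, chrom, strand, exons, gene_id=None):
    return make_transcript(tid, chrom, strand, exons, gene_id=gene_id,
                           biotype="coding")


def _lnc(tid, chrom, strand, exons):
    return make_transcript(tid, chrom, strand, exons,
                           biotype="candidate_noncoding")


class TestClassifyDefinitions:
    def test_sense_exon_overlap_same_strand(self):
        gene = _coding("g1.t1", "c1", "+", [(150, 250), (900, 1100)], "g1")
        lnc = _lnc("l1", "c1", "+", [(100, 200), (400, 500)])
        annotation = make_annotation([gene, lnc])
        c = classify(lnc, annotation)
        assert c.lnc_class is LncClass.SENSE
        assert c.evidence_gene_id == "g1"
        assert (c.evidence_interval.start, c.evidence_interval.end) == (150, 250)

    def test_antisense_exon_overlap_other_strand(self):
        gene = _coding("g1.t1", "c1", "+", [(150, 250), (900, 1100)], "g1")
        lnc = _lnc("l1", "c1", "-", [(100, 200), (400, 500)])
        annotation = make_annotation([gene, lnc])
        assert classify(lnc, annotation).lnc_class is LncClass.ANTISENSE

    def test_intronic_either_strand(self):
        gene = _coding("g1.t1", "c1", "+", [(100, 300), (900, 1200)], "g1")
        for strand in "+-":
            lnc = _lnc("l1", "c1", strand, [(400, 500), (600, 700)])
            annotation = make_annotation([gene, lnc])
            c = classify(lnc, annotation)
            assert c.lnc_class is LncClass.INTRONIC
            assert (c.evidence_interval.start, c.evidence_interval.end) == (300, 900)

    def test_no_genes_is_intergenic(self):
        lnc = _lnc("l1", "c1", "+", [(5000, 5200), (5400, 5600)])
        annotation = make_annotation([lnc])
        c = classify(lnc, annotation)
        assert c.lnc_class is LncClass.INTERGENIC
        assert c.evidence_gene_id is None

    def test_bidirectional_divergent_within_window(self):
        # lnc TSS at 5000 on '-', coding TSS at 5400 on '+': distance 400
        gene = _coding("g1.t1", "c1", "+", [(5400, 5800), (7000, 9000)], "g1")
        lnc = _lnc("l1", "c1", "-", [(4200, 4600), (4800, 5001)])
        assert lnc.tss == 5000
        annotation = make_annotation([gene, lnc])
        c = classify(lnc, annotation)
        assert c.lnc_class is LncClass.BIDIRECTIONAL
        assert c.evidence_gene_id == "g1"
        assert c.evidence_tss_distance == 400

    def test_convergent_orientation_not_bidirectional(self):
        # same distance but the lnc sits downstream, pointing at the gene
        gene = _coding("g1.t1", "c1", "+", [(5400, 5800), (7000, 9000)], "g1")
        lnc = _lnc("l1", "c1", "-", [(9200, 9400), (9600, 9800)])
        annotation = make_annotation([gene, lnc])
        assert classify(lnc, annotation).lnc_class is LncClass.INTERGENIC

    def test_sense_beats_intronic_priority(self):
        # exon overlap and intron containment for different genes: sense wins
        g1 = _coding("g1.t1", "c1", "+", [(100, 300), (2000, 2300)], "g1")
        g2 = _coding("g2.t1", "c1", "+", [(380, 420), (800, 900)], "g2")
        lnc = _lnc("l1", "c1", "+", [(390, 500), (600, 700)])
        annotation = make_annotation([g1, g2, lnc])
        c = classify(lnc, annotation)
        assert c.lnc_class is LncClass.SENSE
        assert c.evidence_gene_id == "g2"

    def test_unknown_scaffold_raises(self):
        gene = _coding("g1.t1", "c1", "+", [(100, 300)], "g1")
        lnc = _lnc("l1", "cX", "+", [(100, 200), (400, 500)])
        annotation = make_annotation([gene], {"c1": 10_000})
        with pytest.raises(ValueError, match="unknown scaffold"):
            classify(lnc, annotation)

    def test_tie_broken_by_smallest_gene_id(self):
        ga = _coding("gb.t1", "c1", "+", [(100, 300)], "gb")
        gb = _coding("ga.t1", "c1", "+", [(150, 350)], "ga")
        lnc = _lnc("l1", "c1", "+", [(200, 260), (400, 500)])
        annotation = make_annotation([ga, gb, lnc])
        assert classify(lnc, annotation).evidence_gene_id == "ga"


class TestApcGenes:
    def test_upstream_link_gap(self):
        gene = _coding("g1.t1", "c1", "+", [(400, 1000)], "g1")
        lnc = _lnc("l1", "c1", "+", [(5000, 5400), (5600, 6000)])
        annotation = make_annotation([gene, lnc])
        links = find_apc_genes(lnc, annotation)
        assert links == [ApcLink("l1", "g1", "upstream", 4000)]

    def test_minus_strand_swaps_sides(self):
        gene = _coding("g1.t1", "c1", "+", [(400, 1000)], "g1")
        lnc = _lnc("l1", "c1", "-", [(5000, 5400), (5600, 6000)])
        annotation = make_annotation([gene, lnc])
        assert find_apc_genes(lnc, annotation)[0].side == "downstream"

    @pytest.mark.parametrize("gap,expect", [(10_000, 1), (10_001, 0)])
    def test_window_boundary_inclusive(self, gap, expect):
        gene = _coding("g1.t1", "c1", "+", [(400, 1000)], "g1")
        start = 1000 + gap
        lnc = _lnc("l1", "c1", "+", [(start, start + 200), (start + 400, start + 600)])
        annotation = make_annotation([gene, lnc])
        assert len(find_apc_genes(lnc, annotation)) == expect

    def test_overlapping_gene_never_linked(self):
        gene = _coding("g1.t1", "c1", "+", [(5000, 5100), (6800, 7000)], "g1")
        lnc = _lnc("l1", "c1", "+", [(5500, 5700), (6000, 6200)])  # in intron
        annotation = make_annotation([gene, lnc])
        assert find_apc_genes(lnc, annotation) == []

    def test_random_layouts_equal_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n_genes = int(rng.integers(1, 8))
            transcripts = []
            pos = 1000
            for i in range(n_genes):
                pos += int(rng.integers(500, 12_000))
                length = int(rng.integers(300, 3000))
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                transcripts.append(
                    _coding(f"g{i}.t1", "c1", strand, [(pos, pos + length)], f"g{i}")
                )
                pos += length
            lnc_start = int(rng.integers(0, pos + 15_000))
            lnc_strand = "+" if rng.integers(0, 2) == 0 else "-"
            lnc = _lnc("l1", "c1", lnc_strand,
                       [(lnc_start, lnc_start + 200),
                        (lnc_start + 300, lnc_start + 500)])
            annotation = make_annotation(
                transcripts + [lnc], {"c1": pos + 40_000}
            )
            got = {
                l.side: (l.gene_id, l.gap_bp)
                for l in find_apc_genes(lnc, annotation)
            }
            want = apc_oracle(
                (lnc.start, lnc.end), lnc_strand, gene_dicts(annotation)
            )
            assert got == want


class TestProperties:
    def _flip(self, t):
        flipped = "-" if t.strand == "+" else "+"
        return make_transcript(
            t.transcript_id, t.chrom, flipped,
            [(e.start, e.end) for e in t.exons],
            gene_id=t.gene_id, biotype=t.biotype,
        )

    def test_planted_class_recovery(self, sim_dataset):
        paths, truth = sim_dataset
        lengths = read_scaffold_lengths(paths["scaffolds"])
        annotation, transcripts, _ = read_gtf(paths["gtf"], lengths)
        by_id = {t.transcript_id: t for t in transcripts}
        for tid, want in truth["classes"].items():
            got = classify(by_id[tid], annotation)
            assert got.lnc_class.value == want, tid

    def test_totality_and_exclusivity(self, sim_dataset):
        paths, truth = sim_dataset
        lengths = read_scaffold_lengths(paths["scaffolds"])
        annotation, transcripts, _ = read_gtf(paths["gtf"], lengths)
        by_id = {t.transcript_id: t for t in transcripts}
        lncs = [by_id[tid] for tid in truth["retained_ids"]]
        classified = classify_all(lncs, annotation)
        assert len(classified) == len(lncs)
        counts = {}
        for c in classified:
            counts[c.lnc_class] = counts.get(c.lnc_class, 0) + 1
        assert sum(counts.values()) == len(lncs)

    def test_strand_flip_antisymmetry(self, sim_dataset):
        # classification depends only on RELATIVE strand, so flipping the
        # lncRNA against the fixed annotation swaps sense<->antisense and
        # leaves the strand-free classes (intronic, intergenic) untouched;
        # flipping both sides at once would be the identity
        paths, truth = sim_dataset
        lengths = read_scaffold_lengths(paths["scaffolds"])
        annotation, transcripts, _ = read_gtf(paths["gtf"], lengths)
        by_id = {t.transcript_id: t for t in transcripts}
        swap = {
            LncClass.SENSE: LncClass.ANTISENSE,
            LncClass.ANTISENSE: LncClass.SENSE,
        }
        for tid in truth["retained_ids"]:
            before = classify(by_id[tid], annotation).lnc_class
            after = classify(self._flip(by_id[tid]), annotation).lnc_class
            if before in swap:
                assert after is swap[before], tid
            elif before in (LncClass.INTRONIC, LncClass.INTERGENIC):
                assert after is before, tid

    def test_oracle_equivalence_random_annotations(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            n_genes = int(rng.integers(1, 12))
            transcripts = []
            pos = 3000
            for i in range(n_genes):
                pos += int(rng.integers(300, 6000))
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                exons = []
                p = pos
                for _k in range(int(rng.integers(1, 4))):
                    length = int(rng.integers(150, 700))
                    exons.append((p, p + length))
                    p += length + int(rng.integers(400, 2500))
                transcripts.append(
                    _coding(f"g{i}.t1", "c1", strand, exons, f"g{i}")
                )
                pos = p
            for _q in range(12):
                ls = int(rng.integers(0, pos + 8000))
                lstrand = "+" if rng.integers(0, 2) == 0 else "-"
                e1 = (ls, ls + int(rng.integers(80, 400)))
                gap = int(rng.integers(50, 600))
                e2_start = e1[1] + gap
                e2 = (e2_start, e2_start + int(rng.integers(80, 400)))
                lnc = _lnc("lq", "c1", lstrand, [e1, e2])
                annotation = make_annotation(
                    transcripts + [lnc], {"c1": pos + 50_000}
                )
                got = classify(lnc, annotation).lnc_class.value
                want = classify_oracle(
                    [(e.start, e.end) for e in lnc.exons],
                    lstrand,
                    (lnc.start, lnc.end),
                    [g for g in gene_dicts(annotation) if g["gene_id"] != "G_lq"],
                )
                assert got == want
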