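import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnckit.annotation_io import ExpressionRow, ExpressionTable, SequenceSet
from lnckit.filter_cascade import (
    FilterConfig,
    apply_filter_cascade,
    build_step_predicates,
    scan_longest_orf,
)
from conftest import make_annotation, make_transcript, uniform_expression
from oracles import longest_orf_aa


class TestScanLongestOrf:
    def test_minimal_orf(self):
        assert scan_longest_orf("ATGAAATAG") == 2  # ATG AAA stop

    def test_no_atg(self):
        assert scan_longest_orf("CCCCCC") == 0

    def test_empty(self):
        assert scan_longest_orf("") == 0

    def test_open_ended_run_not_counted(self):
        assert scan_longest_orf("ATGAAAAAA") == 0

    def test_n_never_matches(self):
        # the would-be stop TAG is disrupted on neither strand by N in ATG
        assert scan_longest_orf("ANGAAATAG") == 0

    def test_reverse_strand_found(self):
        # revcomp of ATGAAATAG = CTATTTCAT
        assert scan_longest_orf("CTATTTCAT") == 2

    @settings(deadline=None, max_examples=50)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=120))
    def test_equals_enumeration_oracle(self, seq):
        assert scan_longest_orf(seq) == longest_orf_aa(seq)

    def test_random_900nt_equals_oracle(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(25):
            seq = "".join(bases[rng.integers(0, 4, 900)])
            assert scan_longest_orf(seq) == longest_orf_aa(seq)


class TestBoundaries:
    def test_length_199_removed_at_min_length(self):
        lnc = make_transcript("lnc1", "c1", "+", [(10_000, 10_100), (10_500, 10_599)])
        annotation = make_annotation([lnc], {"c1": 100_000})
        table = uniform_expression(["lnc1"])
        seqs = SequenceSet({"lnc1": "C" * lnc.length})
        retained, report = apply_filter_cascade([lnc], annotation, table, seqs)
        assert retained == []
        assert report.fate["lnc1"] == "min_length"
        assert lnc.length == 199

    def test_all_boundaries_retained(self):
        # length 200, 2 exons, max coverage 0.8, max FPKM 0.1, ORF 100 aa,
        # mid-scaffold, no evidence -> retained
        lnc = make_transcript(
            "lnc1", "c1", "+", [(10_000, 10_200), (10_500, 10_703)]
        )
        assert lnc.length == 403  # room for a 100-aa ORF
        annotation = make_annotation([lnc], {"c1": 100_000})
        table = ExpressionTable(("E", "L", "P"))
        for lib in ("E", "L", "P"):
            table.set("lnc1", lib, ExpressionRow(10, 0.1, 0.8))
        orf100 = "ATG" + "AAA" * 99 + "TAA"  # exactly 100 aa
        seqs = SequenceSet({"lnc1": (orf100 + "C" * 100)[: lnc.length]})
        assert scan_longest_orf(seqs["lnc1"]) == 100
        retained, report = apply_filter_cascade([lnc], annotation, table, seqs)
        assert retained == ["lnc1"]

    def test_orf_101_removed(self):
        lnc = make_transcript(
            "lnc1", "c1", "+", [(10_000, 10_200), (10_500, 10_706)]
        )
        annotation = make_annotation([lnc], {"c1": 100_000})
        table = uniform_expression(["lnc1"])
        orf101 = "ATG" + "AAA" * 100 + "TAA"
        seqs = SequenceSet({"lnc1": (orf101 + "C" * 100)[: lnc.length]})
        retained, report = apply_filter_cascade([lnc], annotation, table, seqs)
        assert retained == []
        assert report.fate["lnc1"] == "orf"

    @pytest.mark.parametrize(
        "start,expect_removed",
        [(2000, False), (1999, True)],
    )
    def test_scaffold_margin_strict(self, start, expect_removed):
        lnc = make_transcript(
            "lnc1", "c1", "+", [(start, start + 150), (start + 300, start + 450)]
        )
        annotation = make_annotation([lnc], {"c1": 100_000})
        table = uniform_expression(["lnc1"])
        seqs = SequenceSet({"lnc1": "C" * lnc.length})
        retained, report = apply_filter_cascade([lnc], annotation, table, seqs)
        assert (retained == []) is expect_removed
        if expect_removed:
            assert report.fate["lnc1"] == "scaffold_end"

    def test_known_lncrna_bypasses_sense_overlap(self):
        coding = make_transcript(
            "cod.t1", "c1", "+", [(10_000, 10_500), (12_000, 12_500)],
            gene_id="cod", biotype="coding",
        )
        known = make_transcript(
            "known1", "c1", "+", [(10_200, 10_400), (10_600, 10_800)],
            biotype="known_lncRNA",
        )
        novel = make_transcript(
            "novel1", "c1", "+", [(10_200, 10_400), (10_600, 10_800)],
            biotype="candidate_noncoding",
        )
        annotation = make_annotation([coding, known, novel], {"c1": 100_000})
        table = uniform_expression(["known1", "novel1"])
        seqs = SequenceSet({t: "C" * 400 for t in ("known1", "novel1")})
        retained, report = apply_filter_cascade(
            [known, novel], annotation, table, seqs
        )
        assert retained == ["known1"]
        assert report.fate["novel1"] == "sense_exon_overlap"

    def test_expression_max_over_libraries(self):
        # adequate in ONE library is enough
        lnc = make_transcript("lnc1", "c1", "+", [(10_000, 10_200), (10_500, 10_700)])
        annotation = make_annotation([lnc], {"c1": 100_000})
        table = ExpressionTable(("E", "L", "P"))
        table.set("lnc1", "E", ExpressionRow(1, 0.05, 0.2))
        table.set("lnc1", "L", ExpressionRow(1, 0.05, 0.3))
        table.set("lnc1", "P", ExpressionRow(50, 2.0, 0.95))
        seqs = SequenceSet({"lnc1": "C" * lnc.length})
        retained, _ = apply_filter_cascade([lnc], annotation, table, seqs)
        assert retained == ["lnc1"]


class TestErrors:
    def test_missing_sequence_names_id(self):
        lnc = make_transcript("lnc1", "c1", "+", [(10_000, 10_200), (10_500, 10_700)])
        annotation = make_annotation([lnc], {"c1": 100_000})
        table = uniform_expression(["lnc1"])
        with pytest.raises(ValueError, match="lnc1"):
            apply_filter_cascade([lnc], annotation, table, SequenceSet())

    def test_missing_expression_names_id(self):
        lnc = make_transcript("lnc1", "c1", "+", [(10_000, 10_200), (10_500, 10_700)])
        annotation = make_annotation([lnc], {"c1": 100_000})
        seqs = SequenceSet({"lnc1": "C" * 400})
        with pytest.raises(ValueError, match="lnc1"):
            apply_filter_cascade([lnc], annotation, ExpressionTable(("E", "L", "P")), seqs)


class TestCascadeProperties:
    def test_planted_failures_on_synthetic(self, sim_dataset):
        _paths, truth = sim_dataset
        # exercised end-to-end in test_cli; here just check the plan shape
        per_rule = {}
        for rule in truth["filter_failures"].values():
            per_rule[rule] = per_rule.get(rule, 0) + 1
        assert all(v == 3 for v in per_rule.values())
        assert len(per_rule) == 8

    def test_conservation_and_set_invariance_under_permutation(self, sim_dataset):
        from lnckit.annotation_io import (
            read_expression_table, read_fasta, read_gtf, read_id_set,
            read_scaffold_lengths,
        )
        paths, truth = sim_dataset
        lengths = read_scaffold_lengths(paths["scaffolds"])
        annotation, transcripts, _ = read_gtf(paths["gtf"], lengths)
        seqs = read_fasta(paths["transcripts_fasta"])
        table = read_expression_table(paths["expression"])
        evidence = frozenset(read_id_set(paths["evidence"]))
        candidates = [t for t in transcripts if t.biotype != "coding"]
        config = FilterConfig(evidence_ids=evidence)
        retained, report = apply_filter_cascade(
            candidates, annotation, table, seqs, config
        )
        report.check_conservation()
        assert report.n_input == len(candidates)
        # retained set equals {all pass every predicate}, independent of order
        predicates = build_step_predicates(annotation, table, seqs, config)
        want = sorted(
            t.transcript_id
            for t in candidates
            if not any(fails(t) for _name, fails in predicates)
        )
        assert retained == want
        assert retained == truth["retained_ids"]
        # attribution equals first-failing rule in cascade order
        for tid, rule in truth["filter_failures"].items():
            assert report.fate[tid] == rule

    def test_monotonicity_relaxing_thresholds(self, sim_dataset):
        from lnckit.annotation_io import (
            read_expression_table, read_fasta, read_gtf, read_scaffold_lengths,
        )
        paths, _ = sim_dataset
        lengths = read_scaffold_lengths(paths["scaffolds"])
        annotation, transcripts, _ = read_gtf(paths["gtf"], lengths)
        seqs = read_fasta(paths["transcripts_fasta"])
        table = read_expression_table(paths["expression"])
        candidates = [t for t in transcripts if t.biotype != "coding"]
        base, _ = apply_filter_cascade(candidates, annotation, table, seqs)
        relaxed_configs = [
            FilterConfig(min_length_bp=0),
            FilterConfig(min_exons=1),
            FilterConfig(min_coverage=0.0),
            FilterConfig(min_fpkm=0.0),
            FilterConfig(max_orf_aa=10**6),
            FilterConfig(scaffold_end_margin_bp=0),
            FilterConfig(drop_sense_exon_overlap=False),
        ]
        for config in relaxed_configs:
            relaxed, _ = apply_filter_cascade(
                candidates, annotation, table, seqs, config
            )
            assert set(base) <= set(relaxed)
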