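"""T>C conversion calling, SNP masking and the read-level simulator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from slamscreen import simulate as sim
from slamscreen.nascent import (
    Mismatch,
    ReadAlignment,
    SnpBackground,
    build_snp_background,
    call_nascent,
    classify_read,
    read_alignments,
)


def _read(mismatches, contig="chrS1", strand="+", start=0, end=50):
    return ReadAlignment(
        read_id="r", cell_barcode="c", umi="u", contig=contig,
        start=start, end=end, strand=strand, mapq=60,
        mismatches=mismatches,
    )


def _mm(pos, ref, alt, qual=50):
    return Mismatch(ref_pos=pos, ref_base=ref, read_base=alt, base_quality=qual)


EMPTY = SnpBackground()


class TestClassify:
    def test_all_tc_is_nascent(self):
        read = _read([_mm(1, "T", "C"), _mm(5, "T", "C"), _mm(9, "T", "C")])
        call = classify_read(read, EMPTY, "+")
        assert call.label == "nascent" and call.n_tc == 3

    def test_quarter_tc_is_preexisting(self):
        # 1 of 4 eligible mismatches: 0.25 does not exceed the 30% rule
        mms = [_mm(1, "T", "C"), _mm(2, "G", "A"), _mm(3, "C", "A"),
               _mm(4, "A", "T")]
        call = classify_read(_read(mms), EMPTY, "+")
        assert call.label == "preexisting"
        assert call.n_tc == 1 and call.n_mismatch == 4

    def test_masked_snp_removes_conversion(self):
        read = _read([_mm(7, "T", "C")])
        bg = SnpBackground({("chrS1", 7): ("T", "C")})
        call = classify_read(read, bg, "+")
        assert call.label == "preexisting" and call.n_mismatch == 0

    def test_minus_strand_uses_ag(self):
        read = _read([_mm(3, "A", "G")], strand="-")
        assert classify_read(read, EMPTY, "-").label == "nascent"
        # the same genomic mismatch on a plus-strand gene is not a conversion
        assert classify_read(read, EMPTY, "+").label == "preexisting"

    def test_low_quality_mismatch_ignored(self):
        read = _read([_mm(1, "T", "C", qual=45)])  # threshold is strict >
        call = classify_read(read, EMPTY, "+", min_base_quality=45)
        assert call.label == "preexisting" and call.n_mismatch == 0

    def test_no_mismatches_is_preexisting(self):
        assert classify_read(_read([]), EMPTY, "+").label == "preexisting"

    def test_raising_fraction_threshold_is_monotone(self):
        rng = np.random.default_rng(5)
        reads = []
        for _ in range(100):
            mms = [
                _mm(int(p), "T", "C") if rng.random() < 0.5
                else _mm(int(p), "G", "A")
                for p in rng.choice(50, rng.integers(0, 6), replace=False)
            ]
            reads.append(_read(mms))
        previous = None
        for thr in (0.0, 0.2, 0.3, 0.5, 0.9):
            n = sum(
                classify_read(r, EMPTY, "+", min_tc_fraction=thr).label
                == "nascent"
                for r in reads
            )
            if previous is not None:
                assert n <= previous
            previous = n

    def test_masking_never_increases_conversions(self):
        read = _read([_mm(1, "T", "C"), _mm(9, "T", "C")])
        base = classify_read(read, EMPTY, "+").n_tc
        masked = classify_read(
            read, SnpBackground({("chrS1", 9): ("T", "C")}), "+"
        ).n_tc
        assert masked <= base


class TestSnpBackground:
    def _pile(self, n_alt, n_ref, pos=10):
        reads = []
        for i in range(n_alt):
            reads.append(_read([_mm(pos, "T", "C")], start=0, end=50))
        for i in range(n_ref):
            reads.append(_read([], start=0, end=50))
        return reads

    def test_high_fraction_site_masked(self):
        bg = build_snp_background(self._pile(9, 1))
        assert ("chrS1", 10) in bg

    def test_rare_mismatch_not_masked(self):
        bg = build_snp_background(self._pile(1, 99))
        assert ("chrS1", 10) not in bg

    def test_low_coverage_never_masked(self):
        bg = build_snp_background(self._pile(5, 0))  # coverage 5 < 10
        assert len(bg) == 0

    def test_empty_stream_warns(self):
        with pytest.warns(UserWarning):
            bg = build_snp_background([])
        assert len(bg) == 0

    def test_bed_round_trip(self, tmp_path):
        bg = build_snp_background(self._pile(9, 1))
        path = tmp_path / "mask.bed"
        bg.to_bed(path)
        assert SnpBackground.from_bed(path).masked_sites.keys() == \
            bg.masked_sites.keys()


class TestReadSimulator:
    def test_no_conversion_no_error_means_snp_only_mismatches(self, tmp_path):
        genome = sim.build_genome(6, n_mito_genes=0, seed=21)
        lib = sim.make_library(["gene0000"], 1, 1, seed=21)
        truth = sim.make_truth(
            genome, lib, n_cells=20, seed=21,
            p_conversion=0.0, p_error=0.0, n_snps=0,
        )
        counts = sim.simulate_counts(truth)
        sam = tmp_path / "r.sam"
        sim.simulate_reads(truth, counts, genome, sam)
        for aln in read_alignments(sam):
            assert aln.mismatches == []

    def test_saturated_conversion_hits_every_templated_t(self, tmp_path):
        genome = sim.build_genome(4, n_mito_genes=0, seed=22)
        lib = sim.make_library(["gene0000"], 1, 1, seed=22)
        truth = sim.make_truth(
            genome, lib, n_cells=10, seed=22,
            p_conversion=1.0, p_error=0.0, n_snps=0,
        )
        counts = sim.simulate_counts(truth)
        sam = tmp_path / "r.sam"
        tr = sim.simulate_reads(truth, counts, genome, sam).set_index("read_id")
        checked = 0
        for aln in read_alignments(sam):
            if tr.loc[aln.read_id, "origin"] != "nascent":
                continue
            gene = next(
                g for g in genome.genes
                if g.gene_id == tr.loc[aln.read_id, "gene_id"]
            )
            ref = genome.sequence(aln.contig, aln.start, aln.end)
            templated = b"T" if gene.strand == "+" else b"A"
            n_t = int((ref == templated).sum())
            assert len(aln.mismatches) == n_t
            checked += 1
        assert checked > 10

    def test_snp_present_on_both_origins(self, tmp_path):
        genome = sim.build_genome(4, n_mito_genes=0, seed=23)
        lib = sim.make_library(["gene0000"], 1, 1, seed=23)
        truth = sim.make_truth(
            genome, lib, n_cells=40, seed=23,
            p_conversion=0.0, p_error=0.0, n_snps=40,
        )
        counts = sim.simulate_counts(truth)
        sam = tmp_path / "r.sam"
        tr = sim.simulate_reads(truth, counts, genome, sam).set_index("read_id")
        seen = {"nascent": 0, "preexisting": 0, "intergenic": 0}
        for aln in read_alignments(sam):
            covered = [
                (c, p) for (c, p) in truth.snp_positions
                if c == aln.contig and aln.start <= p < aln.end
            ]
            assert len(aln.mismatches) == len(covered)
            if covered:
                seen[tr.loc[aln.read_id, "origin"]] += 1
        # conversion-free run: nascent and pre-existing reads both carry SNPs
        assert seen["preexisting"] > 0 and seen["nascent"] > 0

    def test_mean_conversions_match_rate(self, read_level_screen):
        genome, _, truth, _, sam, truth_reads = read_level_screen
        nasc = truth_reads[truth_reads["origin"] == "nascent"]
        # templated-T count per 50-nt read is ~12.5 on random sequence
        expected = truth.p_conversion * 12.5
        mean_conv = nasc["n_true_conversions"].mean()
        sd = np.sqrt(expected / len(nasc))
        assert abs(mean_conv - expected) < 5 * sd + 0.05

    def test_deterministic_sam_output(self, tmp_path):
        genome = sim.build_genome(5, n_mito_genes=0, seed=24)
        lib = sim.make_library(["gene0000"], 1, 1, seed=24)
        truth = sim.make_truth(genome, lib, n_cells=15, seed=24)
        counts = sim.simulate_counts(truth)
        a, b = tmp_path / "a.sam", tmp_path / "b.sam"
        ta = sim.simulate_reads(truth, counts, genome, a)
        tb = sim.simulate_reads(truth, counts, genome, b)
        assert a.read_bytes() == b.read_bytes()
        pd.testing.assert_frame_equal(ta, tb)


class TestCallerOnSimulation:
    def test_oracle_equivalence_on_small_read_set(self, read_level_screen):
        """Labels match a brute-force recomputation that extracts mismatches
        by comparing SAM text directly against the reference sequence."""
        genome, _, truth, _, sam, _ = read_level_screen
        labels = call_nascent(
            read_alignments(sam), SnpBackground(), min_base_quality=30
        ).set_index("read_id")

        n_checked = 0
        with open(sam) as fh:
            for line in fh:
                if line.startswith("@"):
                    continue
                if n_checked >= 100:
                    break
                f = line.split("\t")
                name, flag, contig, pos, seq = (
                    f[0], int(f[1]), f[2], int(f[3]) - 1, f[9]
                )
                ref = genome.sequence(contig, pos, pos + len(seq))
                ref = ref.tobytes().decode()
                conv = ("T", "C") if not (flag & 16) else ("A", "G")
                n_mm = sum(a != b for a, b in zip(ref, seq))
                n_tc = sum(
                    a == conv[0] and b == conv[1]
                    for a, b in zip(ref, seq)
                )
                expect = "nascent" if n_mm and n_tc / n_mm > 0.30 \
                    else "preexisting"
                # alignment strand equals gene strand in this simulation
                assert labels.loc[name, "label"] == expect
                n_checked += 1
        assert n_checked == 100

    def test_unlabeled_sample_yields_no_nascent_calls(self, tmp_path):
        genome = sim.build_genome(6, n_mito_genes=0, seed=25)
        lib = sim.make_library(["gene0000"], 1, 1, seed=25)
        truth = sim.make_truth(
            genome, lib, n_cells=25, seed=25,
            p_conversion=0.0, p_error=0.0, n_snps=0,
        )
        counts = sim.simulate_counts(truth)
        sam = tmp_path / "r.sam"
        sim.simulate_reads(truth, counts, genome, sam)
        labels = call_nascent(
            read_alignments(sam), SnpBackground(), min_base_quality=30
        )
        assert (labels["label"] == "preexisting").all()

    def test_determinism_of_labels(self, read_level_screen):
        *_, sam, _ = read_level_screen
        l1 = call_nascent(read_alignments(sam), EMPTY, min_base_quality=30)
        l2 = call_nascent(read_alignments(sam), EMPTY, min_base_quality=30)
        pd.testing.assert_frame_equal(l1, l2)
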