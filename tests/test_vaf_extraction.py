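"""CIGAR-walk pileup, left-alignment, VAF summarization and cohort extraction."""

import math
import random

import numpy as np
import pandas as pd
import pysam
import pytest
from scipy import stats

from hpaudit.regions import load_region_table
from hpaudit.synthetic_data import simulate_reads, toy_reference
from hpaudit.vaf_extraction import (
    count_indels_at_region,
    extract_cohort,
    summarize_region,
)

from _oracle import oracle_counts, random_reads


def _header(contig, length):
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": contig, "LN": length}]}
    )


def _read(header, tid_name, start0, cigar, seq, name="r", mapq=60, flag=0):
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.query_sequence = seq
    seg.flag = flag
    seg.reference_id = header.get_tid(tid_name)
    seg.reference_start = start0
    seg.mapping_quality = mapq
    seg.cigartuples = cigar
    seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return seg


@pytest.fixture()
def toy(toy_region_6T):
    ref, region = toy_region_6T
    return ref, region, _header(region.chromosome, len(ref))


class TestPileup:
    def test_clean_pileup(self, toy):
        ref, region, header = toy
        reads = [
            _read(header, region.chromosome, 110 + i % 80, [(0, 100)],
                  ref[110 + i % 80 : 210 + i % 80], name=f"r{i}")
            for i in range(100)
        ]
        counts = count_indels_at_region(reads, region, ref)
        assert counts.anchor_depth == 100
        assert counts.per_position_ins_reads.sum() == 0
        assert counts.per_position_del_reads.sum() == 0

    def test_zero_depth(self, toy):
        ref, region, header = toy
        counts = count_indels_at_region([], region, ref)
        assert counts.anchor_depth == 0
        s = summarize_region(counts, "s")
        assert math.isnan(s.vaf_ins) and math.isnan(s.vaf_del)
        assert not s.evaluable

    def test_exact_deletion_fraction(self, toy):
        """200 spanning reads, exactly 40 with a 1-bp deletion in the run."""
        ref, region, header = toy
        run_start0 = region.genomic_start - 1
        reads = []
        for i in range(200):
            start0 = 150 + (i % 20)
            a = run_start0 - start0
            if i < 40:
                seq = ref[start0 : start0 + a] + ref[start0 + a + 1 : start0 + 101]
                reads.append(_read(header, region.chromosome, start0,
                                   [(0, a), (2, 1), (0, 100 - a)], seq))
            else:
                reads.append(_read(header, region.chromosome, start0,
                                   [(0, 100)], ref[start0 : start0 + 100]))
        counts = count_indels_at_region(reads, region, ref)
        assert counts.per_position_del_reads.max() == 40
        assert counts.anchor_depth == 200
        s = summarize_region(counts, "s")
        assert s.vaf_del == pytest.approx(0.20)

    def test_mid_run_indels_left_align(self, toy):
        """Indels placed mid-run are tallied at the left-aligned position."""
        ref, region, header = toy
        run_start0 = region.genomic_start - 1
        start0 = 150
        a = run_start0 - start0
        # deletion of the 3rd run base
        del_read = _read(
            header, region.chromosome, start0,
            [(0, a + 2), (2, 1), (0, 98 - a)],
            ref[start0 : start0 + a + 2] + ref[start0 + a + 3 : start0 + 101],
        )
        # insertion of the run base after the 2nd run base
        ins_read = _read(
            header, region.chromosome, start0,
            [(0, a + 2), (1, 1), (0, 97 - a)],
            ref[start0 : start0 + a + 2] + region.base + ref[start0 + a + 2 : start0 + 99],
        )
        counts = count_indels_at_region([del_read, ins_read], region, ref)
        # deletion shifts to the first run base (index 1)
        assert counts.per_position_del_reads[1] == 1
        assert counts.per_position_del_reads[2:].sum() == 0
        # insertion shifts to open after the flank base (index 0)
        assert counts.per_position_ins_reads[0] == 1
        assert counts.per_position_ins_reads[1:].sum() == 0

    def test_read_with_both_indels_increments_both(self, toy):
        ref, region, header = toy
        run_start0 = region.genomic_start - 1
        start0 = 150
        a = run_start0 - start0
        seq = (
            ref[start0 : start0 + a]
            + region.base  # insertion at flank
            + ref[start0 + a : start0 + a + 2]
            + ref[start0 + a + 3 : start0 + 100]  # deletion of 3rd run base
        )
        read = _read(
            header, region.chromosome, start0,
            [(0, a), (1, 1), (0, 2), (2, 1), (0, 97 - a)], seq,
        )
        counts = count_indels_at_region([read], region, ref)
        assert counts.per_position_ins_reads.max() == 1
        assert counts.per_position_del_reads.max() == 1

    def test_filtered_reads_excluded(self, toy):
        ref, region, header = toy
        ok = _read(header, region.chromosome, 150, [(0, 100)], ref[150:250])
        dup = _read(header, region.chromosome, 150, [(0, 100)], ref[150:250], flag=1024)
        sec = _read(header, region.chromosome, 150, [(0, 100)], ref[150:250], flag=256)
        low = _read(header, region.chromosome, 150, [(0, 100)], ref[150:250], mapq=0)
        counts = count_indels_at_region([ok, dup, sec, low], region, ref)
        assert counts.anchor_depth == 1

    def test_order_invariance(self, toy, rng):
        ref, region, header = toy
        reads = random_reads(rng, ref, region, 60, header)
        c1 = count_indels_at_region(reads, region, ref)
        shuffled = reads[:]
        random.Random(5).shuffle(shuffled)
        c2 = count_indels_at_region(shuffled, region, ref)
        np.testing.assert_array_equal(c1.per_position_depth, c2.per_position_depth)
        np.testing.assert_array_equal(
            c1.per_position_ins_reads, c2.per_position_ins_reads
        )
        np.testing.assert_array_equal(
            c1.per_position_del_reads, c2.per_position_del_reads
        )

    def test_matches_oracle_on_randomized_reads(self, catalogue, rng):
        """Spot equivalence with the aligned-pairs interpreter (20 read sets)."""
        for i in range(20):
            region0 = catalogue[i % len(catalogue)]
            ref, region = toy_reference(region0, flank=120)
            header = _header(region.chromosome, len(ref))
            reads = random_reads(rng, ref, region, 25, header)
            counts = count_indels_at_region(reads, region, ref)
            depth, ins, dele = oracle_counts(reads, region, ref)
            np.testing.assert_array_equal(counts.per_position_depth, depth)
            np.testing.assert_array_equal(counts.per_position_ins_reads, ins)
            np.testing.assert_array_equal(counts.per_position_del_reads, dele)


class TestSummarize:
    def test_division(self, toy):
        ref, region, header = toy
        hdr, reads, truth = simulate_reads(
            region, ref, 200, np.random.default_rng(1), del_fraction=0.2
        )
        counts = count_indels_at_region(reads, region, ref)
        s = summarize_region(counts, "s1")
        assert s.max_del_reads == truth["bg_del"]
        assert s.vaf_del == truth["bg_del"] / 200
        assert s.evaluable

    def test_depth_threshold_boundary(self, toy):
        ref, region, header = toy
        reads = [
            _read(header, region.chromosome, 150, [(0, 100)], ref[150:250], name=f"r{i}")
            for i in range(90)
        ]
        counts = count_indels_at_region(reads, region, ref)
        assert not summarize_region(counts, "s", depth_threshold=100).evaluable
        assert summarize_region(counts, "s", depth_threshold=90).evaluable

    def test_carrier_vaf_within_binomial_interval(self, toy):
        """Injected carrier at true VAF 0.5, depth 2000: observed VAF in the
        central 99% binomial interval."""
        ref, region, header = toy
        _, reads, truth = simulate_reads(
            region, ref, 2000, np.random.default_rng(42),
            carrier_kind="del", carrier_vaf=0.5,
        )
        counts = count_indels_at_region(reads, region, ref)
        s = summarize_region(counts, "s")
        lo, hi = stats.binom.ppf([0.005, 0.995], 2000, 0.5) / 2000
        assert lo <= s.vaf_del <= hi


class TestExtractCohort:
    def test_bundle_extraction_matches_truth_ledger(self, bundle):
        regions = load_region_table(bundle["regions"])
        labels = pd.read_csv(bundle["labels"], sep="\t").set_index("sample_id")["cohort"]
        matrix = extract_cohort(
            bundle["bams"], regions, str(bundle["reference"]), labels
        )
        assert len(matrix.records) == len(bundle["bams"]) * 29
        truth = pd.read_csv(bundle["truth"], sep="\t")
        rec = matrix.records.set_index(["sample_id", "region_id"])
        for _, row in truth.iterrows():
            r = rec.loc[(row.sample_id, row.region_id)]
            assert r["depth"] == row.n_reads
            assert r["max_ins_reads"] == row.bg_ins_reads
            assert r["max_del_reads"] == row.bg_del_reads + row.carrier_reads

    def test_missing_file_fails_fast(self, bundle):
        regions = load_region_table(bundle["regions"])
        manifest = dict(bundle["bams"])
        manifest["ghost"] = "/nonexistent/ghost.bam"
        with pytest.raises(FileNotFoundError, match="ghost"):
            extract_cohort(manifest, regions, str(bundle["reference"]))
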