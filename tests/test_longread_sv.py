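"""Unit tests for read QC, bin mapping and deviation-based SV calling."""

import numpy as np
import pytest

from conftest import exhaustive_map
from ribodyn import refgen
from ribodyn.longread_sv import (
    BinAlignment,
    UnitIndex,
    bin_alignments_from_paf,
    bin_alignments_from_sam,
    call_read_sv,
    map_bin,
    map_read_bins,
    qc_filter,
    split_bins,
    summarize_sample,
    write_paf,
    write_sam,
)
from ribodyn.refgen import LongRead, revcomp


def make_read(length, mean_q, rid="r"):
    seq = "A" * length
    quals = np.full(length, int(mean_q)) if float(mean_q).is_integer() else None
    if quals is None:
        quals = np.full(length, 18)
        quals[: int(round((mean_q - 18) * length))] = 19  # tune the mean
    return LongRead(id=rid, sequence=seq, qualities=quals)


class TestQCFilter:
    def test_length_boundary_is_strict(self, params):
        assert not qc_filter(make_read(8000, 30), params).passed
        assert qc_filter(make_read(8001, 30), params).passed

    def test_quality_boundary_is_strict(self, params):
        assert not qc_filter(make_read(8001, 18.0), params).passed
        r = LongRead(id="r", sequence="A" * 8001,
                     qualities=np.full(8001, 18) + (np.arange(8001) < 81))
        assert r.mean_q > 18.0
        assert qc_filter(r, params).passed

    def test_long_good_read_passes(self, params):
        assert qc_filter(make_read(12000, 25), params).passed

    def test_empty_read_fails_with_reason(self, params):
        r = LongRead(id="e", sequence="", qualities=np.array([], dtype=int))
        res = qc_filter(r, params)
        assert not res.passed and res.reason == "empty"

    def test_error_prob_domain_mean_is_lower(self, params):
        # mixing Q10 and Q30 bases: error-domain mean is dominated by bad bases
        quals = np.array([10, 30] * 5000)
        r = LongRead(id="m", sequence="A" * 10000, qualities=quals)
        assert qc_filter(r, params, quality_domain="phred").passed
        assert not qc_filter(r, params, quality_domain="error_prob").passed


class TestSplitBins:
    @pytest.mark.parametrize("length,expected", [(8999, 29), (9000, 30), (299, 0), (300, 1)])
    def test_bin_count_floor(self, length, expected):
        bins = split_bins("A" * length, 300)
        assert len(bins) == expected
        assert all(len(b) == 300 for b in bins)

    def test_concatenation_reconstructs_prefix(self, clean_array):
        reads = refgen.simulate_long_reads(clean_array, n_reads=5, seed=13)
        for r in reads:
            bins = split_bins(r, 300)
            assert "".join(bins) == r.sequence[: len(bins) * 300]


class TestMapBin:
    def test_origin_wrapping_bin(self, unit):
        circ = unit.sequence + unit.sequence
        bin_seq = circ[8950 : 8950 + 300]
        aln = map_bin(bin_seq, unit)
        assert aln.mapped and aln.strand == "+"
        assert aln.unit_pos == 8950
        assert aln.mismatches == 0

    def test_mismatched_bin_counts_mismatches(self, unit):
        rng = np.random.default_rng(17)
        bin_seq = list(unit.sequence[2000:2300])
        for i in (50, 200):
            bin_seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bin_seq[i]]
        aln = map_bin("".join(bin_seq), unit, max_mismatch=5)
        assert aln.mapped
        assert aln.unit_pos == 2000
        assert aln.mismatches == 2

    def test_reverse_strand_reflection(self, unit):
        fwd = unit.sequence[4000:4300]
        aln = map_bin(revcomp(fwd), unit)
        assert aln.mapped and aln.strand == "-"
        # reflected so that consecutive reverse bins advance by +bin_len
        assert aln.unit_pos == (9100 - 300 - 4000) % 9100

    def test_random_bin_is_unmapped(self, unit):
        rng = np.random.default_rng(23)
        bin_seq = "".join(refgen.BASES[rng.integers(0, 4, 300)])
        assert not map_bin(bin_seq, unit).mapped
        assert exhaustive_map(bin_seq, unit) is None

    def test_seeded_mapper_agrees_with_exhaustive_scan(self, unit, clean_array):
        """Independent oracle: a full Hamming scan over every offset and both
        strands must agree with the seeded mapper bin for bin."""
        index = UnitIndex(unit)
        reads = refgen.simulate_long_reads(
            clean_array, n_reads=10, error_rate=0.0,
            length_law={"law": "fixed", "length": 6000}, seed=19,
        )
        for read in reads:
            for i, b in enumerate(split_bins(read, 300)):
                aln = map_bin(b, index, bin_index=i)
                oracle = exhaustive_map(b, unit)
                assert aln.mapped and oracle is not None
                assert (aln.unit_pos, aln.strand, aln.mismatches) == oracle


def aln(i, pos, strand="+"):
    return BinAlignment(bin_index=i, read_offset=i * 300, unit_pos=pos,
                        strand=strand, mismatches=0, mapped=True)


class TestCallReadSV:
    def test_regular_spacing_no_call(self, params):
        res = call_read_sv([aln(0, 1000), aln(1, 1300)], params)
        assert res.informative and res.calls == []

    def test_deviation_exactly_at_tolerance_no_call(self, params):
        res = call_read_sv([aln(0, 1000), aln(1, 1400)], params)
        assert res.calls == []

    def test_deviation_above_tolerance_is_deletion(self, params):
        res = call_read_sv([aln(0, 1000), aln(1, 1401)], params)
        (c,) = res.calls
        assert c.type == "deletion" and c.size == 101 and c.deviation == 101

    def test_negative_deviation_is_insertion(self, params):
        res = call_read_sv([aln(0, 1000), aln(1, 1100)], params)
        (c,) = res.calls
        assert c.type == "insertion" and c.size == 200

    def test_junction_crossing_is_deviation_free(self, params):
        res = call_read_sv([aln(0, 9000), aln(1, 200)], params)
        assert res.calls == []

    def test_unmapped_gap_scales_expected_distance(self, params):
        # bins 0 and 2 mapped, bin 1 not: expected distance 600
        res = call_read_sv([aln(0, 1000), aln(2, 1600)], params)
        assert res.calls == []
        res = call_read_sv([aln(0, 1000), aln(2, 2101)], params)
        (c,) = res.calls
        assert c.size == 501

    def test_mixed_strand_pair_excluded(self, params):
        res = call_read_sv([aln(0, 1000), aln(1, 5000, "-")], params)
        assert res.calls == [] and res.n_inversion_pairs == 1

    def test_fewer_than_two_mapped_bins_uninformative(self, params):
        res = call_read_sv([aln(0, 1000)], params)
        assert not res.informative

    def test_planted_deletion_recovered_exactly(self, unit, params):
        array = refgen.build_array(unit, n_c=12, deletions=[(6, 2000, 2500)], seed=29)
        reads = refgen.simulate_long_reads(
            array, n_reads=40, error_rate=0.0,
            length_law={"law": "fixed", "length": 9000}, seed=29,
        )
        index = UnitIndex(unit)
        junction = array.deletion_junctions()[0][0]
        n_spanning = 0
        for read in reads:
            alns = map_read_bins(read, index)
            res = call_read_sv(alns, params, read_id=read.id)
            spans = read.truth.start + 300 < junction < read.truth.end - 300
            if spans:
                n_spanning += 1
                assert len(res.calls) == 1
                assert res.calls[0].type == "deletion"
                assert res.calls[0].size == 500
        assert n_spanning > 0


class TestSummarizeSample:
    def test_clean_input_zero_sv_fraction(self, unit, clean_array, params):
        reads = refgen.simulate_long_reads(
            clean_array, n_reads=30, error_rate=0.0,
            length_law={"law": "fixed", "length": 9000}, seed=31,
        )
        s = summarize_sample(reads, unit, params)
        assert s.sv_read_fraction == 0.0
        assert s.n_input >= s.n_pass_qc >= s.n_analyzed >= s.n_sv_reads

    def test_filter_chain_counts_weakly_decreasing(self, unit, clean_array, params):
        reads = refgen.simulate_long_reads(clean_array, n_reads=50, error_rate=0.02, seed=37)
        s = summarize_sample(reads, unit, params)
        assert s.n_input >= s.n_pass_qc >= s.n_analyzed >= s.n_sv_reads >= s.n_deletion_reads

    def test_equal_deletion_load_gives_comparable_fractions(self, unit, params):
        """Two samples simulated with the same planted-deletion rate should
        not differ in deletion-read fraction beyond binomial noise."""
        fractions = []
        for seed in (41, 43):
            array = refgen.build_array(unit, n_c=12, deletions=[(6, 3000, 3400)], seed=seed)
            reads = refgen.simulate_long_reads(
                array, n_reads=60, error_rate=0.0,
                length_law={"law": "fixed", "length": 9000}, seed=seed,
            )
            s = summarize_sample(reads, unit, params)
            fractions.append((s.n_deletion_reads, s.n_analyzed))
        (k1, n1), (k2, n2) = fractions
        p = (k1 + k2) / (n1 + n2)
        sd = np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        assert abs(k1 / n1 - k2 / n2) < 3 * max(sd, 1e-9)


class TestExternalAlignments:
    def _mapped(self, unit, params, with_deletion):
        dels = [(6, 2000, 2500)] if with_deletion else None
        array = refgen.build_array(unit, n_c=12, deletions=dels, seed=47)
        reads = refgen.simulate_long_reads(
            array, n_reads=25, error_rate=0.0,
            length_law={"law": "fixed", "length": 9000}, seed=47,
        )
        index = UnitIndex(unit)
        passing = [r for r in reads if qc_filter(r, params).passed]
        per_read = {r.id: map_read_bins(r, index) for r in passing}
        return {r.id: r for r in passing}, per_read

    def test_sam_round_trip_gives_identical_calls(self, unit, params, tmp_path):
        reads, per_read = self._mapped(unit, params, with_deletion=True)
        internal = summarize_sample(None, unit, params, alignments=per_read)
        sam = tmp_path / "bins.sam"
        write_sam(per_read, reads, unit, params, sam)
        imported = bin_alignments_from_sam(sam, unit, params)
        external = summarize_sample(None, unit, params, alignments=imported)
        key = lambda c: (c.read_id, c.bin_i, c.bin_j, c.deviation, c.type)
        assert sorted(map(key, internal.calls)) == sorted(map(key, external.calls))
        assert len(internal.calls) > 0

    def test_paf_round_trip_gives_identical_calls(self, unit, params, tmp_path):
        reads, per_read = self._mapped(unit, params, with_deletion=True)
        internal = summarize_sample(None, unit, params, alignments=per_read)
        paf = tmp_path / "bins.paf"
        write_paf(per_read, reads, unit, params, paf)
        imported = bin_alignments_from_paf(paf, unit, params)
        external = summarize_sample(None, unit, params, alignments=imported)
        key = lambda c: (c.read_id, c.bin_i, c.bin_j, c.deviation, c.type)
        assert sorted(map(key, internal.calls)) == sorted(map(key, external.calls))
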