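import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from offcall.intervals import (BinSet, GenomicBin, PartitionParams,
                               annotate_exons, build_binset,
                               build_off_targets, build_on_targets,
                               compute_gc, merge_intervals,
                               offtarget_depth_fraction, read_capture_bed,
                               recommend_max_offtarget, _split_equal)

GENOME = {"chr1": 1_000_000, "chr2": 500_000}


def write_bed(tmp_path, lines, name="targets.bed"):
    p = tmp_path / name
    p.write_text("".join(line + "\n" for line in lines))
    return p


class TestReadCaptureBed:
    def test_overlapping_lines_merge(self, tmp_path):
        p = write_bed(tmp_path, ["chr1\t100\t200", "chr1\t150\t250"])
        assert read_capture_bed(p, GENOME) == [("chr1", 100, 250)]

    def test_unknown_chromosome_dropped(self, tmp_path, caplog):
        p = write_bed(tmp_path, ["chr1\t100\t200", "chrUn_gl000220\t0\t100"])
        assert read_capture_bed(p, GENOME) == [("chr1", 100, 200)]
        assert "chrUn_gl000220" in caplog.text

    def test_extra_columns_ignored(self, tmp_path):
        p3 = write_bed(tmp_path, ["chr1\t10\t50", "chr2\t5\t30"], "a.bed")
        p4 = write_bed(tmp_path, ["chr1\t10\t50\tname\t0\t+",
                                  "chr2\t5\t30\tname\t0\t-"], "b.bed")
        assert read_capture_bed(p3, GENOME) == read_capture_bed(p4, GENOME)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = write_bed(tmp_path, ["chr1\t100\t200", "chr1\tfoo\tbar"])
        with pytest.raises(ValueError, match=":2"):
            read_capture_bed(p, GENOME)

    def test_empty_file_errors(self, tmp_path):
        p = write_bed(tmp_path, [])
        with pytest.raises(ValueError, match="no target"):
            read_capture_bed(p, GENOME)


class TestBuildOnTargets:
    def test_long_interval_split_into_equal_parts(self):
        bins = build_on_targets([("chr1", 1000, 1750)], GENOME, 100, 300)
        assert [b.length for b in bins] == [250, 250, 250]
        assert bins[0].start == 1000 and bins[-1].end == 1750

    def test_boundary_length_unchanged(self):
        bins = build_on_targets([("chr1", 1000, 1300)], GENOME, 100, 300)
        assert [(b.start, b.end) for b in bins] == [(1000, 1300)]

    def test_short_interval_extended_symmetrically(self):
        bins = build_on_targets([("chr1", 1000, 1040)], GENOME, 100, 300)
        assert [(b.start, b.end) for b in bins] == [(970, 1070)]

    def test_odd_residue_goes_right(self):
        bins = build_on_targets([("chr1", 1000, 1041)], GENOME, 100, 300)
        # deficit 59: 29 left, 30 right
        assert [(b.start, b.end) for b in bins] == [(971, 1071)]

    def test_extension_clipped_at_chromosome_start(self):
        bins = build_on_targets([("chr1", 5, 25)], GENOME, 100, 300)
        assert [(b.start, b.end) for b in bins] == [(0, 100)]

    def test_extension_collision_remerges(self):
        bins = build_on_targets([("chr1", 1000, 1020), ("chr1", 1060, 1080)],
                                GENOME, 100, 300)
        for a, b in zip(bins, bins[1:]):
            assert b.start >= a.end
        assert bins[0].start <= 970
        assert sum(b.length for b in bins) >= 100

    def test_tiny_chromosome_spanned_with_warning(self, caplog):
        bins = build_on_targets([("chrS", 10, 20)], {"chrS": 50}, 100, 300)
        assert [(b.start, b.end) for b in bins] == [(0, 50)]
        assert "shorter than" in caplog.text


class TestBuildOffTargets:
    def test_worked_partition_example(self):
        genome = {"chr1": 100_300}
        on = [GenomicBin("chr1", 10_000, 10_300, "on_target")]
        off = build_off_targets(on, genome, 300, 50_000, 1)
        coords = [(b.start, b.end) for b in off]
        assert coords == [(0, 9700), (10_600, 55_450), (55_450, 100_300)]
        assert all(b.length == 44_850 for b in off[1:])

    def test_padding_consumes_small_gap(self):
        genome = {"chr1": 100_000}
        on = [GenomicBin("chr1", 10_000, 10_300, "on_target"),
              GenomicBin("chr1", 10_800, 11_100, "on_target")]
        off = build_off_targets(on, genome, 300, 50_000, 1)
        assert not any(b.start >= 10_300 and b.end <= 10_800 for b in off)

    def test_empty_chromosome_fully_tiled(self):
        genome = {"chr2": 120_000}
        off = build_off_targets([], genome, 300, 50_000, 1)
        assert off[0].start == 0 and off[-1].end == 120_000
        assert sum(b.length for b in off) == 120_000

    def test_min_off_target_discards_small_gaps(self):
        genome = {"chr1": 100_000}
        on = [GenomicBin("chr1", 10_000, 10_300, "on_target"),
              GenomicBin("chr1", 11_500, 11_800, "on_target")]
        # gap 10_600..11_200 is 600 bp; discarded at min_off_target=1000
        off = build_off_targets(on, genome, 300, 50_000, 1000)
        assert not any(b.start == 10_600 for b in off)


class TestAnnotateExons:
    @pytest.fixture()
    def binset(self):
        bins = [GenomicBin("chr1", 0, 1000, "off_target"),
                GenomicBin("chr1", 2000, 2300, "on_target"),
                GenomicBin("chr1", 3000, 10_000, "off_target")]
        return BinSet(bins=bins, genome={"chr1": 20_000})

    def test_contained_utr_exon_flags_off_target_bin(self, binset, tmp_path):
        bed = write_bed(tmp_path, ["chr1\t4000\t4200\tUTR5"], "exons.bed")
        annotate_exons(binset, bed)
        assert [b.exonic for b in binset] == [False, False, True]

    def test_one_bp_edge_overlap_counts(self, binset, tmp_path):
        bed = write_bed(tmp_path, ["chr1\t999\t1500"], "exons.bed")
        annotate_exons(binset, bed)
        assert binset[0].exonic and not binset[2].exonic

    def test_missing_file_all_false_with_warning(self, binset, tmp_path, caplog):
        annotate_exons(binset, tmp_path / "absent.bed")
        assert not any(b.exonic for b in binset)
        assert "missing" in caplog.text


class TestComputeGc:
    @pytest.fixture()
    def fasta(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">chr1\nGCGCATATANGCAAAAAAAANNNNNNNN\n")
        return p

    def test_gc_extremes_and_n_exclusion(self, fasta):
        bins = [GenomicBin("chr1", 0, 4, "on_target"),     # GCGC
                GenomicBin("chr1", 4, 8, "on_target"),     # ATAT
                GenomicBin("chr1", 8, 12, "on_target")]    # ANGC
        bs = BinSet(bins=bins, genome={"chr1": 28})
        compute_gc(bs, str(fasta))
        assert bs[0].gc == 1.0
        assert bs[1].gc == 0.0
        assert bs[2].gc == pytest.approx(2 / 3)

    def test_mostly_n_bin_flagged_nan(self, fasta):
        bs = BinSet(bins=[GenomicBin("chr1", 19, 27, "off_target")],
                    genome={"chr1": 28})
        compute_gc(bs, str(fasta))
        assert math.isnan(bs[0].gc)

    def test_missing_chromosome_named_in_error(self, fasta):
        bs = BinSet(bins=[GenomicBin("chr9", 0, 4, "on_target")],
                    genome={"chr9": 100})
        with pytest.raises(KeyError, match="chr9"):
            compute_gc(bs, str(fasta))


class TestSizingAdvice:
    @pytest.mark.parametrize("max_on,ratio,expected", [
        (300, 80, 48_000),     # the typical exome regime, ~50 kbp advice
        (300, 1, 1000),        # 600 rounds to the nearest 1000
        (300, 117, 70_000),    # deeper off-target contamination
    ])
    def test_recommended_off_bin_size(self, max_on, ratio, expected):
        assert recommend_max_offtarget(max_on, ratio) == expected

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            recommend_max_offtarget(300, 0)

    def test_offtarget_depth_fraction_is_about_one_eightieth(self):
        frac = offtarget_depth_fraction(47.2, 33.6, 18.0, 0.057)
        assert 1 / frac == pytest.approx(80, rel=0.05)


# --------------------------------------------------------------------------
# properties


@settings(max_examples=200, deadline=None, derandomize=True)
@given(start=st.integers(0, 10**6), length=st.integers(1, 10**5),
       max_len=st.integers(1, 5000))
def test_split_balance_property(start, length, max_len):
    parts = _split_equal(start, start + length, max_len)
    sizes = [e - s for s, e in parts]
    assert max(sizes) - min(sizes) <= 1
    assert parts[0][0] == start and parts[-1][1] == start + length
    for (s1, e1), (s2, e2) in zip(parts, parts[1:]):
        assert e1 == s2
    assert len(parts) == math.ceil(length / max_len)


def random_partition_case(rng):
    genome = {"chr1": int(rng.integers(50_000, 400_000)),
              "chr2": int(rng.integers(50_000, 400_000))}
    raw = []
    for chrom, clen in genome.items():
        for _ in range(int(rng.integers(0, 12))):
            s = int(rng.integers(0, clen - 1))
            e = min(clen, s + int(rng.integers(1, 2000)))
            raw.append((chrom, s, e))
    return genome, merge_intervals(raw)


@pytest.mark.parametrize("n_cases", [200])
def test_partition_invariants_fuzz(n_cases):
    """On random capture sets the partition keeps the target span,
    stays disjoint, honours padding and off-target size bounds."""
    rng = np.random.default_rng(42)
    params = PartitionParams(100, 300, 300, 50_000, 1)
    for _ in range(n_cases):
        genome, raw = random_partition_case(rng)
        bs = build_binset(raw, genome, params)
        bs.validate()  # disjointness, padding, size bounds
        # on-target union covers the raw targets
        on = [(b.chrom, b.start, b.end) for b in bs if b.kind == "on_target"]
        for chrom, s, e in raw:
            covered = sum(min(e, oe) - max(s, os_)
                          for c, os_, oe in on if c == chrom and os_ < e and oe > s)
            assert covered == e - s


def test_binset_bed_round_trip_is_byte_identical(tmp_path, small_batch):
    bins, _, _, _ = small_batch
    p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
    bins.to_bed(p1)
    BinSet.from_bed(p1, genome=bins.genome).to_bed(p2)
    assert p1.read_bytes() == p2.read_bytes()
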