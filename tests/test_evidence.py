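"""Split, discordant and coverage evidence extraction from alignments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eccscout.evidence import (
    AlignmentRecord,
    SupplementaryAnchor,
    call_discordant_regions,
    call_split_junctions,
    compute_coverage,
    find_peaks,
    normalize_bpm,
    read_sam,
)
from eccscout.simulate import SimulationConfig, simulate_read_pairs


def make_record(
    name="r1",
    chrom="chr1",
    pos=0,
    cigar=((("M", 100),)),
    *,
    proper=True,
    reverse=False,
    mate_reverse=True,
    mate_chrom=None,
    mate_pos=0,
    tlen=0,
    anchors=(),
    unmapped=False,
    supplementary=False,
    secondary=False,
    paired=True,
    is_read1=True,
):
    return AlignmentRecord(
        query_name=name,
        paired=paired,
        proper_pair=proper,
        unmapped=unmapped,
        mate_unmapped=False,
        reverse=reverse,
        mate_reverse=mate_reverse,
        secondary=secondary,
        supplementary=supplementary,
        is_read1=is_read1,
        chrom=chrom,
        pos=pos,
        cigar=list(cigar),
        mapq=60,
        mate_chrom=mate_chrom or chrom,
        mate_pos=mate_pos,
        tlen=tlen,
        supplementary_anchors=list(anchors),
    )


# ---------------------------------------------------------------------------
# parsing


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:10000\n"


class TestParse:
    def test_header_only_yields_nothing(self, tmp_path):
        path = tmp_path / "empty.sam"
        path.write_text(SAM_HEADER)
        records, lengths = read_sam(path)
        assert records == []
        assert lengths == {"chr1": 10000}

    def test_unmapped_flag_decoded_and_excluded_downstream(self, tmp_path):
        path = tmp_path / "u.sam"
        path.write_text(SAM_HEADER + "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n")
        records, _ = read_sam(path)
        assert len(records) == 1 and records[0].unmapped
        assert call_split_junctions(records, min_split=1) == []
        track = compute_coverage(records, {"chr1": 10000})
        assert track.total_aligned_bases == 0

    def test_supplementary_anchor_tag_decoded_zero_based(self, tmp_path):
        path = tmp_path / "sa.sam"
        path.write_text(
            SAM_HEADER
            + "r1\t0\tchr1\t501\t60\t50M150S\t=\t501\t0\t"
            + "A" * 200 + "\t" + "I" * 200
            + "\tSA:Z:chr1,101,+,50S150M,60,0;\n"
        )
        records, _ = read_sam(path)
        (rec,) = records
        assert rec.pos == 500  # converted from 1-based 501
        (anchor,) = rec.supplementary_anchors
        assert anchor == SupplementaryAnchor("chr1", 100, "+", "50S150M")


# ---------------------------------------------------------------------------
# split junctions


def split_read(name, s, e, break_at, read_len=200, chrom="chr1", reverse=False):
    """A wrap-around split read: first part ends at e, second part starts at s."""
    first_len = break_at
    second_len = read_len - break_at
    rec = make_record(
        name=name,
        chrom=chrom,
        pos=e - first_len,
        cigar=[("M", first_len), ("S", second_len)],
        reverse=reverse,
        anchors=[
            SupplementaryAnchor(chrom, s, "-" if reverse else "+", f"{first_len}S{second_len}M")
        ],
        proper=False,
    )
    return rec


class TestSplitJunctions:
    def test_five_reads_make_a_junction(self):
        records = [split_read(f"r{i}", 300, 7000, 80 + i) for i in range(5)]
        (junction,) = call_split_junctions(records, min_split=5)
        assert (junction.chrom, junction.start, junction.end) == ("chr1", 300, 7000)
        assert junction.support == 5

    def test_four_reads_do_not(self):
        records = [split_read(f"r{i}", 300, 7000, 80 + i) for i in range(4)]
        assert call_split_junctions(records, min_split=5) == []

    def test_colinear_split_is_not_a_circle(self):
        # second read part aligns downstream (deletion signature)
        rec = make_record(
            name="d1",
            pos=300,
            cigar=[("M", 80), ("S", 120)],
            anchors=[SupplementaryAnchor("chr1", 5000, "+", "80S120M")],
        )
        assert call_split_junctions([rec] * 5, min_split=1) == []

    def test_reverse_strand_split_counts_identically(self):
        records = [split_read(f"r{i}", 300, 7000, 90, reverse=True) for i in range(5)]
        (junction,) = call_split_junctions(records, min_split=5)
        assert (junction.start, junction.end) == (300, 7000)

    def test_opposite_strand_anchor_ignored(self):
        rec = split_read("r1", 300, 7000, 90)
        rec.supplementary_anchors = [SupplementaryAnchor("chr1", 300, "-", "90S110M")]
        assert call_split_junctions([rec] * 5, min_split=1) == []

    @given(st.randoms(use_true_random=False))
    def test_order_invariance_and_consensus_within_tolerance(self, rnd):
        records = [
            split_read(f"r{i}", 300 + (i % 3), 7000 - (i % 2), 50 + i) for i in range(8)
        ]
        baseline = call_split_junctions(records, min_split=5)
        shuffled = records[:]
        rnd.shuffle(shuffled)
        assert call_split_junctions(shuffled, min_split=5) == baseline
        (junction,) = baseline
        for rec in records:
            s = rec.supplementary_anchors[0].pos
            e = rec.reference_end
            assert abs(junction.start - s) <= 5
            assert abs(junction.end - e) <= 5

    def test_junctions_match_ground_truth_on_clean_simulation(self, clean_sim, tmp_path):
        from eccscout.simulate import emit_oracle_alignments

        path = tmp_path / "clean.sam"
        emit_oracle_alignments(clean_sim.genome, clean_sim.circ, clean_sim.truth, path)
        records, _ = read_sam(path)
        junctions = call_split_junctions(records, min_split=5)
        truth = clean_sim.truth
        assert junctions
        for junction in junctions:
            assert junction.chrom == truth.chrom
            assert abs(junction.start - truth.start) <= 5
            assert abs(junction.end - truth.end) <= 5


# ---------------------------------------------------------------------------
# discordant regions


def interval_union(intervals, merge_distance=0):
    """Brute-force union oracle over integer positions."""
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + merge_distance:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(m) for m in merged]


class TestDiscordant:
    def test_single_improper_pair_spans_both_mates(self):
        rec = make_record(
            name="p1", pos=1000, tlen=50_200, proper=False,
            mate_pos=51_000, cigar=[("M", 200)],
        )
        (region,) = call_discordant_regions([rec], max_insert=1_000)
        assert (region.start, region.end, region.pair_count) == (1000, 51_200, 1)

    def test_all_proper_pairs_give_nothing(self):
        records = [
            make_record(name=f"p{i}", pos=i * 10, mate_pos=i * 10 + 300,
                        tlen=500, cigar=[("M", 200)])
            for i in range(20)
        ]
        assert call_discordant_regions(records, max_insert=1_000) == []

    def test_pair_counted_once_despite_two_records(self):
        r1 = make_record(name="p1", pos=100, mate_pos=5_000, proper=False,
                         cigar=[("M", 200)], is_read1=True)
        r2 = make_record(name="p1", pos=5_000, mate_pos=100, proper=False,
                         cigar=[("M", 200)], is_read1=False,
                         reverse=True, mate_reverse=False)
        (region,) = call_discordant_regions([r1, r2], max_insert=10_000)
        assert region.pair_count == 1

    def test_large_insert_flags_discordant(self):
        rec = make_record(name="p1", pos=0, mate_pos=9_000, tlen=9_200,
                          cigar=[("M", 200)], proper=True)
        (region,) = call_discordant_regions([rec], max_insert=1_000)
        assert region.pair_count == 1

    @given(
        st.lists(
            st.tuples(st.integers(0, 3_000), st.integers(1, 400)),
            min_size=1,
            max_size=40,
        ),
        st.integers(0, 50),
    )
    def test_merging_matches_union_oracle(self, spans, merge_distance):
        records = [
            make_record(
                name=f"p{i}", pos=start, mate_pos=start + width, proper=False,
                cigar=[("M", 100)], tlen=width + 100,
            )
            for i, (start, width) in enumerate(spans)
        ]
        regions = call_discordant_regions(
            records, max_insert=10_000, merge_distance=merge_distance
        )
        expected = interval_union(
            [(start, max(start + 100, start + width + 100)) for start, width in spans],
            merge_distance,
        )
        assert [(r.start, r.end) for r in regions] == expected
        assert sum(r.pair_count for r in regions) == len(spans)


# ---------------------------------------------------------------------------
# coverage and BPM


class TestCoverage:
    def test_single_alignment_block(self):
        rec = make_record(pos=10, cigar=[("M", 100)])
        track = compute_coverage([rec], {"chr1": 1_000})
        arr = track.depths["chr1"]
        assert arr[10:110].sum() == 100 and arr.sum() == 100
        assert track.total_aligned_bases == 100

    def test_empty_input_zero_track(self):
        track = compute_coverage([], {"chr1": 500})
        assert track.total_aligned_bases == 0
        assert track.depths["chr1"].sum() == 0

    def test_overlap_depth_two(self):
        records = [
            make_record(name="a", pos=0, cigar=[("M", 100)]),
            make_record(name="b", pos=50, cigar=[("M", 100)]),
        ]
        arr = compute_coverage(records, {"chr1": 1_000}).depths["chr1"]
        assert (arr[50:100] == 2).all()
        assert (arr[0:50] == 1).all() and (arr[100:150] == 1).all()

    def test_out_of_bounds_alignment_rejected(self):
        rec = make_record(pos=950, cigar=[("M", 100)])
        with pytest.raises(ValueError, match="beyond"):
            compute_coverage([rec], {"chr1": 1_000})

    @given(
        st.lists(
            st.tuples(st.integers(0, 900), st.integers(1, 100)),
            min_size=0,
            max_size=30,
        )
    )
    def test_depth_matches_per_base_recount(self, blocks):
        records = [
            make_record(name=f"r{i}", pos=pos, cigar=[("M", n)])
            for i, (pos, n) in enumerate(blocks)
        ]
        arr = compute_coverage(records, {"chr1": 1_000}).depths["chr1"]
        expected = np.zeros(1_000)
        for pos, n in blocks:
            for j in range(pos, pos + n):
                expected[j] += 1
        assert (arr == expected).all()


class TestBPM:
    def test_single_read_normalization_identity(self):
        for length in (50, 128, 200):
            rec = make_record(pos=0, cigar=[("M", length)])
            bpm = normalize_bpm(compute_coverage([rec], {"chr1": 1_000}))
            assert np.allclose(bpm.depths["chr1"][:length], 1e6 / length)
            assert abs(bpm.total_sum() - 1e6) < 1e-6 * 1e6

    def test_duplicating_reads_leaves_bpm_unchanged(self):
        records = [make_record(name=f"r{i}", pos=i * 7, cigar=[("M", 90)]) for i in range(10)]
        once = normalize_bpm(compute_coverage(records, {"chr1": 1_000}))
        twice = normalize_bpm(compute_coverage(records + records, {"chr1": 1_000}))
        assert np.allclose(once.depths["chr1"], twice.depths["chr1"])

    def test_zero_aligned_bases_is_an_error(self):
        with pytest.raises(ValueError, match="enrichment"):
            normalize_bpm(compute_coverage([], {"chr1": 100}))

    def test_read_length_independence_of_regional_bpm(self):
        """Equal base throughput at 100 vs 200 bp gives matching regional BPM."""
        template_rng = np.random.default_rng(5)
        template = "".join("ACGT"[i] for i in template_rng.integers(0, 4, 20_000))
        means = {}
        for read_len, n_pairs in ((100, 2_000), (200, 1_000)):
            config = SimulationConfig(
                seed=2, read_length=read_len, insert_mean=500, insert_sd=30,
                error_rate=0.0, total_ref_length=30_000, element_length=1_000,
            )
            reads = simulate_read_pairs(template, n_pairs, config, template_id="t")
            records = []
            for pair in reads.pairs:
                records.append(make_record(name=pair.name + "a", chrom="t",
                                           pos=pair.offset, cigar=[("M", read_len)]))
                records.append(make_record(name=pair.name + "b", chrom="t",
                                           pos=pair.offset + pair.insert - read_len,
                                           cigar=[("M", read_len)], is_read1=False))
            bpm = normalize_bpm(compute_coverage(records, {"t": 20_000}))
            means[read_len] = bpm.region_mean("t", 5_000, 15_000)
        assert abs(means[100] - means[200]) / means[200] < 0.10


# ---------------------------------------------------------------------------
# peaks


def as_track(x):
    from eccscout.evidence import CoverageTrack

    return CoverageTrack(depths={"c": np.asarray(x, dtype=float)},
                         total_aligned_bases=1, normalized=True)


class TestPeaks:
    def test_constant_track_has_no_peaks(self):
        assert find_peaks(as_track(np.full(100, 3.0))) == []

    def test_rectangular_elevation(self):
        x = np.full(200, 0.5)
        x[80:120] = 5.0
        (peak,) = find_peaks(as_track(x))
        assert peak.apex_position == 80  # leftmost plateau position
        assert peak.prominence == pytest.approx(4.5)
        assert (peak.start, peak.end) == (80, 120)

    def test_sub_threshold_prominence_rejected(self):
        x = np.full(100, 1.0)
        x[50] = 1.5  # prominence 0.5 < 1
        assert find_peaks(as_track(x)) == []

    def test_region_extends_to_prominence_base(self):
        x = np.array([0.0, 0, 2, 4, 6, 4, 2, 0, 0], dtype=float)
        (peak,) = find_peaks(as_track(x))
        assert peak.apex_position == 4
        assert peak.prominence == pytest.approx(6.0)
        # region: positions with depth > apex - prominence = 0
        assert (peak.start, peak.end) == (2, 7)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60)
    def test_matches_bruteforce_oracle_on_random_tracks(self, seed):
        from tests_support import prominence_oracle, random_track_array

        rng = np.random.default_rng(seed)
        x = random_track_array(rng, int(rng.integers(10, 2_000)))
        found = sorted(find_peaks(as_track(x), min_prominence=1.0),
                       key=lambda p: p.apex_position)
        expected = prominence_oracle(x, 1.0)
        assert [p.apex_position for p in found] == [e[0] for e in expected]
        for p, e in zip(found, expected):
            assert p.apex_height == pytest.approx(e[1])
            assert p.prominence == pytest.approx(e[2])
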