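from __future__ import annotations

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnaevol import clusters as cl
from srnaevol.io import AlignmentRecord
from srnaevol.profiles import AbundanceProfile


def aln(start=0, length=21, chrom="chr1", hits=1, nm=0, read_id="r", first="A"):
    return AlignmentRecord(
        read_id=read_id, reference_name=chrom, start=start, strand="+",
        mismatches=nm, hit_count=hits, read_length=length, first_nt=first,
    )


# ---------------------------------------------------------------------------
# partitioning


def test_partition_tiles_with_partial_tail():
    windows = cl.partition_genome({"chr1": 5000}, 2000)
    assert [(w.start, w.end) for w in windows] == [(0, 2000), (2000, 4000), (4000, 5000)]


def test_partition_single_window_chromosome():
    assert len(cl.partition_genome({"chr1": 2000}, 2000)) == 1


def test_partition_rejects_zero_window():
    with pytest.raises(ValueError):
        cl.partition_genome({"chr1": 100}, 0)


@given(
    lengths=st.dictionaries(
        st.sampled_from(["c1", "c2", "c3"]), st.integers(1, 10_000), min_size=1
    ),
    window=st.integers(1, 3000),
)
@settings(max_examples=50, deadline=None)
def test_partition_covers_every_position_exactly_once(lengths, window):
    windows = cl.partition_genome(lengths, window)
    for chrom, length in lengths.items():
        ws = sorted((w for w in windows if w.chrom == chrom), key=lambda w: w.start)
        assert ws[0].start == 0
        assert ws[-1].end == length
        for a, b in zip(ws, ws[1:]):
            assert a.end == b.start  # disjoint and gap-free


# ---------------------------------------------------------------------------
# counting


def test_pirna_reads_counted_in_pirna_class():
    windows = cl.partition_genome({"chr1": 2000})
    cl.count_window_reads(windows, [aln(start=i, length=27) for i in range(100)])
    counts = windows[0].class_counts(cl.SizeClassScheme())
    assert counts == {"siRNA": 0, "miRNA": 0, "piRNA": 100, "other": 0}


def test_length_22_counts_in_both_sirna_and_mirna():
    windows = cl.partition_genome({"chr1": 2000})
    cl.count_window_reads(windows, [aln(length=22)])
    counts = windows[0].class_counts(cl.SizeClassScheme())
    assert counts["siRNA"] == 1 and counts["miRNA"] == 1
    assert windows[0].total_reads == 1  # double class counting, single read


def test_fractional_mode_splits_multimappers():
    windows = cl.partition_genome({"chr1": 4000})
    records = [aln(start=100, hits=2), aln(start=2100, hits=2)]
    cl.count_window_reads(windows, records, count_mode="fractional")
    assert windows[0].total_reads == pytest.approx(0.5)
    assert windows[1].total_reads == pytest.approx(0.5)


def test_count_conservation_in_full_mode(rng):
    windows = cl.partition_genome({"chr1": 10_000}, 2000)
    records = [
        aln(start=int(rng.integers(0, 9970)), length=int(rng.integers(15, 30)),
            read_id=f"r{i}")
        for i in range(500)
    ]
    cl.count_window_reads(windows, records)
    assert sum(w.total_reads for w in windows) == 500


def test_alignment_beyond_chromosome_rejected():
    windows = cl.partition_genome({"chr1": 2000})
    with pytest.raises(ValueError, match="beyond"):
        cl.count_window_reads(windows, [aln(start=2500)])


# ---------------------------------------------------------------------------
# classification


def _window_with(counts: dict[int, float]) -> cl.GenomeWindow:
    w = cl.GenomeWindow("chr1", 0, 2000)
    w.counts_by_length = Counter(counts)
    return w


def test_classify_argmax():
    w = _window_with({21: 60, 27: 40})
    assert cl.classify_window(w) == "siRNA"


def test_classify_tie_at_22_goes_to_sirna():
    # 22 nt reads count equally to siRNA and miRNA; tie order decides.
    w = _window_with({22: 50})
    assert cl.classify_window(w) == "siRNA"


def test_classify_below_min_reads_is_unclassified():
    w = _window_with({27: 5})
    assert cl.classify_window(w, min_reads=10) == "unclassified"


@given(
    st.dictionaries(st.integers(15, 35), st.integers(1, 50), min_size=1, max_size=10)
)
@settings(max_examples=100, deadline=None)
def test_classify_matches_bruteforce_over_raw_lengths(counts):
    """Oracle equivalence: recompute class counts from the raw read-length
    multiset with literal range checks and apply argmax + tie order."""
    w = _window_with(counts)
    got = cl.classify_window(w, min_reads=1)
    ranges = {"siRNA": (20, 22), "miRNA": (22, 24), "piRNA": (24, 29), "other": (15, 19)}
    brute = dict.fromkeys(ranges, 0)
    for length, n in counts.items():
        for label, (lo, hi) in ranges.items():
            if lo <= length <= hi:
                brute[label] += n
    best = max(brute.values())
    tie_order = ["piRNA", "siRNA", "miRNA", "other"]
    expected = min((k for k, v in brute.items() if v == best), key=tie_order.index)
    assert got == expected


def test_classification_is_permutation_invariant(rng):
    lengths = [int(rng.integers(15, 35)) for _ in range(200)]
    records = [aln(start=10 * i % 1900, length=L, read_id=f"r{i}")
               for i, L in enumerate(lengths)]
    labels = []
    for order in (records, records[::-1]):
        windows = cl.partition_genome({"chr1": 2000})
        cl.count_window_reads(windows, order)
        labels.append(cl.classify_window(windows[0]))
    assert labels[0] == labels[1]


# ---------------------------------------------------------------------------
# merging


def _classified(chrom, start, end, label):
    w = cl.GenomeWindow(chrom, start, end)
    w.class_label = label
    return w


def test_adjacent_same_class_windows_merge():
    ws = [_classified("chr1", 0, 2000, "piRNA"), _classified("chr1", 2000, 4000, "piRNA")]
    (c,) = cl.merge_windows(ws, genome_tag="g1")
    assert (c.start, c.end, c.member_windows) == (0, 4000, 2)
    assert c.cluster_id == "g1_chr1_0"


def test_isolated_window_forms_single_cluster():
    ws = [
        _classified("chr1", 0, 2000, "unclassified"),
        _classified("chr1", 2000, 4000, "piRNA"),
        _classified("chr1", 4000, 6000, "unclassified"),
    ]
    (c,) = cl.merge_windows(ws)
    assert (c.start, c.end) == (2000, 4000)


def test_different_classes_do_not_merge():
    ws = [_classified("chr1", 0, 2000, "piRNA"), _classified("chr1", 2000, 4000, "siRNA")]
    assert len(cl.merge_windows(ws)) == 2


def test_merge_disabled_keeps_windows_separate():
    ws = [_classified("chr1", 0, 2000, "piRNA"), _classified("chr1", 2000, 4000, "piRNA")]
    assert len(cl.merge_windows(ws, merge_adjacent=False)) == 2


def test_merge_rejects_unsorted_windows():
    ws = [_classified("chr1", 2000, 4000, "piRNA"), _classified("chr1", 0, 2000, "piRNA")]
    with pytest.raises(ValueError, match="sorted"):
        cl.merge_windows(ws)


# ---------------------------------------------------------------------------
# reference and quantification


def test_cluster_reference_is_genome_substring():
    genome = {"chr1": "ACGT" * 600}
    c = cl.SmallRNACluster("g_chr1_0", "chr1", 0, 2000, "piRNA", 1)
    ref = cl.build_cluster_reference(genome, [c])
    assert ref["g_chr1_0"] == genome["chr1"][:2000]


def test_cluster_reference_empty_list():
    assert cl.build_cluster_reference({"chr1": "ACGT"}, []) == {}


def test_cluster_reference_out_of_range_rejected():
    c = cl.SmallRNACluster("g_chr1_0", "chr1", 0, 2000, "piRNA", 1)
    with pytest.raises(ValueError):
        cl.build_cluster_reference({"chr1": "ACGT"}, [c])


def test_rpm_arithmetic():
    records = [aln(chrom="cl1", start=i, read_id=f"r{i}") for i in range(50)]
    profiles = cl.quantify_clusters(records, total_mapped=2_000_000)
    assert profiles["cl1"].total_rpm == pytest.approx(25.0)


def test_two_mismatch_alignment_excluded_at_max_one():
    records = [aln(chrom="cl1", nm=2)]
    profiles = cl.quantify_clusters(records, total_mapped=100, cluster_ids=["cl1"])
    assert profiles["cl1"].total_count == 0


def test_no_surviving_alignments_gives_zero_profile():
    profiles = cl.quantify_clusters([], total_mapped=100, cluster_ids=["cl1"])
    assert profiles["cl1"].total_rpm == 0.0


def test_zero_total_mapped_rejected():
    with pytest.raises(ValueError):
        cl.quantify_clusters([], total_mapped=0)


# ---------------------------------------------------------------------------
# reporting filter


def _profile_with_rpm(target_rpm: float, total_mapped=1_000_000) -> AbundanceProfile:
    p = AbundanceProfile(total_mapped=total_mapped)
    for _ in range(int(target_rpm * total_mapped / 1e6)):
        p.add(21, "A")
    return p


def test_low_rpm_cluster_absent_from_report():
    profiles = {"lo": _profile_with_rpm(25), "hi": _profile_with_rpm(80)}
    table = cl.report_filter(profiles, min_rpm=50)
    assert list(table.index) == ["hi"]


def test_exactly_threshold_rpm_dropped():
    # strictly-greater semantics: exactly 50 RPM is not reported
    profiles = {"edge": _profile_with_rpm(50.0)}
    assert len(cl.report_filter(profiles, min_rpm=50)) == 0


def test_zero_threshold_reports_everything():
    profiles = {"a": _profile_with_rpm(1), "b": _profile_with_rpm(2)}
    assert len(cl.report_filter(profiles, min_rpm=0)) == 2
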