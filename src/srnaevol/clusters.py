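"""Genome-windowed small-RNA cluster prediction and quantification.

The genome is tiled into fixed windows (default 2 kb).  Aligned reads are
counted per window by length, windows are typed by the dominant size class
(siRNA 20-22 nt, miRNA 22-24 nt, piRNA 24-29 nt, other 15-19 nt), adjacent
same-class windows are merged into named clusters, and reads are
re-quantified against the cluster reference at <=1 mismatch, normalised to
reads per million mapped (RPM).

The size-class ranges overlap at 22 nt (siRNA/miRNA) and 24 nt
(miRNA/piRNA); a read is counted in every class whose range contains its
length and exact ties are broken by a fixed class priority.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .io import AlignmentRecord
from .profiles import AbundanceProfile

__all__ = [
    "SizeClassScheme",
    "GenomeWindow",
    "SmallRNACluster",
    "partition_genome",
    "count_window_reads",
    "classify_window",
    "classify_windows",
    "merge_windows",
    "build_cluster_reference",
    "quantify_clusters",
    "report_filter",
]

DEFAULT_TIE_ORDER = ("piRNA", "siRNA", "miRNA", "other")


@dataclass(frozen=True)
class SizeClassScheme:
    """Ordered map of small-RNA class -> inclusive read-length range (nt)."""

    ranges: tuple[tuple[str, tuple[int, int]], ...] = (
        ("siRNA", (20, 22)),
        ("miRNA", (22, 24)),
        ("piRNA", (24, 29)),
        ("other", (15, 19)),
    )

    def __post_init__(self) -> None:
        for label, (lo, hi) in self.ranges:
            if lo > hi:
                raise ValueError(f"size class {label}: low {lo} > high {hi}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.ranges)

    def classes_for_length(self, length: int) -> list[str]:
        """Every class whose range contains ``length`` (ranges may overlap)."""
        return [label for label, (lo, hi) in self.ranges if lo <= length <= hi]

    def range_of(self, label: str) -> tuple[int, int]:
        return dict(self.ranges)[label]


@dataclass
class GenomeWindow:
    """A fixed-width genomic interval with per-read-length counts."""

    chrom: str
    start: int
    end: int
    counts_by_length: Counter = field(default_factory=Counter)
    class_label: str = "unclassified"

    @property
    def total_reads(self) -> float:
        return sum(self.counts_by_length.values())

    def class_counts(self, scheme: SizeClassScheme) -> dict[str, float]:
        counts = {label: 0.0 for label in scheme.labels}
        for length, n in self.counts_by_length.items():
            for label in scheme.classes_for_length(length):
                counts[label] += n
        return counts


@dataclass
class SmallRNACluster:
    """Merged same-class windows, named <genome_tag>_<chrom>_<start>."""

    cluster_id: str
    chrom: str
    start: int
    end: int
    class_label: str
    member_windows: int
    rpm: float = 0.0


def partition_genome(
    chrom_lengths: dict[str, int], window_size: int = 2000
) -> list[GenomeWindow]:
    """Tile each chromosome into disjoint windows covering every position.

    The final window of a chromosome may be shorter than ``window_size``.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    windows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r}: non-positive length {length}")
        for start in range(0, length, window_size):
            windows.append(GenomeWindow(chrom, start, min(start + window_size, length)))
    return windows


def count_window_reads(
    windows: list[GenomeWindow],
    alignments,
    scheme: SizeClassScheme | None = None,
    count_mode: str = "full",
) -> list[GenomeWindow]:
    """Assign each alignment to the window containing its start position.

    ``full`` mode adds 1 per reported placement; ``fractional`` adds
    1/hit_count so a multi-mapper contributes one read in total.  Strands
    are pooled.
    """
    if count_mode not in ("full", "fractional"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    del scheme  # class counts are derived lazily from counts_by_length
    by_chrom: dict[str, list[GenomeWindow]] = {}
    window_size: dict[str, int] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, ws in by_chrom.items():
        ws.sort(key=lambda w: w.start)
        window_size[chrom] = ws[0].end - ws[0].start
    for aln in alignments:
        if aln.reference_name not in by_chrom:
            raise ValueError(f"alignment {aln.read_id!r}: unknown reference {aln.reference_name!r}")
        ws = by_chrom[aln.reference_name]
        idx = aln.start // window_size[aln.reference_name]
        if idx >= len(ws) or aln.start >= ws[-1].end:
            raise ValueError(
                f"alignment {aln.read_id!r}: start {aln.start} beyond end of "
                f"{aln.reference_name}"
            )
        weight = 1.0 if count_mode == "full" else 1.0 / aln.hit_count
        ws[idx].counts_by_length[aln.read_length] += weight
    return windows


def classify_window(
    window: GenomeWindow,
    scheme: SizeClassScheme | None = None,
    min_reads: float = 10,
    tie_order: tuple[str, ...] = DEFAULT_TIE_ORDER,
) -> str:
    """Type a window by the size class with the most reads.

    Windows with fewer than ``min_reads`` total reads stay unclassified;
    exact ties are resolved by ``tie_order`` priority.
    """
    scheme = scheme or SizeClassScheme()
    if window.total_reads < min_reads:
        window.class_label = "unclassified"
        return window.class_label
    counts = window.class_counts(scheme)
    best = max(counts.values())
    winners = [label for label, n in counts.items() if n == best]
    window.class_label = min(winners, key=tie_order.index)
    return window.class_label


def classify_windows(
    windows: list[GenomeWindow],
    scheme: SizeClassScheme | None = None,
    min_reads: float = 10,
    tie_order: tuple[str, ...] = DEFAULT_TIE_ORDER,
) -> list[GenomeWindow]:
    for w in windows:
        classify_window(w, scheme, min_reads, tie_order)
    return windows


def merge_windows(
    windows: list[GenomeWindow],
    genome_tag: str = "genome",
    merge_adjacent: bool = True,
) -> list[SmallRNACluster]:
    """Merge maximal runs of adjacent same-class windows into clusters.

    Cluster ids follow the <genome_tag>_<chrom>_<start> convention, the
    start being the 0-based start of the first member window.
    """
    for prev, cur in zip(windows, windows[1:]):
        if (cur.chrom, cur.start) < (prev.chrom, prev.start):
            raise ValueError("windows must be sorted by (chrom, start)")
    clusters: list[SmallRNACluster] = []
    open_cluster: SmallRNACluster | None = None
    for w in windows:
        if w.class_label == "unclassified":
            open_cluster = None
            continue
        if (
            merge_adjacent
            and open_cluster is not None
            and open_cluster.chrom == w.chrom
            and open_cluster.end == w.start
            and open_cluster.class_label == w.class_label
        ):
            open_cluster.end = w.end
            open_cluster.member_windows += 1
        else:
            open_cluster = SmallRNACluster(
                cluster_id=f"{genome_tag}_{w.chrom}_{w.start}",
                chrom=w.chrom,
                start=w.start,
                end=w.end,
                class_label=w.class_label,
                member_windows=1,
            )
            clusters.append(open_cluster)
    return clusters


def build_cluster_reference(
    genome: dict[str, str], clusters: list[SmallRNACluster]
) -> dict[str, str]:
    """Extract one FASTA record per cluster: id = cluster_id, sequence =
    the genome substring [start, end)."""
    out: dict[str, str] = {}
    for c in clusters:
        if c.chrom not in genome:
            raise ValueError(f"cluster {c.cluster_id}: unknown chromosome {c.chrom!r}")
        if c.end > len(genome[c.chrom]) or c.start < 0:
            raise ValueError(
                f"cluster {c.cluster_id}: coordinates outside {c.chrom} "
                f"(length {len(genome[c.chrom])})"
            )
        out[c.cluster_id] = genome[c.chrom][c.start : c.end]
    return out


def quantify_clusters(
    alignments,
    total_mapped: float,
    cluster_ids: list[str] | None = None,
    max_mismatch: int = 1,
    length_range: tuple[int, int] = (15, 35),
) -> dict[str, AbundanceProfile]:
    """Per-cluster (length x first 5' base) counts from a re-mapping of the
    reads to the cluster reference, scaled to RPM.

    Alignments with more than ``max_mismatch`` mismatches are discarded.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    profiles: dict[str, AbundanceProfile] = {
        cid: AbundanceProfile(length_range=length_range, total_mapped=total_mapped)
        for cid in (cluster_ids or [])
    }
    for aln in alignments:
        if aln.mismatches > max_mismatch:
            continue
        prof = profiles.setdefault(
            aln.reference_name,
            AbundanceProfile(length_range=length_range, total_mapped=total_mapped),
        )
        prof.add(aln.read_length, aln.first_nt)
    return profiles


def report_filter(
    profiles: dict[str, AbundanceProfile], min_rpm: float = 50.0
) -> pd.DataFrame:
    """Reporting table of per-cluster RPM by (length, first base), keeping
    only clusters with total RPM strictly greater than ``min_rpm``.

    The filter affects reporting only; the ``profiles`` mapping is left
    untouched.
    """
    rows = {}
    for cid, prof in profiles.items():
        if prof.total_rpm > min_rpm:
            rpm = prof.rpm.stack()
            rpm.index = [f"{length}_{base}" for length, base in rpm.index]
            rows[cid] = rpm
    table = pd.DataFrame(rows).T
    table.index.name = "cluster_id"
    return table.sort_index()
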