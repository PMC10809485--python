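"""Read preprocessing and abundance profiling of small-RNA libraries.

Profiles are (read length x first 5' nucleotide) count matrices, normalised
to reads per million mapped (RPM).  Counting is restricted to unique
mappers when profiling the genome, mirroring the distinction between
permissive multimapping (cluster prediction) and unique-mapper profiling.

The sequential feature assignment maps each read to the first feature class
in a priority hierarchy for which it is a unique mapper; non-unique and
unmapped reads are passed to the next round, so every read ends with
exactly one label (a feature or "unassigned").

First-base matrices are indexed by T internally; displays use U per
small-RNA convention (see :meth:`AbundanceProfile.rpm_display`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean

import pandas as pd

from .io import ReadRecord

__all__ = [
    "AbundanceProfile",
    "FeatureHierarchy",
    "preprocess_reads",
    "genome_size_profile",
    "quantify_mirnas",
    "sequential_assign",
]

_BASES = ("A", "C", "G", "T")


class AbundanceProfile:
    """Counts and RPM by (length, first 5' base) for one reference set."""

    def __init__(
        self,
        length_range: tuple[int, int] = (18, 35),
        total_mapped: float | None = None,
    ):
        lo, hi = length_range
        if lo > hi:
            raise ValueError(f"invalid length range {length_range}")
        self.length_range = (lo, hi)
        self.total_mapped = total_mapped
        self.counts = pd.DataFrame(
            0.0, index=range(lo, hi + 1), columns=list(_BASES)
        )
        self.counts.index.name = "length"

    def add(self, length: int, first_nt: str, weight: float = 1.0) -> bool:
        """Count one read; lengths outside the range (and N first bases)
        are ignored.  Returns whether the read was counted."""
        lo, hi = self.length_range
        if not (lo <= length <= hi) or first_nt not in _BASES:
            return False
        self.counts.loc[length, first_nt] += weight
        return True

    @property
    def total_count(self) -> float:
        return float(self.counts.to_numpy().sum())

    @property
    def rpm(self) -> pd.DataFrame:
        if not self.total_mapped or self.total_mapped <= 0:
            raise ValueError("total_mapped must be set and positive to compute RPM")
        return self.counts * (1e6 / self.total_mapped)

    @property
    def total_rpm(self) -> float:
        return float(self.rpm.to_numpy().sum())

    def rpm_display(self) -> pd.DataFrame:
        """RPM matrix with the first-base column T shown as U."""
        return self.rpm.rename(columns={"T": "U"})


@dataclass
class FeatureHierarchy:
    """Ordered (feature_name, reference FASTA mapping) priority list."""

    features: list[tuple[str, dict[str, str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.features]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")

    @property
    def order(self) -> list[str]:
        return [name for name, _ in self.features]


def preprocess_reads(
    reads,
    trim5: int = 6,
    min_len: int = 15,
    min_mean_q: float = 20.0,
    drop_ambiguous: bool = True,
    per_base_min: bool = False,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Trim the 5'-ligated extra bases and apply quality/length filters.

    Each read loses its first ``trim5`` bases, then is dropped if its mean
    Phred quality (or, with ``per_base_min``, its minimum per-base quality)
    is below ``min_mean_q``, if it contains an N, or if it is shorter than
    ``min_len``.  Returns the kept reads and a tally of rejection reasons.
    """
    if trim5 < 0:
        raise ValueError("trim5 must be >= 0")
    kept: list[ReadRecord] = []
    tally = {"kept": 0, "too_short": 0, "low_quality": 0, "ambiguous": 0}
    for read in reads:
        seq = read.sequence[trim5:]
        quals = read.qualities[trim5:] if read.qualities is not None else None
        if len(seq) < min_len:
            tally["too_short"] += 1
            continue
        if quals is not None:
            q = min(quals) if per_base_min else fmean(quals)
            if q < min_mean_q:
                tally["low_quality"] += 1
                continue
        if drop_ambiguous and "N" in seq:
            tally["ambiguous"] += 1
            continue
        kept.append(ReadRecord(read.read_id, seq, quals))
        tally["kept"] += 1
    return kept, tally


def genome_size_profile(
    alignments,
    total_mapped: float,
    unique_only: bool = True,
    max_mismatch: int = 1,
    length_range: tuple[int, int] = (18, 35),
) -> AbundanceProfile:
    """Genome-wide size/first-base distribution from unique mappers."""
    profile = AbundanceProfile(length_range=length_range, total_mapped=total_mapped)
    for aln in alignments:
        if unique_only and aln.hit_count != 1:
            continue
        if aln.mismatches > max_mismatch:
            continue
        profile.add(aln.read_length, aln.first_nt)
    return profile


def quantify_mirnas(
    alignments,
    reference_ids,
    total_mapped: float,
    max_mismatch: int = 1,
    length_range: tuple[int, int] = (18, 26),
) -> dict[str, AbundanceProfile]:
    """Per-miRNA profiles from alignments to a curated mature-miRNA set."""
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValueError("miRNA reference is empty")
    profiles = {
        rid: AbundanceProfile(length_range=length_range, total_mapped=total_mapped)
        for rid in reference_ids
    }
    for aln in alignments:
        if aln.mismatches > max_mismatch:
            continue
        if aln.reference_name not in profiles:
            raise ValueError(f"alignment to unknown miRNA {aln.reference_name!r}")
        profiles[aln.reference_name].add(aln.read_length, aln.first_nt)
    return profiles


def sequential_assign(
    read_ids,
    hierarchy_order: list[str],
    per_round_alignments: dict[str, list],
    max_mismatch: int = 1,
    total_mapped: float | None = None,
    length_range: tuple[int, int] = (18, 35),
) -> tuple[dict[str, str], dict[str, AbundanceProfile]]:
    """Assign reads to feature classes by sequential unique mapping.

    At each round, reads with exactly one reported alignment
    (``hit_count == 1``) within the mismatch bound are assigned to that
    round's feature and removed; everything else continues.  The result is
    a partition: every input read is labelled with a feature or
    ``"unassigned"``.
    """
    remaining = set(read_ids)
    if total_mapped is None:
        total_mapped = len(remaining)
    assignment: dict[str, str] = {}
    profiles: dict[str, AbundanceProfile] = {}
    for feature in hierarchy_order:
        profile = AbundanceProfile(length_range=length_range, total_mapped=total_mapped)
        profiles[feature] = profile
        for aln in per_round_alignments.get(feature, []):
            if aln.read_id in assignment:
                raise ValueError(
                    f"round {feature!r}: alignment stream mentions read "
                    f"{aln.read_id!r} already assigned to {assignment[aln.read_id]!r}"
                )
            if aln.read_id not in remaining:
                continue
            if aln.hit_count == 1 and aln.mismatches <= max_mismatch:
                assignment[aln.read_id] = feature
                profile.add(aln.read_length, aln.first_nt)
        remaining -= set(assignment)
    for read_id in remaining:
        assignment[read_id] = "unassigned"
    return assignment, profiles
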