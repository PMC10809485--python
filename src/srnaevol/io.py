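"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open; the 1-based conventions of
SAM and VCF are converted exactly once, at the format boundary.  Reads with
ambiguous (N) bases are carried through parsing and rejected later by the
preprocessing filter — parsing and policy are kept separate.

FASTA/FASTQ parsing is delegated to Biopython, BAM and VCF to pysam, and
newick to Bio.Phylo.  SAM *text* is parsed natively so that the whole test
suite runs on plain-text fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import Phylo, SeqIO
from Bio.Phylo.BaseTree import Tree

__all__ = [
    "FormatError",
    "ReadRecord",
    "AlignmentRecord",
    "VariantRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_alignments",
    "write_sam",
    "read_bed",
    "write_bed",
    "read_vcf",
    "read_newick",
    "write_newick",
    "get_logger",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def get_logger(stage: str) -> logging.Logger:
    logger = logging.getLogger(f"srnaevol.{stage}")
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@dataclass
class ReadRecord:
    """A small-RNA read: sequence over {A,C,G,T,N} plus optional Phred scores."""

    read_id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: {len(self.qualities)} quality scores "
                f"for {len(self.sequence)} bases"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def first_nt(self) -> str:
        return self.sequence[0] if self.sequence else ""


@dataclass
class AlignmentRecord:
    """One reported placement of a read on a reference.

    ``start`` is 0-based.  ``hit_count`` is the number of placements reported
    for this read in the mapping round it came from (1 == unique mapper).
    ``read_length`` and ``first_nt`` describe the read in its own 5'→3'
    orientation, independent of strand.
    """

    read_id: str
    reference_name: str
    start: int
    strand: str = "+"
    mismatches: int = 0
    hit_count: int = 1
    read_length: int = 0
    first_nt: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"alignment {self.read_id!r}: negative start")
        if self.mismatches < 0:
            raise ValueError(f"alignment {self.read_id!r}: negative mismatch count")
        if self.hit_count < 1:
            raise ValueError(f"alignment {self.read_id!r}: hit_count < 1")

    @property
    def end(self) -> int:
        return self.start + self.read_length


@dataclass
class VariantRecord:
    """A VCF record with the position already converted to 0-based."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, tuple[int | None, ...]] = field(default_factory=dict)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or any(len(a) != 1 for a in self.alts)

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def is_biallelic_snp(self) -> bool:
        return not self.is_indel and not self.is_multiallelic


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse a FASTA file into an id → sequence mapping, order preserved."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        records[rec.id] = seq
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a Phred+33 FASTQ file (constant memory)."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:  # Biopython signals malformed records this way
        raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            quals = read.qualities or [40] * read.length
            qual_str = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual_str}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# SAM / BAM


def _parse_sam_tags(fields: Sequence[str]) -> dict[str, str]:
    tags = {}
    for raw in fields:
        parts = raw.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    return tags


def _sam_record_to_alignment(
    fields: list[str], references: set[str], hit_count: int
) -> AlignmentRecord:
    flag = int(fields[1])
    rname, pos = fields[2], int(fields[3])
    seq = fields[9].upper()
    if rname not in references:
        raise FormatError(f"SAM record {fields[0]!r}: reference {rname!r} not declared in header")
    tags = _parse_sam_tags(fields[11:])
    nm = int(tags.get("NM", 0))
    reverse = bool(flag & 0x10)
    # SEQ is stored reference-forward; the read's own 5' base on the minus
    # strand is the complement of the last stored base.
    if seq == "*":
        first = ""
        length = 0
    elif reverse:
        first = seq[-1].translate(_COMPLEMENT)
        length = len(seq)
    else:
        first = seq[0]
        length = len(seq)
    return AlignmentRecord(
        read_id=fields[0],
        reference_name=rname,
        start=pos - 1,
        strand="-" if reverse else "+",
        mismatches=nm,
        hit_count=hit_count,
        read_length=length,
        first_nt=first,
    )


def _iter_sam_text(path: str | Path, stats: dict) -> Iterator[AlignmentRecord]:
    references: set[str] = set()
    saw_header = False
    # First pass: per-read placement counts, used when NH tags are absent.
    # The dict holds one int per read id, not the records themselves.
    per_read: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                saw_header = True
                if line.startswith("@SQ"):
                    for f in line.rstrip("\n").split("\t")[1:]:
                        if f.startswith("SN:"):
                            references.add(f[3:])
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise FormatError(f"{path}: truncated SAM record line")
            if int(fields[1]) & 0x4:
                continue
            per_read[fields[0]] = per_read.get(fields[0], 0) + 1
    if not saw_header:
        raise FormatError(f"{path}: SAM file has no header")
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if int(fields[1]) & 0x4:
                stats["unmapped"] += 1
                continue
            tags = _parse_sam_tags(fields[11:])
            hits = int(tags["NH"]) if "NH" in tags else per_read[fields[0]]
            yield _sam_record_to_alignment(fields, references, hits)
            stats["mapped"] += 1


def _iter_bam(path: str | Path, stats: dict) -> Iterator[AlignmentRecord]:
    import pysam

    with pysam.AlignmentFile(str(path), "rb") as bam:
        per_read: dict[str, int] = {}
        any_nh = True
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            if not rec.has_tag("NH"):
                any_nh = False
            per_read[rec.query_name] = per_read.get(rec.query_name, 0) + 1
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped:
                stats["unmapped"] += 1
                continue
            seq = (rec.query_sequence or "").upper()
            if rec.is_reverse:
                first = seq[-1].translate(_COMPLEMENT) if seq else ""
            else:
                first = seq[0] if seq else ""
            hits = rec.get_tag("NH") if any_nh and rec.has_tag("NH") else per_read[rec.query_name]
            yield AlignmentRecord(
                read_id=rec.query_name,
                reference_name=rec.reference_name,
                start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                hit_count=int(hits),
                read_length=len(seq),
                first_nt=first,
            )
            stats["mapped"] += 1


def read_alignments(
    path: str | Path, format: str | None = None, stats: dict | None = None
) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM (native) or BAM (pysam) file.

    Unmapped records are skipped but counted in ``stats['unmapped']``.
    ``hit_count`` comes from the NH tag when present, otherwise from the
    per-read number of mapped records in the file.
    """
    if stats is None:
        stats = {}
    stats.setdefault("unmapped", 0)
    stats.setdefault("mapped", 0)
    if format is None:
        format = "BAM" if str(path).endswith(".bam") else "SAM"
    if format.upper() == "BAM":
        yield from _iter_bam(path, stats)
    else:
        yield from _iter_sam_text(path, stats)


def write_sam(
    alignments: Iterable[tuple],
    chrom_lengths: dict[str, int],
    path: str | Path,
) -> int:
    """Write SAM text.  ``alignments`` yields (read_id, chrom, start0, strand,
    sequence_read_orientation, mismatches, hit_count)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for read_id, chrom, start, strand, seq, nm, nh in alignments:
            flag = 16 if strand == "-" else 0
            stored = seq[::-1].translate(_COMPLEMENT) if strand == "-" else seq
            fh.write(
                f"{read_id}\t{flag}\t{chrom}\t{start + 1}\t255\t{len(seq)}M\t*\t0\t0\t"
                f"{stored}\t*\tNM:i:{nm}\tNH:i:{nh}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: Iterable[tuple], path: str | Path) -> int:
    """Write 0-based half-open intervals: (chrom, start, end[, name])."""
    n = 0
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            if end <= start:
                raise FormatError(f"BED interval {chrom}:{start}-{end}: end <= start")
            rest = "\t" + "\t".join(str(x) for x in iv[3:]) if len(iv) > 3 else ""
            fh.write(f"{chrom}\t{start}\t{end}{rest}\n")
            n += 1
    return n


def read_bed(path: str | Path) -> list[tuple]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if end <= start:
                raise FormatError(f"{path}: BED interval {chrom}:{start}-{end}: end <= start")
            intervals.append((chrom, start, end, *f[3:]))
    return intervals


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read VCF v4.x via pysam; POS is converted to 0-based.

    Non-SNP records are retained (flagged through ``is_indel`` /
    ``is_multiallelic``) so that downstream filters can tally them.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            genotypes = {
                sample: tuple(rec.samples[sample]["GT"]) for sample in rec.samples
            }
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    genotypes=genotypes,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: Tree | str, path: str | Path) -> None:
    if isinstance(tree, str):
        with open(path, "w") as fh:
            fh.write(tree.rstrip("\n") + "\n")
    else:
        Phylo.write(tree, str(path), "newick")


def read_newick(path: str | Path) -> Tree:
    return Phylo.read(str(path), "newick")
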