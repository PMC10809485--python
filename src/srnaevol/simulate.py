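"""Seeded synthetic data with known ground truth for every pipeline stage.

Three generators:

* a random genome plus planted small-RNA clusters, each emitting reads with
  a class-specific length spectrum, 5'-nucleotide bias and strand mix
  (FASTQ + truth SAM + truth BED) — no external aligner is needed because
  the truth SAM records each read at its generating locus;
* coding-sequence populations with controlled polymorphism (theta),
  divergence to an outgroup and nonsynonymous/synonymous rate ratio omega,
  imposed by acceptance–rejection on proposed mutations;
* protein-domain families derived from a common ancestor at controlled
  per-residue divergences.

Every generator is a pure function of its seed and parameters.  The 5'
bias is honoured by rejection-sampling the read start among locus
positions whose genomic base equals the sampled first nucleotide, so reads
remain exact genome substrings when the error rate is zero.  miRNA loci
emit reads from two fixed start positions (mature/star pile-ups) chosen at
generation time so their 5' bases follow the bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .clusters import SizeClassScheme
from .io import AlignmentRecord, ReadRecord
from .mkt import CODON_TO_AA, SENSE_CODONS, STOP_CODONS

__all__ = [
    "ClusterSpec",
    "SimTruth",
    "CdsPopulationSpec",
    "default_cluster_specs",
    "simulate_genome",
    "plant_clusters",
    "simulate_reads",
    "simulate_cds_population",
    "simulate_domain_family",
]

_BASES = np.array(["A", "C", "G", "T"])
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class ClusterSpec:
    """Recipe for one planted small-RNA cluster."""

    class_label: str
    locus_length: int = 2000
    n_reads: int = 500
    length_distribution: dict[int, float] = field(default_factory=dict)
    first_nt_bias: dict[str, float] = field(default_factory=lambda: dict.fromkeys("ACGT", 0.25))
    strand_mix: float = 0.5  # fraction of reads on the minus strand
    mature_fraction: float = 0.8  # miRNA only: reads from the mature arm

    def __post_init__(self) -> None:
        scheme = SizeClassScheme()
        lo, hi = scheme.range_of(self.class_label)
        for length in self.length_distribution:
            if not lo <= length <= hi:
                raise ValueError(
                    f"{self.class_label} spec: length {length} outside class range {lo}-{hi}"
                )
        for dist, name in ((self.length_distribution, "length_distribution"),
                           (self.first_nt_bias, "first_nt_bias")):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        if not 0.0 <= self.strand_mix <= 1.0:
            raise ValueError("strand_mix must be in [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth: cluster loci and/or simulated CDS parameters."""

    planted_clusters: list[tuple[str, int, int, str]] = field(default_factory=list)
    omega_true: float = 1.0
    divergence_true: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega_true <= 0:
            raise ValueError("omega_true must be positive")
        if self.divergence_true < 0:
            raise ValueError("divergence_true must be non-negative")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.planted_clusters:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"planted clusters overlap on {chrom}: {e1} > {s2}")

    def bed_records(self) -> list[tuple]:
        return [(c, s, e, label) for c, s, e, label in self.planted_clusters]


@dataclass
class CdsPopulationSpec:
    """Recipe for a CDS population sample plus outgroup.

    Defaults describe a medium-sized gene sampled from a diverse insect
    population: 1000 codons, 20 haplotypes, nucleotide diversity 1% and 5%
    proposed divergence to the outgroup.
    """

    cds_length: int = 3000
    n_samples: int = 20
    theta: float = 0.01  # expected pairwise polymorphic sites per site
    divergence_true: float = 0.05  # proposed substitutions per site to outgroup
    omega_true: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cds_length % 3 != 0 or self.cds_length <= 0:
            raise ValueError("cds_length must be a positive multiple of 3")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.theta < 0 or self.divergence_true < 0:
            raise ValueError("theta and divergence_true must be non-negative")
        if self.omega_true <= 0:
            raise ValueError("omega_true must be positive")


def default_cluster_specs() -> dict[str, ClusterSpec]:
    """Study-condition spectra for the four classes.

    Lengths concentrate in the middle of each class range; piRNAs and
    miRNAs carry the 5'-U bias characteristic of those pathways, siRNAs
    and the sub-20 nt "other" fraction are unbiased.
    """
    return {
        "siRNA": ClusterSpec(
            "siRNA",
            length_distribution={20: 0.25, 21: 0.50, 22: 0.25},
        ),
        "miRNA": ClusterSpec(
            "miRNA",
            length_distribution={22: 0.50, 23: 0.35, 24: 0.15},
            first_nt_bias={"A": 0.20, "C": 0.10, "G": 0.10, "T": 0.60},
            strand_mix=0.0,
        ),
        "piRNA": ClusterSpec(
            "piRNA",
            length_distribution={24: 0.05, 25: 0.15, 26: 0.25, 27: 0.25, 28: 0.20, 29: 0.10},
            first_nt_bias={"A": 0.10, "C": 0.10, "G": 0.10, "T": 0.70},
        ),
        "other": ClusterSpec(
            "other",
            length_distribution={15: 0.20, 16: 0.25, 17: 0.25, 18: 0.20, 19: 0.10},
        ),
    }


# ---------------------------------------------------------------------------
# Genome and clusters


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random genome with i.i.d. bases at the given GC fraction."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def plant_clusters(
    genome: dict[str, str],
    specs: list[ClusterSpec],
    seed: int = 0,
    gap: int = 2000,
) -> tuple[dict[str, str], SimTruth]:
    """Choose non-overlapping loci for the specs, >= one window apart.

    The genome sequence itself is returned unchanged: the 5' bias is
    honoured later by read-start selection, so planted loci stay ordinary
    genome substrings.  Placement is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    planted: list[tuple[str, int, int, str]] = []
    remaining = list(specs)
    for chrom in chroms:
        if not remaining:
            break
        chrom_len = len(genome[chrom])
        # Fit as many specs as possible on this chromosome, in order.
        take = []
        used = gap
        for spec in remaining:
            if used + spec.locus_length + gap <= chrom_len:
                take.append(spec)
                used += spec.locus_length + gap
            else:
                break
        remaining = remaining[len(take) :]
        if not take:
            continue
        slack = chrom_len - used
        # Random non-negative extra gaps summing to <= slack.
        extras = np.floor(rng.dirichlet(np.ones(len(take) + 1)) * slack).astype(int)
        pos = gap + extras[0]
        for spec, extra in zip(take, extras[1:]):
            planted.append((chrom, int(pos), int(pos + spec.locus_length), spec.class_label))
            pos += spec.locus_length + gap + int(extra)
    if remaining:
        raise ValueError(
            f"could not place {len(remaining)} cluster(s) without overlap; "
            "use a longer genome"
        )
    return genome, SimTruth(planted_clusters=planted, seed=seed)


def _positions_by_base(seq: str, start: int, end: int) -> dict[str, np.ndarray]:
    arr = np.frombuffer(seq[start:end].encode(), dtype="S1")
    return {b: start + np.nonzero(arr == b.encode())[0] for b in "ACGT"}


def _sample_discrete(rng, dist: dict, n: int) -> list:
    keys = sorted(dist)
    p = np.array([dist[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=n, p=p)
    return [keys[i] for i in idx]


def simulate_reads(
    genome: dict[str, str],
    truth: SimTruth,
    specs: list[ClusterSpec],
    error_rate: float = 0.01,
    seed: int = 0,
    raw_prefix: int = 0,
    base_quality: int = 40,
) -> tuple[list[ReadRecord], list[AlignmentRecord], list[tuple]]:
    """Draw reads from each planted locus and record their true placements.

    Returns (reads, truth alignments, truth SAM rows).  Each read starts at
    a position inside its cluster whose base matches a draw from the spec's
    5'-nucleotide bias, with length sampled from the spec's distribution;
    with ``raw_prefix`` > 0 the FASTQ reads carry that many extra random 5'
    bases (the library-preparation artefact removed by preprocessing), while
    the truth alignments always describe the trimmed read.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    if len(truth.planted_clusters) != len(specs):
        raise ValueError("one spec per planted cluster required")
    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    alignments: list[AlignmentRecord] = []
    sam_rows: list[tuple] = []
    for (chrom, start, end, label), spec in zip(truth.planted_clusters, specs):
        if label != spec.class_label:
            raise ValueError("spec order must match planted cluster order")
        seq = genome[chrom]
        max_len = max(spec.length_distribution)
        if max_len > end - start:
            raise ValueError(f"spec length range exceeds locus length at {chrom}:{start}")
        index = _positions_by_base(seq, start, end)
        lengths = _sample_discrete(rng, spec.length_distribution, spec.n_reads)
        firsts = _sample_discrete(rng, spec.first_nt_bias, spec.n_reads)
        strands = rng.random(spec.n_reads) < spec.strand_mix
        if spec.class_label == "miRNA":
            starts_plus = _mirna_fixed_starts(rng, index, spec, start, end, max_len)
        for i in range(spec.n_reads):
            length, first = lengths[i], firsts[i]
            strand = "-" if strands[i] else "+"
            if spec.class_label == "miRNA":
                arm = 0 if rng.random() < spec.mature_fraction else 1
                pos = starts_plus[arm]
                strand = "+"
            else:
                pos = _pick_start(rng, index, first, strand, length, start, end)
            frag = seq[pos : pos + length]
            read_seq = _revcomp(frag) if strand == "-" else frag
            read_seq, n_err = _apply_errors(rng, read_seq, error_rate)
            read_id = f"read_{chrom}_{start}_{i}"
            full_seq = read_seq
            if raw_prefix > 0:
                full_seq = "".join(rng.choice(_BASES, size=raw_prefix)) + read_seq
            reads.append(
                ReadRecord(read_id, full_seq, [base_quality] * len(full_seq))
            )
            alignments.append(
                AlignmentRecord(
                    read_id=read_id,
                    reference_name=chrom,
                    start=pos,
                    strand=strand,
                    mismatches=n_err,
                    hit_count=1,
                    read_length=length,
                    first_nt=read_seq[0],
                )
            )
            sam_rows.append((read_id, chrom, pos, strand, read_seq, n_err, 1))
    return reads, alignments, sam_rows


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _apply_errors(rng, seq: str, rate: float) -> tuple[str, int]:
    if rate == 0.0:
        return seq, 0
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq, 0
    bases = list(seq)
    for i in hits:
        others = [b for b in "ACGT" if b != bases[i]]
        bases[i] = others[rng.integers(3)]
    return "".join(bases), len(hits)


def _pick_start(rng, index, first: str, strand: str, length: int, lo: int, hi: int) -> int:
    """A start position honouring the first-base draw on the given strand."""
    if strand == "+":
        cands = index[first]
        cands = cands[cands <= hi - length]
        if len(cands) == 0:  # locus lacks the base; fall back to uniform
            return int(rng.integers(lo, hi - length + 1))
        return int(cands[rng.integers(len(cands))])
    # Minus strand: the read's 5' base sits at the 3'-most genome position.
    cands = index[_COMP[first]]
    cands = cands[cands >= lo + length - 1]
    if len(cands) == 0:
        return int(rng.integers(lo, hi - length + 1))
    return int(cands[rng.integers(len(cands))] - length + 1)


def _mirna_fixed_starts(rng, index, spec: ClusterSpec, lo: int, hi: int, max_len: int):
    """Mature and star start positions with bias-conforming 5' bases."""
    starts = []
    thirds = [(lo, lo + (hi - lo) // 2 - max_len), (lo + (hi - lo) // 2, hi - max_len)]
    for arm_lo, arm_hi in thirds:
        first = _sample_discrete(rng, spec.first_nt_bias, 1)[0]
        cands = index[first]
        cands = cands[(cands >= arm_lo) & (cands <= arm_hi)]
        if len(cands) == 0:
            starts.append(int(rng.integers(arm_lo, arm_hi + 1)))
        else:
            starts.append(int(cands[rng.integers(len(cands))]))
    return starts


# ---------------------------------------------------------------------------
# CDS populations


def _random_cds(rng, n_codons: int) -> list[str]:
    codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    return list("".join(codons))


def _propose_base(rng, current: str) -> str:
    others = [b for b in "ACGT" if b != current]
    return others[rng.integers(3)]


def _mutate_sites(
    rng,
    seq: list[str],
    site_mask: np.ndarray,
    omega: float,
) -> list[int]:
    """Acceptance–rejection mutation of the flagged sites, in place.

    Synonymous proposals are always accepted, nonsynonymous ones with
    probability min(1, omega); proposals creating a stop codon are redrawn
    among the remaining alternative bases (skipped if none is stop-free).
    Returns the site indices actually changed.
    """
    changed = []
    for i in np.nonzero(site_mask)[0]:
        i = int(i)
        cstart = i - (i % 3)
        codon = "".join(seq[cstart : cstart + 3])
        offset = i % 3
        options = [b for b in "ACGT" if b != seq[i]]
        rng.shuffle(options)
        for base in options:
            candidate = codon[:offset] + base + codon[offset + 1 :]
            if candidate in STOP_CODONS:
                continue
            synonymous = CODON_TO_AA[candidate] == CODON_TO_AA[codon]
            if synonymous or rng.random() < min(1.0, omega):
                seq[i] = base
                changed.append(i)
            break  # one proposal per site; redraws only dodge stops
    return changed


def simulate_cds_population(
    spec: CdsPopulationSpec,
) -> tuple[list[str], str, str, SimTruth]:
    """Simulate (population haplotypes, outgroup, ancestor, truth).

    The outgroup branch proposes a change at each site with probability
    ``divergence_true``; the polymorphism layer makes a site segregating
    with probability theta × a_n (a_n the harmonic number of n−1, so the
    expected pairwise diversity before selection is theta), with the
    derived-allele count drawn from the neutral 1/k frequency spectrum.
    Nonsynonymous proposals survive with probability min(1, omega_true).
    """
    rng = np.random.default_rng(spec.seed)
    n_codons = spec.cds_length // 3
    ancestral = _random_cds(rng, n_codons)

    outgroup = ancestral.copy()
    mask = rng.random(spec.cds_length) < spec.divergence_true
    _mutate_sites(rng, outgroup, mask, spec.omega_true)

    a_n = sum(1.0 / k for k in range(1, spec.n_samples))
    p_seg = min(1.0, spec.theta * a_n)
    population = [ancestral.copy() for _ in range(spec.n_samples)]
    seg_sites = np.nonzero(rng.random(spec.cds_length) < p_seg)[0]
    k_weights = np.array([1.0 / k for k in range(1, spec.n_samples)])
    k_weights /= k_weights.sum()
    for i in seg_sites:
        i = int(i)
        carrier_count = int(rng.choice(np.arange(1, spec.n_samples), p=k_weights))
        carriers = rng.choice(spec.n_samples, size=carrier_count, replace=False)
        # Mutate one carrier in its own context, then copy the change.
        template = population[int(carriers[0])]
        changed = _mutate_sites(rng, template, np.eye(1, spec.cds_length, i)[0] > 0,
                                spec.omega_true)
        for c in carriers[1:]:
            for j in changed:
                population[int(c)][j] = template[j]
    population_seqs = ["".join(s) for s in population]
    _repair_stops(population_seqs, ancestral)
    out_seq = "".join(outgroup)
    truth = SimTruth(
        omega_true=spec.omega_true,
        divergence_true=spec.divergence_true,
        seed=spec.seed,
    )
    return population_seqs, out_seq, "".join(ancestral), truth


def _repair_stops(seqs: list[str], ancestral: list[str]) -> None:
    """Revert any codon that combined independent changes into a stop."""
    anc = "".join(ancestral)
    for idx, seq in enumerate(seqs):
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        for ci in range(len(codons) - 1):  # terminal codon may be a stop
            if codons[ci] in STOP_CODONS:
                codons[ci] = anc[ci * 3 : ci * 3 + 3]
        seqs[idx] = "".join(codons)


# ---------------------------------------------------------------------------
# Protein-domain families


def simulate_domain_family(
    n_per_group: int = 2,
    n_groups: int = 2,
    length: int = 70,
    within_divergence: float = 0.1,
    between_divergence: float = 0.5,
    seed: int = 0,
) -> dict[str, str]:
    """Protein domains in ``n_groups`` subfamilies of ``n_per_group``.

    Group ancestors diverge from a common root at ``between_divergence``
    substitutions per residue; members diverge from their group ancestor at
    ``within_divergence``.  Group structure is recoverable from the
    identity matrix.
    """
    rng = np.random.default_rng(seed)
    root = rng.choice(_AA20, size=length)

    def mutate(parent: np.ndarray, rate: float) -> np.ndarray:
        child = parent.copy()
        hits = np.nonzero(rng.random(length) < rate)[0]
        for i in hits:
            choices = _AA20[_AA20 != child[i]]
            child[i] = choices[rng.integers(len(choices))]
        return child

    family: dict[str, str] = {}
    for g in range(n_groups):
        ancestor = mutate(root, between_divergence)
        for m in range(n_per_group):
            name = f"dom{chr(ord('A') + g)}{m + 1}"
            family[name] = "".join(mutate(ancestor, within_divergence))
    return family
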