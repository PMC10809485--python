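"""Ka/Ks estimation (Nei–Gojobori 1986) and the McDonald–Kreitman test.

The NG86 estimator counts synonymous (S) and nonsynonymous (N) *sites* by
enumerating the nine single-nucleotide neighbours of each codon, and
synonymous/nonsynonymous *differences* (Sd, Nd) with pathway averaging:
codons differing at k > 1 positions contribute the mean over all k!
orderings of the single changes, excluding orderings that pass through a
stop codon.  Proportions pN = Nd/N and pS = Sd/S are corrected for
multiple hits with the Jukes–Cantor formula d = -(3/4)·ln(1 - (4/3)p),
giving Ka, Ks and omega = Ka/Ks.

The McDonald–Kreitman test contrasts within-population polymorphism with
divergence to an outgroup at synonymous versus nonsynonymous positions in
a 2x2 table [[Dn, Ds], [Pn, Ps]], tested with Fisher's exact test.  The
neutrality index NI = (Pn/Ps)/(Dn/Ds) and alpha = 1 - NI summarise the
departure from neutrality (alpha > 0: excess of adaptive fixations).

Mutations to stop codons count as nonsynonymous; internal stop codons in
input sequences are invalid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy.stats import hypergeom

from .io import VariantRecord

__all__ = [
    "CODON_TO_AA",
    "STOP_CODONS",
    "SENSE_CODONS",
    "CodonAlignment",
    "SiteCounts",
    "KaKsResult",
    "MktResult",
    "CorrectionDomainError",
    "apply_snps",
    "ng86_sites",
    "pathway_differences",
    "ng86_pairwise",
    "classify_changes",
    "fisher_exact_2x2",
    "mkt",
    "majority_consensus",
    "mkt_from_alignment",
]

_TABLE = unambiguous_dna_by_id[1]  # the standard genetic code
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
_BASES = ("A", "C", "G", "T")

_IUPAC_HET = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("AC"): "M",
    frozenset("GT"): "K", frozenset("CG"): "S", frozenset("AT"): "W",
}


class CorrectionDomainError(ValueError):
    """A raw proportion >= 3/4, outside the Jukes–Cantor domain."""


def _check_cds(seq: str, name: str = "sequence") -> None:
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: length {len(seq)} not a multiple of 3")
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon at position {i}")


@dataclass
class CodonAlignment:
    """An in-frame population sample plus one outgroup sequence."""

    population: list[str]
    outgroup: str

    def __post_init__(self) -> None:
        if len(self.population) < 1:
            raise ValueError("population must contain at least one sequence")
        length = len(self.outgroup)
        if any(len(s) != length for s in self.population):
            raise ValueError("population and outgroup sequences must have equal length")
        _check_cds(self.outgroup, "outgroup")
        for i, seq in enumerate(self.population):
            _check_cds(seq, f"population[{i}]")


@dataclass
class SiteCounts:
    N: float  # nonsynonymous sites
    S: float  # synonymous sites
    Nd: float  # nonsynonymous differences (pathway-averaged)
    Sd: float  # synonymous differences


@dataclass
class KaKsResult:
    pN: float
    pS: float
    Ka: float
    Ks: float
    omega: float | None  # None when Ks == 0
    flags: list[str] = field(default_factory=list)


@dataclass
class MktResult:
    Pn: float
    Ps: float
    Dn: float
    Ds: float
    p_value: float
    NI: float | None
    alpha: float | None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# SNP -> sequence


def apply_snps(
    reference: str,
    variants: list[VariantRecord],
    sample: str,
    haplotype_rule: str = "split",
    cds_start: int = 0,
) -> tuple[list[str], dict[str, int]]:
    """Substitute one sample's biallelic SNPs into a reference CDS.

    ``split`` (default) emits two haplotype sequences per sample, so that
    heterozygous alleles keep their counts for polymorphism classification;
    ``consensus`` emits one sequence with IUPAC codes at heterozygous
    positions.  Indel and multi-allelic records are skipped and tallied.
    """
    if haplotype_rule not in ("split", "consensus"):
        raise ValueError(f"unknown haplotype_rule {haplotype_rule!r}")
    tally = {"applied": 0, "indel": 0, "multiallelic": 0, "missing_gt": 0}
    haplotypes = [list(reference), list(reference)]
    for var in variants:
        if var.is_indel:
            tally["indel"] += 1
            continue
        if var.is_multiallelic:
            tally["multiallelic"] += 1
            continue
        pos = var.pos - cds_start
        if not 0 <= pos < len(reference):
            raise ValueError(f"variant at {var.chrom}:{var.pos} outside the CDS")
        if reference[pos] != var.ref:
            raise ValueError(
                f"variant at {var.chrom}:{var.pos}: REF {var.ref!r} disagrees with "
                f"reference base {reference[pos]!r}"
            )
        gt = var.genotypes.get(sample)
        if gt is None or any(a is None for a in gt):
            tally["missing_gt"] += 1
            continue
        alleles = (var.ref, var.alts[0])
        for h, allele_idx in zip(haplotypes, gt):
            h[pos] = alleles[allele_idx]
        tally["applied"] += 1
    if haplotype_rule == "split":
        return ["".join(h) for h in haplotypes], tally
    merged = []
    for a, b in zip(*haplotypes):
        merged.append(a if a == b else _IUPAC_HET[frozenset((a, b))])
    return ["".join(merged)], tally


# ---------------------------------------------------------------------------
# NG86


def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each of the nine single-nucleotide neighbours contributes 1/3 of a site
    to S if it encodes the same amino acid, otherwise to N; changes to stop
    codons are nonsynonymous.  S + N == 3 exactly.
    """
    if codon not in CODON_TO_AA:
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            if neighbour not in STOP_CODONS and CODON_TO_AA[neighbour] == aa:
                syn += 1
    s_sites = syn / 3.0
    return s_sites, 3.0 - s_sites


def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """Pathway-averaged (Nd, Sd, blocked) between two sense codons.

    Averages over all orderings of the differing positions, skipping
    orderings whose intermediate codons are stops.  When every ordering is
    blocked by stops, differences are split evenly and ``blocked`` is True.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff)
    if k == 0:
        return 0.0, 0.0, False
    nd_total = sd_total = 0.0
    n_paths = 0
    for order in permutations(diff):
        current = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                blocked = True
                break
            steps.append((current, nxt))
            current = nxt
        if blocked or current in STOP_CODONS:
            continue
        n_paths += 1
        for frm, to in steps:
            if CODON_TO_AA[frm] == CODON_TO_AA[to]:
                sd_total += 1
            else:
                nd_total += 1
    if n_paths == 0:
        return k / 2.0, k / 2.0, True
    return nd_total / n_paths, sd_total / n_paths, False


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4)·ln(1 - (4/3)·p)."""
    if p >= 0.75:
        raise CorrectionDomainError(f"proportion {p} >= 3/4: Jukes–Cantor undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pairwise(seq_a: str, seq_b: str) -> tuple[SiteCounts, KaKsResult]:
    """NG86 Ka, Ks and omega between two in-frame CDS of equal length."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    _check_cds(seq_a, "seq_a")
    _check_cds(seq_b, "seq_b")
    n_sites = s_sites = nd = sd = 0.0
    flags: list[str] = []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        nd_c, sd_c, blocked = pathway_differences(ca, cb)
        nd += nd_c
        sd += sd_c
        if blocked:
            flags.append(f"codon {i // 3}: all pathways through stops, split evenly")
    p_n = nd / n_sites if n_sites > 0 else 0.0
    p_s = sd / s_sites if s_sites > 0 else 0.0
    ka = jukes_cantor(p_n)
    ks = jukes_cantor(p_s)
    omega = (ka / ks) if ks > 0 else None
    return (
        SiteCounts(N=n_sites, S=s_sites, Nd=nd, Sd=sd),
        KaKsResult(pN=p_n, pS=p_s, Ka=ka, Ks=ks, omega=omega, flags=flags),
    )


# ---------------------------------------------------------------------------
# Polymorphism vs divergence


def majority_consensus(population: list[str]) -> str:
    """Per-site majority base; ties broken alphabetically (deterministic)."""
    out = []
    for column in zip(*population):
        counts: dict[str, int] = {}
        for base in column:
            counts[base] = counts.get(base, 0) + 1
        out.append(max(sorted(counts), key=counts.get))
    return "".join(out)


def classify_changes(alignment: CodonAlignment) -> tuple[float, float, float, float, dict]:
    """Count polymorphic and divergent changes, split by synonymous effect.

    Per nucleotide site: if more than one allele segregates in the
    population the site is polymorphic; if the population is monomorphic
    and differs from the outgroup it is divergent.  The synonymous /
    nonsynonymous call substitutes the alternate base into the codon formed
    by the population-majority bases at the other two positions.  Sites
    with >2 population alleles, or any N, are skipped and tallied.
    """
    pn = ps = dn = ds = 0.0
    tally = {
        "multiallelic": 0,
        "ambiguous": 0,
        "stop_context": 0,
        "derived_polarized": 0,
    }
    population, outgroup = alignment.population, alignment.outgroup
    consensus = majority_consensus(population)
    for i in range(len(outgroup)):
        column = {seq[i] for seq in population}
        if "N" in column or outgroup[i] == "N":
            tally["ambiguous"] += 1
            continue
        if len(column) > 2:
            tally["multiallelic"] += 1
            continue
        codon_start = i - (i % 3)
        context = list(consensus[codon_start : codon_start + 3])
        offset = i % 3

        def codon_with(base: str) -> str:
            c = context.copy()
            c[offset] = base
            return "".join(c)

        if len(column) == 2:  # polymorphic
            b1, b2 = sorted(column)
            c1, c2 = codon_with(b1), codon_with(b2)
            if c1 in STOP_CODONS and c2 in STOP_CODONS:
                tally["stop_context"] += 1
                continue
            synonymous = (
                c1 not in STOP_CODONS
                and c2 not in STOP_CODONS
                and CODON_TO_AA[c1] == CODON_TO_AA[c2]
            )
            if synonymous:
                ps += 1
            else:
                pn += 1
            # Outgroup-based polarization is an annotation only; it does not
            # change the standard MKT counts.
            if outgroup[i] in column:
                tally["derived_polarized"] += 1
        else:
            (pop_base,) = column
            if pop_base == outgroup[i]:
                continue
            c_pop, c_out = codon_with(pop_base), codon_with(outgroup[i])
            if c_pop in STOP_CODONS and c_out in STOP_CODONS:
                tally["stop_context"] += 1
                continue
            synonymous = (
                c_pop not in STOP_CODONS
                and c_out not in STOP_CODONS
                and CODON_TO_AA[c_pop] == CODON_TO_AA[c_out]
            )
            if synonymous:
                ds += 1
            else:
                dn += 1
    return pn, ps, dn, ds, tally


# ---------------------------------------------------------------------------
# Fisher's exact test and the MKT


def fisher_exact_2x2(table: list[list[int]]) -> tuple[float, list[str]]:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers.

    p is the sum of hypergeometric probabilities, over all tables with the
    observed margins, of tables no more probable than the observed one
    (relative tie tolerance 1e-12).  Degenerate tables with a zero margin
    give p = 1 by convention and are flagged.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0, ["degenerate-margin"]
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = range(lo, hi + 1)
    pmf = hypergeom.pmf(list(support), n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0), []


def mkt(pn: float, ps: float, dn: float, ds: float) -> MktResult:
    """McDonald–Kreitman test from polymorphism/divergence counts."""
    for x in (pn, ps, dn, ds):
        if x < 0:
            raise ValueError("counts must be non-negative")
    p_value, flags = fisher_exact_2x2([[round(dn), round(ds)], [round(pn), round(ps)]])
    ni: float | None = None
    alpha: float | None = None
    if ps > 0 and dn > 0:
        if ds > 0:
            ni = (pn / ps) / (dn / ds)
        else:
            ni = 0.0  # Dn/Ds diverges; the neutrality index tends to 0
            flags = flags + ["ds-zero"]
        alpha = 1.0 - ni
    else:
        flags = flags + ["ni-undefined"]
    return MktResult(Pn=pn, Ps=ps, Dn=dn, Ds=ds, p_value=p_value, NI=ni, alpha=alpha, flags=flags)


def mkt_from_alignment(alignment: CodonAlignment) -> tuple[MktResult, KaKsResult, dict]:
    """Full per-gene selection summary: MKT counts plus NG86 Ka/Ks of the
    population majority consensus against the outgroup."""
    pn, ps, dn, ds, tally = classify_changes(alignment)
    result = mkt(pn, ps, dn, ds)
    representative = majority_consensus(alignment.population)
    try:
        _check_cds(representative, "consensus")
    except ValueError:
        # alleles from different haplotypes can combine into a stop codon in
        # the consensus; fall back to the first haplotype
        representative = alignment.population[0]
    _, kaks = ng86_pairwise(representative, alignment.outgroup)
    return result, kaks, tally
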