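# Methods

This note documents the models and procedures implemented in `srnaevol`,
the defaults they ship with and why, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Small-RNA cluster calling

The genome is tiled into disjoint fixed-width windows (default 2000 nt;
the final window of a chromosome may be shorter). Each alignment is
assigned to the window containing its *start* position — reads are ≤ 35 nt
against 2 kb windows, so fractional-overlap assignment would change at
most ~35 bp of edge attribution and is not worth the complexity. Strands
are pooled for counting; strand is retained on the alignment records for
diagnostics.

Windows are typed from per-length read counts via the size-class scheme
siRNA = 20–22 nt, miRNA = 22–24 nt, piRNA = 24–29 nt, other = 15–19 nt.
These ranges deliberately overlap at 22 nt and 24 nt. A read is counted
in *every* class whose range contains its length; the window label is the
argmax of the class counts, with exact ties broken by the fixed priority
piRNA > siRNA > miRNA > other. Double counting plus deterministic
tie-breaking is the least-surprising reading of overlapping published
ranges; the alternative (priority or exclusive binning) would silently
reallocate boundary lengths. A window needs at least `min_reads = 10`
reads to be classified at all — a guard against one-read "clusters"; the
threshold is exposed as a flag.

Multi-mapped reads contribute one count per reported placement in the
default `full` mode, mirroring an aligner configured to report up to ~10
placements during permissive cluster discovery; `fractional` mode
(1/hit_count per placement) is available where conservation of read totals
matters more than sensitivity.

Maximal runs of adjacent same-class windows merge into a cluster named
`<genome_tag>_<chrom>_<start-of-first-window>` (0-based). Merging is on by
default because biological siRNA/piRNA clusters routinely exceed 2 kb;
`merge_adjacent=False` keeps one cluster per window.

Re-quantification extracts the cluster sequences as a reference, keeps
alignments with ≤ 1 mismatch, and scales counts by 10⁶ / total mapped
reads of *that mapping round* (RPM is round-relative in a sequential
mapping design). The reporting filter drops clusters whose total RPM is
not strictly greater than 50; it affects the report only, never internal
state.

## Read preprocessing and profiles

Raw reads lose a fixed 5′ prefix (default 6 nt, the ligated spacer of the
library protocol), then are dropped if mean Phred < 20, if any N remains,
or if shorter than 15 nt. "Low quality" is read as *mean* read quality —
the common adapter-trimmer semantic — with a per-base-minimum mode behind
a flag. Preprocessing is idempotent: a second pass with `trim5=0` changes
nothing.

Genome-wide abundance profiles are (length × first 5′ base) matrices over
18–35 nt (18–26 nt in miRNA mode) restricted to unique mappers
(`hit_count == 1`) with ≤ 1 mismatch. First bases are held as T
internally and displayed as U, per small-RNA convention.

Sequential assignment walks an ordered hierarchy of single-feature
references. At each round, reads unique in that round's reference (one
reported placement, mismatches within bound) are assigned and removed;
everything else — multimappers and non-mappers — continues. The result is
a partition: every read ends with exactly one feature label or
`unassigned`. The hierarchy order is a scientific choice with real effect
on reads unique in more than one reference, so it is config-supplied and
recorded in the run manifest rather than hard-coded.

## Selection analysis

**Sequence construction.** Biallelic SNPs are substituted into the
reference CDS per sample; heterozygotes default to *two haplotype
sequences per sample* (rule `split`) because collapsing to IUPAC consensus
destroys the allele counts that polymorphism classification needs;
`consensus` is available for compatibility with consensus-FASTA workflows.
Indel and multi-allelic records are skipped and tallied, and a REF base
that disagrees with the supplied reference is an error, not a warning.

**NG86.** Synonymous site counts per codon are the classic fraction of the
nine single-nucleotide neighbours that preserve the amino acid (mutations
to stops count as nonsynonymous), so S + N = 3 per codon exactly; per
pair, sites are averaged over the two sequences. Codons differing at k > 1
positions contribute pathway-averaged difference counts over all k!
orderings, excluding orderings that pass through a stop codon; if *every*
ordering is blocked, the differences are split evenly between Sd and Nd
and the codon is flagged rather than silently guessed. Proportions are
corrected with Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)·p); p ≥ 3/4 raises a
domain error reporting the raw proportion. NG86 with JC correction was
chosen as the estimator because it is the canonical approximate method and
is fully specified — every piece is testable against exhaustive
enumeration, which the suite does for all 61 sense codons and all codon
pairs differing at ≤ 2 positions.

**MKT.** Per nucleotide site: a site with two segregating population
alleles is polymorphic (even if the outgroup also differs — a segregating
site is not a fixed difference); a monomorphic site differing from the
outgroup is divergent. The synonymous/nonsynonymous call substitutes the
alternate base into the codon formed by the population-majority bases at
the other two codon positions — deterministic, and robust to rare
double-segregating codons. Sites with > 2 alleles or any N are skipped and
tallied. Fisher's two-sided exact p on [[Dn, Ds], [Pn, Ps]] is computed by
direct enumeration over the free cell of the hypergeometric support
(tables no more probable than the observed one, relative tie tolerance
1e-12); a zero margin gives p = 1 by convention, flagged. NI and α are
reported when Ps > 0 and Dn > 0; Ds = 0 with Dn > 0 yields NI = 0 (the
limit), flagged. Outgroup-based derived-allele polarization is computed
but reported only as an annotation — standard MKT counts are
polarity-free.

The headline Ka/Ks accompanying an MKT table is the NG86 estimate between
the population majority consensus and the outgroup (falling back to the
first haplotype in the rare case the consensus combines alleles into a
stop codon).

## Domain comparison

Global Needleman–Wunsch under BLOSUM62 with affine penalties: gap open 10,
gap extend 0.5, an internal gap of length L costing open + extend·L, and
end gaps free — the default contract of the EMBOSS Needle tool this stage
reproduces. Identity % and gap % are computed from the single reported
optimal alignment (traceback is deterministic); alignment % is defined as
100 − gap %. The dynamic programming is delegated to Biopython's
PairwiseAligner; the test suite checks its scores against an independent
exhaustive enumeration of all global alignments on short sequences.

The dendrogram is agglomerative clustering (default average linkage, a
flag otherwise) of the distance matrix 100 − identity. Items are
pre-sorted lexicographically by label so ties merge in label order and the
output is invariant to input order; branch lengths follow the ultrametric
convention (leaf at height 0, edge = half the merge-height difference, so
two items at distance d form a cherry with branches d/2). Merge heights
are checked to be non-decreasing.

## The synthetic-data generator

**What it emulates.** Planted small-RNA clusters with class-specific
length spectra, 5′-nucleotide bias and strand mix; a truth SAM that plays
the role of the alignment step (each read placed at its generating locus,
`NH:i:1`), and a truth BED of loci. Defaults, chosen once as the study
conditions: 2000 nt loci, 500 reads per cluster, substitution error rate
0.01; siRNAs 20–22 nt with no 5′ bias and mixed strands, miRNAs 22–24 nt
with 5′-U bias 0.6 emitted from two fixed start positions per locus
(an 80/20 mature/star pile-up, mimicking miRNA read stacking without a
hairpin model), piRNAs 24–29 nt with the characteristic 5′-U bias (0.7),
"other" 15–19 nt unbiased.

The 5′ bias is honoured by *start-position selection*: the first base is
drawn from the bias and the read start is sampled among locus positions
carrying that base (on the minus strand, positions whose complement
matches). This keeps every read an exact genome substring at error rate
0 while the observed first-base distribution follows the bias — resampling
the base itself would have broken genome consistency.

CDS populations: a random stop-free ancestor; an outgroup branch proposing
a substitution per site with probability `divergence_true`; a polymorphism
layer making each site segregating with probability θ·a_n (a_n the
harmonic number of n − 1), with derived-allele counts from the neutral 1/k
spectrum, so expected pairwise diversity before selection equals θ
(default 0.01, a realistic insect-population value; defaults 3000 nt, 20
haplotypes, 5% divergence). Selection is acceptance–rejection: synonymous
proposals always accepted, nonsynonymous with probability min(1, ω);
proposals creating stops are redrawn among the remaining bases. This makes
ω a *transparent* acceptance ratio rather than a rate-matrix parameter —
sufficient for recovery testing, and the recovered NG86 Ka/Ks carries a
small downward bias (order 10%) because NG86 counts stop-neighbours as
mutable nonsynonymous sites that the simulator never uses.

**What it does not emulate — hence what passing tests do not show.** No
coalescent genealogy or linkage (sites are independent), no recombination,
no indels, no quality-score structure (flat Phred 40, so the quality
filter passes everything simulated), no multimapping reads (truth
alignments are unique by construction; multimapper handling is exercised
by constructed fixtures instead), no hairpin structure for miRNAs, no
ping-pong piRNA signature. Recovery rates measured here bound the
method's behaviour under its own assumptions, not under real library
artefacts.

## Pipeline and reproducibility

Stages run in dependency order in a run directory; the manifest records
the resolved config and a sha256 checksum per output. Floats in tables are
written with 6-significant-digit formatting so byte-identity of reruns is
meaningful, and the suite asserts it. One global seed derives per-stage
seeds via `SeedSequence([seed, stage_id])` — a single knob, independent
streams. Validation problem sizes (50 planted clusters × 200 reads; 500
neutral MKT simulations of 3000 nt × 20 haplotypes; 20 replicates per ω;
100 alignment-enumeration trials at length ≤ 8) were chosen so the whole
validation completes in well under a minute while keeping binomial
uncertainty on the measured rates small relative to their acceptance
bands.

## Known limitations

* The original cluster-calling script's handling of the 22/24 nt bin
  overlaps and of window merging is not published; the choices here
  (double counting + tie order; merge adjacent) are defensible readings,
  exposed as flags.
* The exact feature order of the original sequential remapping is
  unpublished; results that depend on it cannot be reproduced bit-exactly,
  which is why the order is explicit config.
* NG86 underestimates under strong rate heterogeneity; no codon-model
  (ML) estimator is provided, deliberately.
* `classify_changes` uses the population-majority context codon; under
  extreme codon-level polymorphism this approximation can misclassify
  individual sites (skipped-site tallies make the exposure visible).
* BAM input is supported via pysam but all shipped fixtures are SAM text.
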