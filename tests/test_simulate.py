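from __future__ import annotations

import numpy as np
import pytest

from srnaevol import simulate as sim
from srnaevol.clusters import SizeClassScheme
from srnaevol.mkt import STOP_CODONS

from oracles import GENETIC_CODE


# ---------------------------------------------------------------------------
# genome


def test_genome_deterministic_for_fixed_seed():
    assert sim.simulate_genome(100, 0.5, seed=1) == sim.simulate_genome(100, 0.5, seed=1)


def test_genome_zero_length_rejected():
    with pytest.raises(ValueError):
        sim.simulate_genome(0, 0.5, seed=1)


def test_genome_extreme_gc_observed():
    # Binomial(1e5, 0.99): 0.98 is ~32 sd below the mean, so the observed
    # GC fraction lies in [0.98, 1.0] with overwhelming probability.
    g = sim.simulate_genome(100_000, 0.99, seed=2)
    gc = (g.count("G") + g.count("C")) / len(g)
    assert 0.98 <= gc <= 1.0


# ---------------------------------------------------------------------------
# planting


def test_single_cluster_planted_with_requested_length():
    genome = {"chr1": sim.simulate_genome(10_000, 0.5, seed=3)}
    spec = sim.default_cluster_specs()["piRNA"]
    _, truth = sim.plant_clusters(genome, [spec], seed=4)
    ((chrom, start, end, label),) = truth.planted_clusters
    assert end - start == 2000
    assert label == "piRNA"


def test_overfull_genome_rejected():
    genome = {"chr1": sim.simulate_genome(5000, 0.5, seed=3)}
    specs = [sim.default_cluster_specs()["piRNA"] for _ in range(5)]
    with pytest.raises(ValueError, match="longer genome"):
        sim.plant_clusters(genome, specs, seed=4)


def test_planting_deterministic_for_fixed_seed():
    specs = [sim.default_cluster_specs()["siRNA"] for _ in range(50)]
    genome = {"chr1": sim.simulate_genome(260_000, 0.5, seed=5)}
    _, t1 = sim.plant_clusters(genome, specs, seed=6)
    _, t2 = sim.plant_clusters(genome, specs, seed=6)
    assert t1.planted_clusters == t2.planted_clusters


def test_planted_clusters_leave_window_gaps():
    specs = [sim.default_cluster_specs()["siRNA"] for _ in range(10)]
    genome = {"chr1": sim.simulate_genome(80_000, 0.5, seed=5)}
    _, truth = sim.plant_clusters(genome, specs, seed=6, gap=2000)
    ivs = sorted((s, e) for _, s, e, _ in truth.planted_clusters)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        assert s2 - e1 >= 2000


# ---------------------------------------------------------------------------
# reads


def test_pirna_reads_have_class_lengths(small_simulation):
    truth = small_simulation["truth"]
    lo, hi = SizeClassScheme().range_of("piRNA")
    pirna_loci = {
        (c, s, e) for c, s, e, label in truth.planted_clusters if label == "piRNA"
    }
    pirna_reads = [
        a for a in small_simulation["alignments"]
        if any(s <= a.start and a.end <= e for _, s, e in pirna_loci)
    ]
    assert pirna_reads
    assert all(lo <= a.read_length <= hi for a in pirna_reads)


def test_error_free_reads_substring_match_genome(small_simulation):
    genome = small_simulation["genome"]
    comp = str.maketrans("ACGT", "TGCA")
    for read_id, chrom, pos, strand, seq, nm, nh in small_simulation["sam_rows"]:
        assert nm == 0
        fragment = genome[chrom][pos : pos + len(seq)]
        expected = fragment if strand == "+" else seq  # check both directions
        if strand == "-":
            fragment = fragment.translate(comp)[::-1]
        assert seq == fragment


def test_first_nt_bias_honoured():
    # 0.7 T bias, n = 10 000: binomial 99.9% interval is far inside
    # [0.67, 0.73].
    genome = {"chr1": sim.simulate_genome(12_000, 0.5, seed=11)}
    spec = sim.ClusterSpec(
        "piRNA",
        locus_length=2000,
        n_reads=10_000,
        length_distribution={26: 1.0},
        first_nt_bias={"A": 0.1, "C": 0.1, "G": 0.1, "T": 0.7},
    )
    genome, truth = sim.plant_clusters(genome, [spec], seed=12)
    reads, alignments, _ = sim.simulate_reads(genome, truth, [spec], error_rate=0.0, seed=13)
    t_frac = sum(1 for a in alignments if a.first_nt == "T") / len(alignments)
    assert 0.67 <= t_frac <= 0.73


def test_reads_deterministic_for_fixed_seed(small_simulation):
    genome = small_simulation["genome"]
    truth = small_simulation["truth"]
    specs = small_simulation["specs"]
    reads2, _, _ = sim.simulate_reads(genome, truth, specs, error_rate=0.0, seed=9)
    assert [(r.read_id, r.sequence) for r in small_simulation["reads"]] == [
        (r.read_id, r.sequence) for r in reads2
    ]


def test_truth_reads_lie_inside_truth_intervals(small_simulation):
    intervals = [(c, s, e) for c, s, e, _ in small_simulation["truth"].planted_clusters]
    for a in small_simulation["alignments"]:
        assert any(
            c == a.reference_name and s <= a.start and a.end <= e
            for c, s, e in intervals
        )


def test_default_specs_have_modal_length_inside_class_range():
    scheme = SizeClassScheme()
    for label, spec in sim.default_cluster_specs().items():
        lo, hi = scheme.range_of(label)
        mode = max(spec.length_distribution, key=spec.length_distribution.get)
        assert lo <= mode <= hi


def test_spec_with_out_of_range_length_rejected():
    with pytest.raises(ValueError, match="outside"):
        sim.ClusterSpec("siRNA", length_distribution={25: 1.0})


def test_error_rate_adds_mismatches():
    genome = {"chr1": sim.simulate_genome(12_000, 0.5, seed=21)}
    spec = sim.default_cluster_specs()["siRNA"]
    spec.n_reads = 2000
    genome, truth = sim.plant_clusters(genome, [spec], seed=22)
    _, alignments, _ = sim.simulate_reads(genome, truth, [spec], error_rate=0.02, seed=23)
    mismatch_rate = sum(a.mismatches for a in alignments) / sum(
        a.read_length for a in alignments
    )
    assert 0.01 < mismatch_rate < 0.03


# ---------------------------------------------------------------------------
# CDS populations


def test_neutral_nonsyn_syn_ratio_matches_code_table_expectation():
    """At omega=1, the accepted nonsynonymous:synonymous change ratio on the
    outgroup branch approaches the neutral expectation from brute-force
    enumeration of all single-base changes over all sense codons."""
    syn = nonsyn = 0
    for codon, aa in GENETIC_CODE.items():
        if aa == "*":
            continue
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                neighbour = codon[:pos] + base + codon[pos + 1 :]
                if GENETIC_CODE[neighbour] == "*":
                    continue  # the simulator redraws stop proposals
                if GENETIC_CODE[neighbour] == aa:
                    syn += 1
                else:
                    nonsyn += 1
    expected_ratio = nonsyn / syn
    spec = sim.CdsPopulationSpec(
        cds_length=60_000, n_samples=2, theta=0.0, divergence_true=0.05,
        omega_true=1.0, seed=31,
    )
    population, outgroup, ancestral, _ = sim.simulate_cds_population(spec)
    obs_syn = obs_nonsyn = 0
    for i in range(0, len(ancestral), 3):
        ca, cb = ancestral[i : i + 3], outgroup[i : i + 3]
        if ca == cb:
            continue
        # count one accepted change per changed position
        for pos in range(3):
            if ca[pos] != cb[pos]:
                mutated = ca[:pos] + cb[pos] + ca[pos + 1 :]
                if GENETIC_CODE.get(mutated, "*") == GENETIC_CODE[ca]:
                    obs_syn += 1
                else:
                    obs_nonsyn += 1
    observed_ratio = obs_nonsyn / obs_syn
    assert observed_ratio == pytest.approx(expected_ratio, rel=0.15)


def test_zero_divergence_gives_identical_outgroup():
    spec = sim.CdsPopulationSpec(cds_length=300, divergence_true=0.0, seed=32)
    _, outgroup, ancestral, _ = sim.simulate_cds_population(spec)
    assert outgroup == ancestral


def test_cds_population_deterministic():
    spec = sim.CdsPopulationSpec(seed=33)
    a = sim.simulate_cds_population(spec)
    b = sim.simulate_cds_population(spec)
    assert a[0] == b[0] and a[1] == b[1]


def test_no_internal_stops_in_any_simulated_sequence():
    spec = sim.CdsPopulationSpec(cds_length=3000, theta=0.02, seed=34)
    population, outgroup, ancestral, _ = sim.simulate_cds_population(spec)
    for seq in population + [outgroup, ancestral]:
        for i in range(0, len(seq) - 3, 3):
            assert seq[i : i + 3] not in STOP_CODONS


def test_pairwise_diversity_tracks_theta():
    spec = sim.CdsPopulationSpec(
        cds_length=30_000, n_samples=10, theta=0.01, divergence_true=0.0,
        omega_true=1.0, seed=35,
    )
    population, _, _, _ = sim.simulate_cds_population(spec)
    diffs = []
    for i in range(len(population)):
        for j in range(i + 1, len(population)):
            d = sum(a != b for a, b in zip(population[i], population[j]))
            diffs.append(d / spec.cds_length)
    assert np.mean(diffs) == pytest.approx(0.01, rel=0.25)


# ---------------------------------------------------------------------------
# domain families


def test_domain_family_groups_are_closer_within_than_between():
    family = sim.simulate_domain_family(seed=41)
    assert sorted(family) == ["domA1", "domA2", "domB1", "domB2"]

    def ident(a, b):
        return sum(x == y for x, y in zip(a, b)) / len(a)

    within = ident(family["domA1"], family["domA2"])
    between = ident(family["domA1"], family["domB1"])
    assert within > between
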