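"""End-to-end orchestration: simulate → clusters → profile → mkt → domains.

A run directory holds one subdirectory per stage plus a JSON manifest with
the resolved configuration and a sha256 checksum of every output.  All
floating-point table cells are written with 6-significant-digit formatting
so that byte-identity of reruns is meaningful.  One global seed derives
per-stage seeds through a fixed scheme (``SeedSequence([seed, stage])``),
giving independent streams from a single knob.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusters as cl
from . import domains as dom
from . import io
from . import mkt as mk
from . import profiles as pr
from . import simulate as sim

__all__ = ["DEFAULT_CONFIG", "load_config", "derive_seed", "run_pipeline",
           "run_simulate", "run_clusters", "run_profile", "run_mkt", "run_domains"]

FLOAT_FMT = "%.6g"

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "genome_tag": "simg1",
    "simulate": {
        "genome_length": 60000,
        "gc": 0.5,
        "clusters_per_class": 3,
        "reads_per_cluster": 500,
        "error_rate": 0.01,
        "raw_prefix": 6,
        "cds_length": 3000,
        "n_samples": 20,
        "theta": 0.01,
        "divergence": 0.05,
        "omega": 0.5,
        "domain_groups": 2,
        "domains_per_group": 2,
        "domain_length": 70,
    },
    "clusters": {
        "window_size": 2000,
        "min_reads": 10,
        "count_mode": "full",
        "merge_adjacent": True,
        "max_mismatch": 1,
        "min_rpm": 50.0,
    },
    "profile": {
        "trim5": 6,
        "min_len": 15,
        "min_mean_q": 20,
        "max_mismatch": 1,
        "length_min": 18,
        "length_max": 35,
        "hierarchy": ["miRNA", "siRNA", "piRNA", "other"],
    },
    "mkt": {"haplotype_rule": "split"},
    "domains": {
        "matrix": "BLOSUM62",
        "gap_open": 10.0,
        "gap_extend": 0.5,
        "linkage": "average",
    },
}

_STAGE_IDS = {"simulate": 1, "clusters": 2, "profile": 3, "mkt": 4, "domains": 5}


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed from the global one: SeedSequence([seed, stage id])."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in base:
            raise ValueError(f"unknown config field {path + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config field {path + key!r} must be a mapping")
            out[key] = _merge(base[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Resolve a run config: defaults, then YAML file, then overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stages


def run_simulate(cfg: dict, outdir: Path) -> dict:
    log = io.get_logger("simulate")
    p = cfg["simulate"]
    seed = derive_seed(cfg["seed"], "simulate")
    d = outdir / "simulate"
    d.mkdir(parents=True, exist_ok=True)

    genome = {"chr1": sim.simulate_genome(p["genome_length"], p["gc"], seed)}
    base_specs = sim.default_cluster_specs()
    specs = []
    for i in range(p["clusters_per_class"] * 4):
        spec = copy.deepcopy(list(base_specs.values())[i % 4])
        spec.n_reads = p["reads_per_cluster"]
        specs.append(spec)
    genome, truth = sim.plant_clusters(genome, specs, seed=seed + 1)
    reads, alignments, sam_rows = sim.simulate_reads(
        genome, truth, specs, error_rate=p["error_rate"], seed=seed + 2,
        raw_prefix=p["raw_prefix"],
    )
    io.write_fasta(genome, d / "genome.fasta")
    io.write_bed(truth.bed_records(), d / "truth.bed")
    io.write_fastq(reads, d / "reads.fastq")
    io.write_sam(sam_rows, {c: len(s) for c, s in genome.items()}, d / "truth.sam")

    cds_spec = sim.CdsPopulationSpec(
        cds_length=p["cds_length"], n_samples=p["n_samples"], theta=p["theta"],
        divergence_true=p["divergence"], omega_true=p["omega"], seed=seed + 3,
    )
    population, outgroup, ancestral, _ = sim.simulate_cds_population(cds_spec)
    io.write_fasta({f"hap{i:02d}": s for i, s in enumerate(population)},
                   d / "population.fasta")
    io.write_fasta({"outgroup": outgroup}, d / "outgroup.fasta")
    io.write_fasta({"ancestral": ancestral}, d / "ancestral.fasta")

    family = sim.simulate_domain_family(
        n_per_group=p["domains_per_group"], n_groups=p["domain_groups"],
        length=p["domain_length"], seed=seed + 4,
    )
    io.write_fasta(family, d / "domains.fasta")

    with open(d / "params.yaml", "w") as fh:
        yaml.safe_dump({"seed": seed, "simulate": p}, fh, sort_keys=True)
    log.info("simulate: %d clusters, %d reads, %d haplotypes, %d domains",
             len(specs), len(reads), len(population), len(family))
    return {"n_reads": len(reads), "n_clusters": len(specs)}


def run_clusters(cfg: dict, outdir: Path) -> dict:
    log = io.get_logger("clusters")
    p = cfg["clusters"]
    d = outdir / "clusters"
    d.mkdir(parents=True, exist_ok=True)
    sim_dir = outdir / "simulate"
    if not (sim_dir / "truth.sam").exists():
        raise FileNotFoundError("clusters stage: missing simulate stage outputs")

    genome = io.read_fasta(sim_dir / "genome.fasta")
    stats: dict = {}
    alignments = list(io.read_alignments(sim_dir / "truth.sam", stats=stats))
    windows = cl.partition_genome({c: len(s) for c, s in genome.items()}, p["window_size"])
    cl.count_window_reads(windows, alignments, count_mode=p["count_mode"])
    cl.classify_windows(windows, min_reads=p["min_reads"])
    predicted = cl.merge_windows(windows, genome_tag=cfg["genome_tag"],
                                 merge_adjacent=p["merge_adjacent"])
    io.write_bed(
        [(c.chrom, c.start, c.end, c.cluster_id, c.class_label) for c in predicted],
        d / "clusters.bed",
    )
    reference = cl.build_cluster_reference(genome, predicted)
    io.write_fasta(reference, d / "clusters.fasta")

    projected = project_to_clusters(alignments, predicted)
    surviving = [a for a in projected if a.mismatches <= p["max_mismatch"]]
    total_mapped = len(surviving)
    profiles = cl.quantify_clusters(
        surviving, total_mapped=max(total_mapped, 1),
        cluster_ids=[c.cluster_id for c in predicted], max_mismatch=p["max_mismatch"],
    )
    rpm_rows = {cid: prof.rpm.stack() for cid, prof in profiles.items()}
    matrix = pd.DataFrame(
        {cid: row for cid, row in rpm_rows.items()}
    ).T
    matrix.columns = [f"{length}_{base}" for length, base in matrix.columns]
    matrix.index.name = "cluster_id"
    _write_table(matrix.sort_index(), d / "cluster_rpm.tsv")
    report = cl.report_filter(profiles, min_rpm=p["min_rpm"])
    _write_table(report, d / "report.tsv")
    log.info("clusters: %d alignments in, %d clusters out (%d reported)",
             len(alignments), len(predicted), len(report))
    return {"n_clusters": len(predicted), "n_reported": len(report)}


def project_to_clusters(alignments, predicted) -> list[io.AlignmentRecord]:
    """Re-express genome alignments in cluster-reference coordinates,
    standing in for the re-mapping round against the cluster FASTA."""
    out = []
    for aln in alignments:
        for c in predicted:
            if c.chrom == aln.reference_name and c.start <= aln.start and aln.end <= c.end:
                out.append(
                    io.AlignmentRecord(
                        read_id=aln.read_id, reference_name=c.cluster_id,
                        start=aln.start - c.start, strand=aln.strand,
                        mismatches=aln.mismatches, hit_count=aln.hit_count,
                        read_length=aln.read_length, first_nt=aln.first_nt,
                    )
                )
                break
    return out


def run_profile(cfg: dict, outdir: Path) -> dict:
    log = io.get_logger("profile")
    p = cfg["profile"]
    d = outdir / "profile"
    d.mkdir(parents=True, exist_ok=True)
    sim_dir = outdir / "simulate"
    if not (sim_dir / "reads.fastq").exists():
        raise FileNotFoundError("profile stage: missing simulate stage outputs")

    kept, tally = pr.preprocess_reads(
        io.read_fastq(sim_dir / "reads.fastq"), trim5=p["trim5"],
        min_len=p["min_len"], min_mean_q=p["min_mean_q"],
    )
    with open(d / "preprocess_tally.json", "w") as fh:
        json.dump(tally, fh, indent=2, sort_keys=True)

    stats: dict = {}
    alignments = list(io.read_alignments(sim_dir / "truth.sam", stats=stats))
    length_range = (p["length_min"], p["length_max"])
    profile = pr.genome_size_profile(
        alignments, total_mapped=max(stats["mapped"], 1),
        max_mismatch=p["max_mismatch"], length_range=length_range,
    )
    _write_table(profile.rpm_display(), d / "genome_profile.tsv")

    cluster_bed = outdir / "clusters" / "clusters.bed"
    assignment_counts = {}
    if cluster_bed.exists():
        features = {}
        for chrom, start, end, cid, label in io.read_bed(cluster_bed):
            features.setdefault(label, []).append((chrom, int(start), int(end)))
        order = [f for f in p["hierarchy"] if f in features]
        per_round = {
            f: [a for a in alignments
                if any(c == a.reference_name and s <= a.start and a.end <= e
                       for c, s, e in features[f])]
            for f in order
        }
        assignment, feat_profiles = pr.sequential_assign(
            [a.read_id for a in alignments], order, per_round,
            max_mismatch=p["max_mismatch"],
            total_mapped=len(alignments), length_range=length_range,
        )
        for label in sorted(set(assignment.values())):
            assignment_counts[label] = sum(1 for v in assignment.values() if v == label)
        counts = pd.Series(assignment_counts, name="n_reads").to_frame()
        counts.index.name = "feature"
        _write_table(counts, d / "assignment_counts.tsv")
        rpm_totals = {f: prof.total_rpm for f, prof in feat_profiles.items()}
        totals = pd.Series(rpm_totals, name="total_rpm").to_frame()
        totals.index.name = "feature"
        _write_table(totals, d / "feature_rpm.tsv")
    log.info("profile: %d raw reads, %d kept, %d aligned",
             sum(tally.values()), tally["kept"], stats["mapped"])
    return {"kept": tally["kept"], "assigned": assignment_counts}


def run_mkt(cfg: dict, outdir: Path) -> dict:
    log = io.get_logger("mkt")
    d = outdir / "mkt"
    d.mkdir(parents=True, exist_ok=True)
    sim_dir = outdir / "simulate"
    if not (sim_dir / "population.fasta").exists():
        raise FileNotFoundError("mkt stage: missing simulate stage outputs")
    population = list(io.read_fasta(sim_dir / "population.fasta").values())
    outgroup = next(iter(io.read_fasta(sim_dir / "outgroup.fasta").values()))
    alignment = mk.CodonAlignment(population=population, outgroup=outgroup)
    result, kaks, tally = mk.mkt_from_alignment(alignment)
    table = pd.DataFrame(
        [{
            "gene": "sim_cds", "Pn": result.Pn, "Ps": result.Ps,
            "Dn": result.Dn, "Ds": result.Ds, "p_value": result.p_value,
            "NI": result.NI, "alpha": result.alpha,
            "Ka": kaks.Ka, "Ks": kaks.Ks, "omega": kaks.omega,
        }]
    ).set_index("gene")
    _write_table(table, d / "mkt.tsv")
    with open(d / "skipped_tally.json", "w") as fh:
        json.dump(tally, fh, indent=2, sort_keys=True)
    log.info("mkt: Pn=%s Ps=%s Dn=%s Ds=%s p=%.3g", result.Pn, result.Ps,
             result.Dn, result.Ds, result.p_value)
    return {"p_value": result.p_value, "omega": kaks.omega}


def run_domains(cfg: dict, outdir: Path) -> dict:
    log = io.get_logger("domains")
    p = cfg["domains"]
    d = outdir / "domains"
    d.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "simulate" / "domains.fasta"
    if not fasta.exists():
        raise FileNotFoundError("domains stage: missing simulate stage outputs")
    sequences = io.read_fasta(fasta)
    ident, alnpct = dom.identity_matrix(
        sequences, matrix=p["matrix"], gap_open=p["gap_open"],
        gap_extend=p["gap_extend"],
    )
    _write_table(ident, d / "identity_pct.tsv")
    _write_table(alnpct, d / "alignment_pct.tsv")
    newick, _ = dom.cluster_dendrogram(ident, linkage=p["linkage"])
    io.write_newick(newick, d / "dendrogram.nwk")
    log.info("domains: %d sequences compared", len(sequences))
    return {"n_domains": len(sequences)}


_STAGES = {
    "simulate": run_simulate,
    "clusters": run_clusters,
    "profile": run_profile,
    "mkt": run_mkt,
    "domains": run_domains,
}


def run_pipeline(cfg: dict, outdir: str | Path, stages: list[str] | None = None) -> dict:
    """Run the requested stages in dependency order and write the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or list(_STAGES)
    summary = {}
    for stage in _STAGES:
        if stage in stages:
            summary[stage] = _STAGES[stage](cfg, outdir)
    manifest = {
        "config": cfg,
        "outputs": {
            str(f.relative_to(outdir)): _sha256(f)
            for f in sorted(outdir.rglob("*"))
            if f.is_file() and f.name != "manifest.json"
        },
        "summary": summary,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
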