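"""Stage orchestration: reproducible runs with config, manifests and reports.

Each ``run_*`` function wires library stages together, validates inputs before
any computation, and writes a JSON manifest (inputs, config, seed, version)
next to its outputs so every result is traceable to its conditions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .annotate import ReferenceSet, annotate_genome, summarize_lengths
from .cluster_tandem import classify_junctions, find_tandem_arrays
from .evolution import dip_test, k2p_distance, p_distance, pairwise_diversity
from .insertion_context import (cooccurrence_test, extract_flanks,
                                nearest_repeat_distances, sample_controls)
from .seqio import (read_bed_repeats, read_fasta, read_gff3, read_repeat_out,
                    write_element_table, write_fasta, write_gff3)
from .synthetic_data import ImplantSpec, implant


@dataclass
class RunConfig:
    """All pipeline thresholds, defaulting to the printed study constants."""

    protein_evalue: float = 1e-120       # tBLASTn screening cutoff
    min_protein_identity: float = 75.0   # over the full transposase
    transposase_len: int = 339           # aa
    mite_evalue: float = 1e-20           # relaxed cutoff for MITE search
    terminal_window: int = 250           # nt of terminus holding the 3 DRs
    dr_len: int = 18
    sir_arm: int = 28
    lir_threshold: int = 60
    flank_len: int = 2500
    n_controls: int = 1000
    control_len: int = 2500
    windows: tuple = (500, 1000, 1500, 2000, 2500)
    min_logo_flanks: int = 4
    alpha: float = 0.05
    ht_alpha: float = 0.005
    gamma_shape: float = 1.0
    seed: int = 0

    def validate_keys(self, overrides: dict) -> None:
        known = {f.name for f in dataclasses.fields(self)}
        for k in overrides:
            if k not in known:
                raise ValueError(f"unknown config key: {k!r}")


def _manifest(path: Path, stage: str, inputs: dict, config) -> None:
    cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    man = {
        "stage": stage,
        "version": __version__,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": cfg,
        "config_sha1": hashlib.sha1(blob).hexdigest(),
    }
    path.write_text(json.dumps(man, indent=2, default=str) + "\n")


def _require(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"missing input: {p}")
    return p


def run_simulate(out_prefix: str, seed: int, genome_length: int = 1_000_000,
                 config: RunConfig | None = None, **spec_kwargs) -> dict:
    """Generate a synthetic genome with ground truth; writes FASTA, truth GFF3,
    reference FASTAs and a manifest."""
    config = config or RunConfig(seed=seed)
    spec = ImplantSpec(seed=seed, genome_length=genome_length, **spec_kwargs)
    genome, truth, refs = implant(spec)
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_fasta([genome], f"{prefix}.genome.fasta")
    write_gff3(truth, f"{prefix}.truth.gff3")
    from .seqio import GenomeRecord
    write_fasta([GenomeRecord(id=k, residues=v, species_code=spec.species_code)
                 for k, v in refs.elements.items()], f"{prefix}.refs.fasta")
    with open(f"{prefix}.proteins.fasta", "w") as fh:
        for name, prot in refs.proteins.items():
            fh.write(f">{name}\n{prot}\n")
    _manifest(Path(f"{prefix}.manifest.json"), "simulate",
              {"out_prefix": out_prefix}, {**dataclasses.asdict(config),
                                           "spec": dataclasses.asdict(spec)})
    return {"genome": genome, "truth": truth, "refs": refs}


def load_references(elements_fasta, proteins_fasta) -> ReferenceSet:
    elements = {r.id: r.residues for r in read_fasta(_require(elements_fasta))}
    proteins = {}
    with open(_require(proteins_fasta)) as fh:
        name = None
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                proteins[name] = ""
            elif name:
                proteins[name] += line
    return ReferenceSet(proteins=proteins, elements=elements)


def run_annotate(genome_fasta, elements_fasta, proteins_fasta, out_prefix: str,
                 config: RunConfig | None = None) -> list:
    """Annotate every contig of a genome FASTA; writes GFF3 + TSV + manifest."""
    config = config or RunConfig()
    genomes = read_fasta(_require(genome_fasta))
    refs = load_references(elements_fasta, proteins_fasta)
    annotations = []
    for g in genomes:
        annotations.extend(annotate_genome(g, refs))
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_gff3(annotations, f"{prefix}.gff3")
    write_element_table(annotations, f"{prefix}.tsv")
    if annotations:
        summary = summarize_lengths(annotations)
        Path(f"{prefix}.summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    _manifest(Path(f"{prefix}.manifest.json"), "annotate",
              {"genome": genome_fasta, "elements": elements_fasta,
               "proteins": proteins_fasta}, config)
    return annotations


def run_cluster(genome_fasta, annotations_gff3, reference_fasta, out_prefix: str,
                max_gap: int = 100, config: RunConfig | None = None) -> list:
    """Find tandem arrays among annotations and type their junctions."""
    config = config or RunConfig()
    genomes = {g.id: g for g in read_fasta(_require(genome_fasta))}
    reference = read_fasta(_require(reference_fasta))[0].residues
    from .annotate import ElementAnnotation
    anns = []
    for row in read_gff3(_require(annotations_gff3)):
        at = row["attributes"]
        anns.append(ElementAnnotation(
            interval=row["interval"], species_code="Dxxx",
            category=at.get("category", "ND"), subfamily=at.get("subfamily", "ND"),
            tir_type=at.get("tir_type", "ND"),
            dr_counts=(int(at.get("dr_left", 0)), int(at.get("dr_right", 0))),
            tsd=at.get("tsd", "unknown"), name=at.get("ID", "")))
    arrays = find_tandem_arrays(anns, max_gap=max_gap)
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.junctions.tsv", "w") as fh:
        fh.write("array\tcontig\tstart\tend\tn_members\tjunction_idx\tjunction_type\n")
        for ai, arr in enumerate(arrays):
            g = genomes[arr.interval.seq_id]
            for ji, j in enumerate(classify_junctions(arr, g, reference)):
                fh.write(f"{ai}\t{arr.interval.seq_id}\t{arr.interval.start}\t"
                         f"{arr.interval.end}\t{len(arr.members)}\t{ji}\t"
                         f"{j.junction_type}\n")
    _manifest(Path(f"{prefix}.manifest.json"), "cluster",
              {"genome": genome_fasta, "annotations": annotations_gff3,
               "reference": reference_fasta}, config)
    return arrays


def run_cooccur(genome_fasta, annotations_gff3, repeats_path, out_prefix: str,
                seed: int, config: RunConfig | None = None) -> list:
    """Poisson co-occurrence of repeat superfamilies in element flanks vs
    seeded random control regions."""
    config = config or RunConfig(seed=seed)
    genomes = read_fasta(_require(genome_fasta))
    gmap = {g.id: g for g in genomes}
    rp = str(repeats_path)
    repeats = read_repeat_out(_require(rp)) if rp.endswith(".out") \
        else read_bed_repeats(_require(rp))
    from .annotate import ElementAnnotation
    anns = []
    for row in read_gff3(_require(annotations_gff3)):
        at = row["attributes"]
        anns.append(ElementAnnotation(
            interval=row["interval"], species_code="Dxxx",
            category=at.get("category", "ND"), subfamily=at.get("subfamily", "ND"),
            tir_type=at.get("tir_type", "ND"), dr_counts=(0, 0),
            tsd=at.get("tsd", "unknown"), name=at.get("ID", "")))
    flanks = []
    for g in genomes:
        flanks.extend(extract_flanks(g, anns, flank_len=config.flank_len))
    controls = sample_controls(genomes, n=config.n_controls,
                               length=config.control_len, seed=seed)
    fd = nearest_repeat_distances(flanks, repeats)
    cd = nearest_repeat_distances(controls, repeats)
    rows = cooccurrence_test(fd, cd, n_flanks=len(flanks),
                             n_controls=len(controls), alpha=config.alpha,
                             windows=tuple(config.windows))
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.cooccurrence.tsv", "w") as fh:
        fh.write("superfamily\twindow\tobserved\texpected\tp_enrich\tp_deplete\tcall\n")
        for r in rows:
            fh.write(f"{r.superfamily}\t{r.window}\t{r.observed}\t{r.expected:.4f}\t"
                     f"{r.p_enrich:.3e}\t{r.p_deplete:.3e}\t{r.call}\n")
    _manifest(Path(f"{prefix}.manifest.json"), "cooccur",
              {"genome": genome_fasta, "annotations": annotations_gff3,
               "repeats": repeats_path, "seed": seed}, config)
    return rows


def run_evolve(aligned_fasta, out_prefix: str, seed: int = 0,
               model: str = "K2P+G", config: RunConfig | None = None) -> dict:
    """Distance matrices, pairwise diversity and a dip-test report for a set of
    aligned element copies."""
    config = config or RunConfig(seed=seed)
    records = read_fasta(_require(aligned_fasta))
    names = [r.id for r in records]
    seqs = [r.residues for r in records]
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if model == "p":
                d = p_distance(seqs[i], seqs[j]).d
            else:
                shape = None if model == "K2P" else config.gamma_shape
                d = k2p_distance(seqs[i], seqs[j], gamma_shape=shape).d
            dist[i, j] = dist[j, i] = d
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.distances.tsv", "w") as fh:
        fh.write("\t" + "\t".join(names) + "\n")
        for i, nm in enumerate(names):
            fh.write(nm + "\t" + "\t".join(f"{v:.6f}" for v in dist[i]) + "\n")
    report = {"model": model, "n": n}
    if n >= 4:
        div = pairwise_diversity(seqs)
        dres = dip_test(div, n_boot=2000, seed=seed)
        report["dip"] = {"statistic": dres.dip, "p": dres.p, "n_boot": dres.n_boot}
    Path(f"{prefix}.report.json").write_text(json.dumps(report, indent=2) + "\n")
    _manifest(Path(f"{prefix}.manifest.json"), "evolve",
              {"aligned": aligned_fasta, "seed": seed, "model": model}, config)
    return report
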