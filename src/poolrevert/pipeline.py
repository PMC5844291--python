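"""End-to-end orchestration: simulate -> align -> call -> classify -> design.

One run is driven by a RunConfig, writes every intermediate artifact into a
run directory (reference FASTA, GFF3, parental VCF, per-mixture FASTQ/SAM/
VCF, classified TSVs, suppressor and design reports), serialises the config
verbatim next to them, and logs seeds and stage progress. Re-running with
the same config reproduces all outputs byte-identically.

Stages can be toggled so any stage can be re-run from the previous stage's
files (e.g. classify alone on externally produced VCFs).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from . import __version__
from .align import build_index, map_read_set, pileup, read_sam, write_sam
from .classify import (AnchorIntegrityWarning, ClassifierParams,
                       classify_calls, read_complex_map, recurrence_filter,
                       write_classified_tsv, write_report_tsv)
from .design import PowerParams, detection_power, expected_af, lane_multiplex
from .poolcall import (CallerParams, call_mixture, estimate_error_rate,
                       read_calls_vcf, write_calls_vcf)
from .simulate import (AnnotationSet, PairedReadSet, PoolSpec, ReadSimParams,
                       ReferenceGenome, Screen, SuppressorModel, make_annotation,
                       make_genome, make_screen, read_truth_table,
                       simulate_pool_reads, write_parental_vcf,
                       write_truth_table)
from .vcfio import read_vcf_records

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "align", "call", "classify", "design")


@dataclass
class RunConfig:
    out_dir: str = "poolrevert_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulate
    genome_length: int = 100_000
    gc_fraction: float = 0.36
    n_genes: int = 20
    gene_length_min: int = 300
    gene_length_max: int = 1500
    ts_gene: str = "gene001"
    n_mixtures: int = 1
    pool_size: int = 10
    n_background: int = 5
    suppressors_per_revertant: int = 1
    # reads
    read_length: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    coverage_per_genome: float = 30.0
    error_rate: float = 0.002
    # align
    k: int = 15
    max_mismatch_fraction: float = 0.1
    # call
    alpha: float = 0.05
    min_af: float = 0.02
    min_depth: int = 10
    estimate_error: bool = False
    # classify
    anchor_min_af: float = 0.9
    background_min_af: float = 0.8
    recurrence_threshold: int = 2

    def to_file(self, path: Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if f.name == "stages":
                    v = ",".join(v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                cur = getattr(defaults, key)
                if key == "stages":
                    kwargs[key] = tuple(s.strip() for s in raw.split(",") if s.strip())
                elif isinstance(cur, bool):
                    kwargs[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(cur, int):
                    kwargs[key] = int(raw)
                elif isinstance(cur, float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)


@dataclass
class RunResult:
    out_dir: Path
    screen: Screen | None
    calls_by_mixture: dict[str, list]
    classified: list
    reports: list
    anchor_warnings: list[str] = field(default_factory=list)

    @property
    def anchor_ok(self) -> bool:
        return not self.anchor_warnings


def _ts3339() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


def run_screen(config: RunConfig) -> RunResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.txt")
    logfh = open(out / "run.log", "a")

    def say(msg: str) -> None:
        line = f"{_ts3339()} {msg}"
        log.info(msg)
        logfh.write(line + "\n")
        logfh.flush()

    say(f"poolrevert {__version__} run start, seed={config.seed}, "
        f"stages={','.join(config.stages)}")
    stages = set(config.stages)
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}")

    screen: Screen | None = None
    try:
        # ---- simulate ----------------------------------------------------
        if "simulate" in stages:
            say("stage simulate: genome + annotation + screen")
            genome = make_genome(config.genome_length, config.gc_fraction,
                                 seed=config.seed)
            annotation = make_annotation(
                genome, config.n_genes,
                (config.gene_length_min, config.gene_length_max),
                seed=config.seed + 1)
            model = SuppressorModel(
                per_revertant_count=config.suppressors_per_revertant)
            screen = make_screen(genome, annotation, config.ts_gene,
                                 N=config.pool_size,
                                 n_background=config.n_background,
                                 suppressor_model=model,
                                 seed=config.seed + 2,
                                 n_mixtures=config.n_mixtures)
            genome.write_fasta(out / "ref.fasta")
            annotation.write_gff3(out / "genes.gff3")
            write_parental_vcf(screen, out / "parental.vcf")
            write_truth_table(screen, out / "truth.tsv")
        else:
            genome = ReferenceGenome.read_fasta(out / "ref.fasta")
            cm_path = out / "complex_map.tsv"
            annotation = AnnotationSet.read_gff3(
                out / "genes.gff3",
                read_complex_map(cm_path) if cm_path.exists() else None)

        # ---- align -------------------------------------------------------
        mixture_ids = [f"mix{i}" for i in range(config.n_mixtures)]
        pileups: dict[str, object] = {}
        if "align" in stages:
            index = build_index(genome, config.k)
            pool = PoolSpec(config.pool_size)
            for mi, mid in enumerate(mixture_ids):
                params = ReadSimParams(
                    read_length=config.read_length,
                    insert_mean=config.insert_mean,
                    insert_sd=config.insert_sd,
                    coverage_per_genome=config.coverage_per_genome,
                    error_rate=config.error_rate,
                    seed=config.seed + 100 + mi)
                if screen is not None:
                    say(f"stage align: simulating reads for {mid} "
                        f"(seed={params.seed})")
                    reads = simulate_pool_reads(screen.mixtures[mi], pool,
                                                params)
                    reads.write_fastq(out / f"{mid}.r1.fastq",
                                      out / f"{mid}.r2.fastq")
                else:
                    say(f"stage align: loading reads for {mid} from FASTQ")
                    reads = _load_fastq_pairs(out / f"{mid}.r1.fastq",
                                              out / f"{mid}.r2.fastq",
                                              config.read_length)
                say(f"stage align: mapping {2 * len(reads)} reads for {mid}")
                alns = map_read_set(reads, index, config.max_mismatch_fraction)
                write_sam(alns, genome, out / f"{mid}.sam")
                pileups[mid] = pileup(alns, genome)

        # ---- call --------------------------------------------------------
        calls_by_mixture: dict[str, list] = {}
        if "call" in stages:
            for mid in mixture_ids:
                pp = pileups.get(mid)
                if pp is None:
                    say(f"stage call: rebuilding pileup for {mid} from SAM")
                    alns = read_sam(out / f"{mid}.sam", genome)
                    pp = pileup(alns, genome)
                e = config.error_rate
                if config.estimate_error:
                    e = estimate_error_rate(pp, genome)
                    say(f"stage call: estimated error rate {e:.3g} for {mid}")
                cp = CallerParams(error_rate=e, alpha=config.alpha,
                                  min_af=config.min_af,
                                  min_depth=config.min_depth)
                calls = call_mixture(pp, genome, cp, mixture_id=mid)
                say(f"stage call: {len(calls)} calls in {mid}")
                write_calls_vcf(calls, out / f"{mid}.calls.vcf", genome)
                calls_by_mixture[mid] = calls

        # ---- classify ----------------------------------------------------
        classified_all: list = []
        reports: list = []
        anchor_warnings: list[str] = []
        if "classify" in stages:
            if not calls_by_mixture:
                for vcf in sorted(out.glob("mix*.calls.vcf")):
                    mid = vcf.name.split(".")[0]
                    calls_by_mixture[mid] = read_calls_vcf(vcf, mid)
            ts_locus = _resolve_ts_locus(out, screen)
            parental = _resolve_parental(out, screen)
            cparams = ClassifierParams(
                ts_locus, anchor_min_af=config.anchor_min_af,
                background_min_af=config.background_min_af,
                min_af=config.min_af)
            for mid, calls in sorted(calls_by_mixture.items()):
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always", AnchorIntegrityWarning)
                    cls = classify_calls(calls, cparams, parental,
                                         annotation, genome)
                for w in caught:
                    if issubclass(w.category, AnchorIntegrityWarning):
                        msg = f"{mid}: {w.message}"
                        anchor_warnings.append(msg)
                        say(f"WARNING {msg}")
                classified_all.extend(cls)
            write_classified_tsv(classified_all, out / "classified.tsv")
            reports = recurrence_filter(
                classified_all, annotation, config.recurrence_threshold,
                ts_gene=config.ts_gene)
            write_report_tsv(reports, out / "suppressor_report.tsv")
            say(f"stage classify: {len(reports)} recurrence-filtered units")

        # ---- design ------------------------------------------------------
        if "design" in stages:
            power = detection_power(PowerParams(
                N=config.pool_size,
                coverage_per_genome=config.coverage_per_genome,
                error_rate=config.error_rate, min_af=config.min_af,
                alpha=config.alpha, n_tests=3 * genome.total_length))
            report = {
                "expected_suppressor_af": expected_af(config.pool_size),
                "genomes_per_lane": lane_multiplex(config.n_mixtures,
                                                   config.pool_size),
                "detection_power": power,
                "pooled_depth": config.pool_size * config.coverage_per_genome,
            }
            with open(out / "design_report.json", "w") as fh:
                json.dump(report, fh, indent=2)
            say(f"stage design: detection power {power:.6f}")

        say("run complete" + (" (anchor warnings present)"
                              if anchor_warnings else ""))
        return RunResult(out, screen, calls_by_mixture, classified_all,
                         reports, anchor_warnings)
    except Exception as exc:  # annotate which stage died
        say(f"FAILED: {type(exc).__name__}: {exc}")
        raise
    finally:
        logfh.close()


def _resolve_ts_locus(out: Path, screen: Screen | None) -> tuple[str, int, str]:
    if screen is not None:
        ts = screen.ts_mutation
        return (ts.chrom, ts.pos, ts.alt)
    truth_path = out / "truth.tsv"
    if truth_path.exists():
        for m in read_truth_table(truth_path):
            if m.role == "ts":
                return (m.chrom, m.pos, m.alt)
    raise ValueError("ts locus unknown: no screen in memory and no truth.tsv")


def _resolve_parental(out: Path, screen: Screen | None):
    if screen is not None:
        return screen.background
    vcf = out / "parental.vcf"
    if not vcf.exists():
        return []
    return [(chrom, pos, ref, alt)
            for chrom, pos, ref, alt, _ in read_vcf_records(vcf)]


def _load_fastq_pairs(r1_path: Path, r2_path: Path,
                      read_length: int) -> PairedReadSet:
    from ._dna import encode
    names: list[str] = []
    mats = []
    for path in (r1_path, r2_path):
        seqs = []
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                if path == r1_path:
                    names.append(rec.name)
                seqs.append(encode(rec.sequence))
        mats.append(np.stack(seqs) if seqs
                    else np.empty((0, read_length), dtype=np.uint8))
    return PairedReadSet(names, mats[0], mats[1], float("nan"))
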