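"""Top-level trio pipeline: k-mer counting, alignment, classification, reports.

``run_pipeline`` wires the stages together for three assemblies with
annotations and read sets: count canonical k-mers per genome, align every
ordered genome pair, classify each genome's bases into Venn sectors, call
non-repetitive (and genic) specific regions using the three k-mer
databases, assign genes to sectors, and emit TSV report tables plus a JSON
manifest recording the configuration and input checksums.

Stages are resumable: a stage is skipped when its outputs exist and the
manifest's recorded input checksums still match, so deleting one
intermediate regenerates only the artifacts downstream of it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

from . import align as al
from .intervals import AnnotationSet, IntervalSet, annotate_overlap
from .kmers import (KmerDB, KmerThresholds, count_kmers_from_files,
                    estimate_mode, profile_sequence_set)
from .pangenome import (SpecificRegionCriteria, assign_all_genes,
                        call_genic_specific_regions, call_specific_regions,
                        classify_bases, spacing_stats, venn_summary)
from .seqio import SequenceSet
from .stats import assembly_stats, region_summary

log = logging.getLogger("pantrio")


@dataclass
class RunConfig:
    """All pipeline parameters; serializable and recorded in the manifest."""

    assumed_genome_size: int = 389_000_000
    k: int = 21
    seed: int = 0
    genome_order: tuple[str, ...] = ("A", "B", "C")
    sample_reads: int | None = None
    log_level: str = "INFO"
    thresholds: KmerThresholds = field(default_factory=KmerThresholds)
    aligner: al.AlignerConfig = field(default_factory=al.AlignerConfig)
    criteria: SpecificRegionCriteria = field(default_factory=SpecificRegionCriteria)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genome_order"] = list(self.genome_order)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "genome_order" in d:
            d["genome_order"] = tuple(d["genome_order"])
        if isinstance(d.get("thresholds"), dict):
            d["thresholds"] = KmerThresholds(**d["thresholds"])
        if isinstance(d.get("aligner"), dict):
            d["aligner"] = al.AlignerConfig(**d["aligner"])
        if isinstance(d.get("criteria"), dict):
            c = dict(d["criteria"])
            if "self_cov_range" in c:
                c["self_cov_range"] = tuple(c["self_cov_range"])
            d["criteria"] = SpecificRegionCriteria(**c)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class GenomeInputs:
    fasta: Path
    gff: Path | None = None
    reads: list[Path] = field(default_factory=list)
    kmer_db: Path | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"stages": {}}
        if path.exists():
            try:
                self.data = json.loads(path.read_text())
            except json.JSONDecodeError:
                pass
        self.data.setdefault("stages", {})

    def up_to_date(self, stage: str, inputs: Sequence[Path],
                   outputs: Sequence[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None:
            return False
        if not all(Path(o).exists() for o in outputs):
            return False
        want = {str(p): _sha256(Path(p)) for p in inputs}
        return rec.get("inputs") == want

    def record(self, stage: str, inputs: Sequence[Path],
               outputs: Sequence[Path], seconds: float) -> None:
        self.data["stages"][stage] = {
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "outputs": [str(o) for o in outputs],
            "seconds": round(seconds, 2),
        }

    def save(self, config: RunConfig) -> None:
        self.data["config"] = config.to_dict()
        self.data["config_hash"] = config.config_hash()
        self.path.write_text(json.dumps(self.data, indent=2) + "\n")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, inputs: Mapping[str, GenomeInputs],
                 out_dir: str | Path) -> Path:
    """Run the full trio analysis; returns the output directory.

    ``inputs`` maps each genome name of ``config.genome_order`` to its FASTA,
    GFF3 and read files (or a precomputed k-mer dump).  Deterministic for a
    fixed config; every artifact is recorded in ``manifest.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    order = list(config.genome_order)
    missing = [g for g in order if g not in inputs]
    if missing:
        raise ValueError(f"no inputs for genome(s) {missing}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")

    def stage(name: str, in_paths, out_paths, fn):
        in_paths = [Path(p) for p in in_paths]
        out_paths = [Path(p) for p in out_paths]
        if manifest.up_to_date(name, in_paths, out_paths):
            log.info("stage %s: up to date, skipping", name)
            return
        t0 = time.perf_counter()
        log.info("stage %s: running", name)
        try:
            fn()
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        manifest.record(name, in_paths, out_paths, time.perf_counter() - t0)
        manifest.save(config)

    genomes = {g: SequenceSet.from_fasta(inputs[g].fasta) for g in order}
    annotations = {g: AnnotationSet.from_gff3(inputs[g].gff)
                   for g in order if inputs[g].gff}

    # ---- assembly statistics -------------------------------------------
    stats_path = out / "assembly_stats.tsv"

    def do_stats():
        with open(stats_path, "w") as fh:
            fh.write("genome\ttotal_span\ttotal_bases\tn_scaffolds\tscaffold_n50\t"
                     "max_scaffold\tn_contigs\tcontig_n50\tmax_contig\t"
                     "span_coverage_pct\tbases_coverage_pct\n")
            for g in order:
                s = assembly_stats(genomes[g], config.assumed_genome_size)
                fh.write(f"{g}\t{s.total_span}\t{s.total_bases}\t{s.n_scaffolds}\t"
                         f"{s.scaffold_n50}\t{s.max_scaffold}\t{s.n_contigs}\t"
                         f"{s.contig_n50}\t{s.max_contig}\t{s.span_coverage_pct}\t"
                         f"{s.bases_coverage_pct}\n")

    stage("stats", [inputs[g].fasta for g in order], [stats_path], do_stats)

    # ---- k-mer databases ------------------------------------------------
    db_paths: dict[str, Path] = {}
    for g in order:
        if inputs[g].kmer_db:
            db_paths[g] = Path(inputs[g].kmer_db)
            continue
        db_paths[g] = out / f"{g}.kmers.tsv"
        reads = inputs[g].reads

        def do_count(g=g, reads=reads):
            db = count_kmers_from_files(reads, k=config.k,
                                        sample_reads=config.sample_reads,
                                        seed=config.seed)
            db.to_tsv(db_paths[g])

        if reads:
            stage(f"kmers:{g}", reads, [db_paths[g]], do_count)

    dbs = {g: KmerDB.from_tsv(p) for g, p in db_paths.items() if p.exists()}

    # ---- pairwise alignments --------------------------------------------
    pair_un: dict[tuple[str, str], Path] = {}
    for g in order:
        index = None
        for h in order:
            if h == g:
                continue
            un_bed = out / f"{g}_vs_{h}.unaligned.bed"
            blocks_tsv = out / f"{g}_vs_{h}.blocks.tsv"
            summ_json = out / f"{g}_vs_{h}.summary.json"
            pair_un[(g, h)] = un_bed

            def do_align(g=g, h=h, un_bed=un_bed, blocks_tsv=blocks_tsv,
                         summ_json=summ_json):
                nonlocal index
                if index is None:
                    index = al.ReferenceIndex(genomes[g], config.aligner)
                res = al.align_genomes(genomes[g], genomes[h], config.aligner,
                                       index=index)
                al.write_blocks_tsv(res.blocks, blocks_tsv)
                res.unaligned(genomes[g]).to_bed(un_bed)
                summ_json.write_text(json.dumps(asdict(res.summary), indent=2) + "\n")

            stage(f"align:{g}:{h}", [inputs[g].fasta, inputs[h].fasta],
                  [un_bed, blocks_tsv, summ_json], do_align)

    # ---- classification + reports ---------------------------------------
    labelings = {}
    for g in order:
        others = tuple(h for h in order if h != g)
        u1 = IntervalSet.from_bed(pair_un[(g, others[0])])
        u2 = IntervalSet.from_bed(pair_un[(g, others[1])])
        labelings[g] = classify_bases(genomes[g].lengths(), u1, u2, g, others)
        sector_bed = out / f"{g}.sectors.bed"
        with open(sector_bed, "w") as fh:
            for sector, sset in labelings[g].by_sector().items():
                for name, arr in sset.items():
                    for s, e in arr:
                        fh.write(f"{name}\t{s}\t{e}\t{sector}\t0\t+\n")

    assignments = {g: assign_all_genes(annotations[g], labelings[g], order)
                   for g in order if g in annotations}
    if assignments:
        for g, amap in assignments.items():
            with open(out / f"{g}.gene_sectors.tsv", "w") as fh:
                fh.write("gene\tsector\n")
                for gid, sector in sorted(amap.items()):
                    fh.write(f"{gid}\t{sector}\n")
        rows = venn_summary(labelings, annotations, assignments, order)
        with open(out / "venn.tsv", "w") as fh:
            fh.write("sector\treporting_genome\tbp\texonic_bp\tgene_count\n")
            for r in rows:
                fh.write(f"{r.sector}\t{r.reporting_genome}\t{r.bp}\t"
                         f"{r.exonic_bp}\t{r.gene_count}\n")

    def summary_row(name, g, regions, profiles):
        s = region_summary(regions, profiles)
        cov = f"{s.mean_kmer_coverage:.1f}" if s.mean_kmer_coverage is not None else "NA"
        return (f"{name}\t{g}\t{s.total_bp}\t{s.regions}\t{s.mean_length}\t"
                f"{s.sd_length}\t{s.max_length}\t{cov}\n")

    if dbs:
        profiles = {g: profile_sequence_set(genomes[g], dbs[g]) for g in order}
        modes = {}
        for g in order:
            try:
                modes[g] = estimate_mode(dbs[g].histogram(),
                                         config.thresholds.error_cutoff)
            except ValueError:
                modes[g] = None
        (out / "kmer_modes.json").write_text(json.dumps(modes, indent=2) + "\n")
        header = ("table\tgenome\ttotal_bp\tregions\tmean_length\tsd_length\t"
                  "max_length\tmean_kmer_coverage\n")
        with open(out / "unaligned_summary.tsv", "w") as fh:
            fh.write(header)
            for (g, h), bed in pair_un.items():
                un = IntervalSet.from_bed(bed)
                fh.write(summary_row(f"unaligned_{g}_vs_{h}", g, un, profiles[g]))
        spec_summ = open(out / "specific_summary.tsv", "w")
        genic_summ = open(out / "genic_specific_summary.tsv", "w")
        spec_summ.write(header)
        genic_summ.write(header)
        spacing = {}
        for g in order:
            others = tuple(h for h in order if h != g)
            cross = [profile_sequence_set(genomes[g], dbs[h]) for h in others]
            spec = call_specific_regions(labelings[g], profiles[g], cross,
                                         config.criteria)
            spec.to_bed(out / f"{g}.specific.bed")
            spec_summ.write(summary_row("specific", g, spec, profiles[g]))
            if g in annotations:
                genic = call_genic_specific_regions(spec, annotations[g],
                                                    config.criteria.min_length)
                genic.to_bed(out / f"{g}.genic_specific.bed")
                genic_summ.write(summary_row("genic_specific", g, genic, profiles[g]))
            try:
                sp = spacing_stats(spec)
                spacing[g] = {"n_regions": sp.n_regions, "mean_gap": sp.mean_gap,
                              "sd_gap": sp.sd_gap, "dispersion": sp.dispersion}
            except ValueError as exc:
                spacing[g] = {"error": str(exc)}
        spec_summ.close()
        genic_summ.close()
        (out / "spacing.json").write_text(json.dumps(spacing, indent=2) + "\n")

    # annotation-category overlap of unaligned regions (reference-centric)
    if annotations:
        with open(out / "unaligned_annotation.tsv", "w") as fh:
            fh.write("focal\tother\tcds\tutr5\tutr3\tnoncoding_exon\tmrna\n")
            for (g, h), bed in pair_un.items():
                if g not in annotations:
                    continue
                cats = annotate_overlap(IntervalSet.from_bed(bed), annotations[g])
                fh.write(f"{g}\t{h}\t{cats['cds']}\t{cats['utr5']}\t{cats['utr3']}"
                         f"\t{cats['noncoding_exon']}\t{cats['mrna']}\n")

    manifest.save(config)
    return out


__all__ = ["RunConfig", "GenomeInputs", "PipelineError", "run_pipeline"]
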