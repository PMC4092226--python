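"""End-to-end orchestration: simulate/load -> preprocess -> annotate ->
target scan -> summary, with all artifacts written as plain-text files.

The pipeline is deterministic under a fixed config (including its seed):
rerunning produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import io as oio
from .annotate import AnnotateConfig, AnnotationResult, ReferenceSet, annotate_tags
from .fold import mfe_fold
from .preprocess import (FilterReport, PreprocessConfig, length_histogram,
                         preprocess_reads)
from .simlib import SimConfig, SimDataset, make_utr, simulate_dataset
from .target import UtrRecord, find_targets, rank_targets
from .seq import to_rna

log = logging.getLogger("ovamir")

__all__ = ["PipelineConfig", "RunSummary", "run_pipeline", "write_outputs"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds in one (YAML round-trippable) object."""

    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    run_target: bool = True
    target_flank: int = 15
    target_mfe_max: float = 0.0
    utr_site_mirs: int = 4
    seed: int = 42
    outdir: str = "ovamir_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            for key in ("length_mode_mir", "length_mode_pirna"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        pre = d.pop("preprocess", {})
        if isinstance(pre, dict):
            pre = PreprocessConfig(**pre)
        ann = d.pop("annotate", {})
        if isinstance(ann, dict):
            ann = AnnotateConfig(**ann)
        return cls(sim=sim, preprocess=pre, annotate=ann, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunSummary:
    """Headline accounting of one pipeline run."""

    filter_report: FilterReport
    group_counts: dict[int, int]
    n_unclassified: int
    n_known: int
    n_novel: int
    n_star: int
    n_families: int
    per_mir_counts: dict[str, int]
    target_ranking: list[dict]
    config_hash: str
    seed: int

    def to_json(self) -> str:
        d = {
            "filter_report": {k: v for k, v in
                              dataclasses.asdict(self.filter_report).items()},
            "group_counts": {str(k): v for k, v in sorted(self.group_counts.items())},
            "n_unclassified": self.n_unclassified,
            "n_known": self.n_known,
            "n_novel": self.n_novel,
            "n_star": self.n_star,
            "n_families": self.n_families,
            "per_mir_counts": dict(sorted(self.per_mir_counts.items())),
            "target_ranking": self.target_ranking,
            "config_hash": self.config_hash,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig,
                 dataset: SimDataset | None = None
                 ) -> tuple[RunSummary, dict]:
    """Run the full analysis; returns (summary, artifacts dict).

    When no dataset is passed, one is simulated from ``config.sim`` with
    ``config.seed``.  Artifacts hold the in-memory intermediates
    (dataset, tags, annotation, targets) for writing or inspection.
    """
    if dataset is None:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        log.info("simulate: %d reads, %d+%d planted miRNA loci",
                 sim_cfg.read_total, sim_cfg.n_known, sim_cfg.n_novel)
        dataset = simulate_dataset(sim_cfg)
    tags, report = preprocess_reads(dataset.reads, config.preprocess,
                                    dataset.contaminants)
    log.info("preprocess: %d raw -> %d clean reads in %d tags",
             report.raw_reads, report.post_copy_reads, report.post_copy_tags)
    refset = ReferenceSet.from_planted(dataset.genome, dataset.planted)
    annotation = annotate_tags(tags, refset, config.annotate)
    log.info("annotate: groups %s, %d unclassified",
             annotation.group_counts, len(annotation.unclassified))

    target_ranking: list[dict] = []
    targets = []
    if config.run_target:
        utr_id, utr_seq = make_utr(dataset.planted, seed=config.seed,
                                   site_mirs=config.utr_site_mirs)
        utr = UtrRecord(id=utr_id, seq=utr_seq, note="simulated 3'-UTR")
        mirnas = {p.name: p.mature_seq for p in dataset.planted if p.known}
        targets = find_targets(mirnas, utr, flank=config.target_flank,
                               mfe_max=config.target_mfe_max)
        for s in rank_targets(targets):
            target_ranking.append({
                "mirna": s.mirna_name, "start": s.utr_start, "end": s.utr_end,
                "seed_class": s.seed_class, "mfe": round(s.duplex_mfe, 2)})
        log.info("target: %d sites for %d miRNAs", len(targets),
                 len(target_ranking))

    summary = RunSummary(
        filter_report=report,
        group_counts=annotation.group_counts,
        n_unclassified=len(annotation.unclassified),
        n_known=len(annotation.known_calls),
        n_novel=len(annotation.novel_calls),
        n_star=len(annotation.star_calls),
        n_families=len(annotation.family_map),
        per_mir_counts={c.assigned_name: c.count for c in annotation.calls
                        if c.status in ("known", "star")},
        target_ranking=target_ranking,
        config_hash=config.config_hash(),
        seed=config.seed,
    )
    artifacts = {"dataset": dataset, "tags": tags, "report": report,
                 "refset": refset, "annotation": annotation,
                 "targets": targets}
    return summary, artifacts


def write_outputs(summary: RunSummary, artifacts: dict, outdir) -> dict[str, str]:
    """Write every artifact as a schema-stable plain-text file.

    Empty runs still produce valid, header-carrying files.  Returns the
    {name: path} map of what was written.
    """
    outdir = oio.ensure_dir(outdir)
    ann: AnnotationResult = artifacts["annotation"]
    tags = artifacts["tags"]
    paths: dict[str, str] = {}

    def p(name):
        paths[name] = f"{outdir}/{name}"
        return paths[name]

    oio.write_tag_fasta(p("tags.fasta"), tags)
    oio.write_tsv(p("tags.tsv"), pd.DataFrame(
        [(t.id, t.seq, t.count) for t in tags],
        columns=["tag_id", "seq", "count"]))
    oio.write_tsv(p("filter_report.tsv"), summary.filter_report.to_frame())
    reads_hist, unique_hist = length_histogram(tags)
    oio.write_tsv(p("length_histogram.tsv"), pd.DataFrame(
        {"length": list(reads_hist), "reads": list(reads_hist.values()),
         "unique_tags": list(unique_hist.values())}))

    for status, fname in (("known", "known.fasta"),
                          ("novel-candidate", "novel.fasta"),
                          ("star", "star.fasta")):
        calls = [c for c in ann.calls if c.status == status]
        oio.write_fasta(p(fname), (
            (f"{c.assigned_name}|{c.tag_id}|count={c.count}|group={c.group}",
             to_rna(c.seq)) for c in calls))

    bed_rows = []
    for profile in ann.profiles:
        for hit in profile.hits_genome:
            bed_rows.append((hit.contig, hit.start, hit.end, profile.tag_id,
                             profile.count, hit.strand))
    oio.write_bed6(p("genome_hits.bed"), bed_rows)

    oio.write_tsv(p("mir_calls.tsv"), pd.DataFrame(
        [(c.tag_id, to_rna(c.seq), c.count, c.group, c.status, c.assigned_name,
          c.family, c.arm) for c in ann.calls],
        columns=["tag_id", "seq", "count", "group", "status", "assigned_name",
                 "family", "arm"]))

    with open(p("precursor_folds.txt"), "w") as fh:
        refset = artifacts["refset"]
        for name in sorted(refset.species_precursor):
            fr = mfe_fold(refset.species_precursor[name])
            fh.write(f">{name}\n{fr.to_vienna()}\n")

    oio.write_tsv(p("targets.tsv"), pd.DataFrame(
        [(s.mirna_name, s.utr_start, s.utr_end, s.seed_class,
          round(s.duplex_mfe, 2)) for s in artifacts.get("targets", [])],
        columns=["mirna", "start", "end", "seed_class", "mfe"]))

    with open(p("summary.json"), "w") as fh:
        fh.write(summary.to_json() + "\n")
    return paths
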