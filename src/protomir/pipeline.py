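"""End-to-end orchestration: simulate -> clean -> annotate -> novel ->
differential expression -> targets, with per-stage TSV outputs."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate, dem, hairpin, preprocess, simdata, target
from .thermo import get_engine

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "protomir_run"
    sim: simdata.SimParams = field(default_factory=simdata.SimParams)
    min_len: int = 18
    max_len: int = 30
    max_hits: int = 25
    fold_engine: str = "auto"
    hairpin: hairpin.HairpinThresholds = field(
        default_factory=hairpin.HairpinThresholds)
    fc_cut: float = 1.0
    p_cut: float = 0.01
    tpm_floor: float = dem.TPM_FLOOR
    target_max_score: float = 4.0
    mfe_ratio_min: float = 0.75

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if key == "sim":
                cfg.sim = simdata.SimParams(**val)
            elif key == "hairpin":
                cfg.hairpin = hairpin.HairpinThresholds(**val)
            elif hasattr(cfg, key):
                setattr(cfg, key, val)
            else:
                raise KeyError(f"unknown config key {key!r}")
        return cfg


@dataclass
class RunSummary:
    outdir: Path
    bundle: simdata.ReferenceBundle
    libraries: dict[str, simdata.SimulatedLibrary]
    ledgers: dict[str, preprocess.ReadLedger]
    profiles: dict[str, preprocess.LibraryProfile]
    annotations: dict[str, annotate.AnnotationTable]
    known_catalog: list[annotate.MirnaRecord]
    novel_catalog: list[hairpin.HairpinCandidate]
    dem_records: list[dem.DemRecord]
    target_hits: list[target.TargetHit]
    targetless: list[str]


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute every stage on a freshly simulated experiment.

    Outputs (ledger, annotation summary, catalogs, DE table, target
    hits, effective config) are written under ``config.outdir``; the
    whole run is deterministic for a fixed ``config.sim.seed``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    engine = get_engine(config.fold_engine)

    log.info("simulating reference bundle (seed=%d)", config.sim.seed)
    bundle = simdata.generate_reference(config.sim)
    simdata.write_bundle(bundle, outdir / "reference")

    libraries, ledgers, profiles, annotations = {}, {}, {}, {}
    for cond in simdata.CONDITIONS:
        lib = simdata.simulate_library(bundle, config.sim, cond)
        simdata.write_fastq(lib, outdir / f"reads_{cond}.fastq")
        profile, ledger = preprocess.clean_reads(
            ((seq, qual) for _rid, seq, qual in lib.reads),
            adapter3=config.sim.adapter3, adapter5=config.sim.adapter5,
            min_len=config.min_len, max_len=config.max_len, condition=cond,
        )
        log.info("%s: %d reads -> %d clean (%.2f%%), %d unique",
                 cond, ledger.total_reads, ledger.clean_reads,
                 ledger.clean_pct, profile.unique_count)
        preprocess.write_collapsed_fasta(profile, outdir / f"clean_{cond}.fa")
        table = annotate.classify(profile, bundle, max_hits=config.max_hits)
        libraries[cond], ledgers[cond] = lib, ledger
        profiles[cond], annotations[cond] = profile, table
    preprocess.write_ledger_tsv(ledgers, outdir / "ledger.tsv")
    annotate.write_annotation_tsv(annotations, outdir / "annotation.tsv")

    known_catalog = annotate.identify_known_mirnas(profiles, bundle.mature_mirnas)
    annotate.write_mirna_catalog(known_catalog, outdir / "known_mirnas.tsv")
    novel_catalog = hairpin.find_novel_mirnas(
        annotations, profiles, bundle.genome, engine,
        config.hairpin, config.max_hits,
    )
    hairpin.write_novel_catalog(novel_catalog, outdir / "novel_mirnas.tsv")
    log.info("catalogs: %d known, %d novel", len(known_catalog), len(novel_catalog))

    n1 = ledgers["calli"].clean_reads
    n2 = ledgers["protoplasts"].clean_reads
    records = dem.call_dems(
        list(known_catalog) + list(novel_catalog), n1, n2,
        fc_cut=config.fc_cut, p_cut=config.p_cut, floor=config.tpm_floor,
    )
    dem.write_dem_tsv(records, outdir / "dem.tsv")
    n_up = sum(r.status == "up" for r in records)
    n_down = sum(r.status == "down" for r in records)
    log.info("differential expression: %d up, %d down", n_up, n_down)

    dem_names = {r.name for r in records if r.status != "unchanged"}
    mirna_seqs: dict[str, str] = {}
    for rec in known_catalog:
        if rec.name in dem_names:
            mirna_seqs[rec.name] = rec.sequence
    for cand in novel_catalog:
        if cand.name in dem_names:
            mirna_seqs[cand.name] = cand.mature
    hits: list[target.TargetHit] = []
    targetless: list[str] = []
    if mirna_seqs:
        hits, targetless = target.predict_targets(
            mirna_seqs, bundle.transcripts, engine,
            max_score=config.target_max_score,
            mfe_ratio_min=config.mfe_ratio_min,
        )
    target.write_hits_tsv(hits, outdir / "target_hits.tsv")
    log.info("targets: %d hits; %d DEMs without targets", len(hits), len(targetless))

    return RunSummary(
        outdir=outdir, bundle=bundle, libraries=libraries, ledgers=ledgers,
        profiles=profiles, annotations=annotations,
        known_catalog=known_catalog, novel_catalog=novel_catalog,
        dem_records=records, target_hits=hits, targetless=targetless,
    )
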