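"""End-to-end catalogue construction with a per-candidate audit manifest.

``build_catalogue`` is the in-memory core: per-tool ingestion (with per-tool
score gates), gap-free re-anchoring, the reliability rule for the
expression-based predictor, 100-nt overlap deduplication, structure triage of
50-nt-extended loci, annotation-conflict removal, read-profile verification
over all libraries, then cluster calling and family assignment.
``run_pipeline`` wraps it in file I/O driven by a single YAML config.

The manifest records, per stage, input / kept / removed counts (always
conserved: kept + removed = input) and exactly one removal rule per removed
candidate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .catalogue import (CatalogueEntry, assign_all_families, call_clusters,
                        cluster_composition, summarize_catalogue)
from .consensus import (CandidatePrediction, FilterLog, HomologyHit, MergedLocus,
                        Triage, anchor_gap_free, candidates_from_gff3,
                        deduplicate_overlaps, extension_triage,
                        remove_annotation_conflicts, reliability_filter)
from .expression import Verdict, verify_locus
from .io import BedRecord, Gff3Record, read_bed, read_fasta, read_gff3, write_gff3
from .sequtils import revcomp

DEFAULT_TOOL_MIN_SCORE = 5.0


@dataclass
class PipelineConfig:
    """One place for every input path and every threshold of the cascade."""

    # inputs
    genome_fasta: str = ""
    tool_predictions: dict[str, str] = field(default_factory=dict)  # tool -> GFF3
    read_beds: dict[str, str] = field(default_factory=dict)         # library -> BED
    annotation_gff3: str | None = None
    mirbase_hits_tsv: str | None = None
    structure_hits_tsv: str | None = None
    reference_families_tsv: str | None = None
    reference_fasta: str | None = None
    outdir: str = "mirforge_out"
    # trimming
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_quality: int = 20
    min_length: int = 15
    # consensus cascade
    score_threshold: float = 7.0
    reliability_max_mismatch: int = 1
    overlap_window: int = 100
    extension_flank: int = 50
    anchor_max_mismatches: int = 1
    homology_min_span: float = 0.9
    homology_max_gaps: int = 0
    homology_cutoff: float = 1e-7
    tool_min_score: dict[str, float] = field(default_factory=dict)
    expression_tools: tuple[str, ...] = ("mirdeep_like",)
    # expression verification
    profile_flank: int = 20
    min_reads: int = 5
    min_sharpness: float = 0.6
    max_gap_coverage_fraction: float = 0.1
    max_flank_coverage_fraction: float = 0.1
    max_blocks: int = 2
    # catalogue structure
    cluster_max_gap: int = 10_000
    family_min_identity: float = 0.9
    require_seed_identity: bool = True
    # enrichment
    fdr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.homology_min_span <= 1, "homology_min_span"),
            (0 < self.fdr < 1, "fdr"),
            (self.min_length >= 1, "min_length"),
            (self.overlap_window >= 0, "overlap_window"),
            (self.cluster_max_gap >= 0, "cluster_max_gap"),
            (0 <= self.family_min_identity <= 1, "family_min_identity"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"config field {name} outside its valid range")

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "expression_tools" in raw and raw["expression_tools"] is not None:
            raw["expression_tools"] = tuple(raw["expression_tools"])
        return cls(**raw)


@dataclass
class StageCount:
    stage: str
    n_input: int
    n_kept: int
    n_removed: int
    removal_reasons: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.n_kept + self.n_removed != self.n_input:
            raise AssertionError(f"stage {self.stage}: kept+removed != input")


@dataclass
class RunManifest:
    stages: list[StageCount] = field(default_factory=list)
    audit: dict[str, str] = field(default_factory=dict)  # removed id -> rule
    config_hash: str = ""
    version: str = __version__

    def add_stage(self, stage: str, n_input: int, n_kept: int,
                  log: FilterLog | None = None, extra_reasons: dict[str, int] | None = None) -> None:
        reasons: dict[str, int] = dict(extra_reasons or {})
        if log is not None:
            for cid, reason in log.removed.items():
                self.audit.setdefault(cid, reason)
                reasons[reason] = reasons.get(reason, 0) + 1
        sc = StageCount(stage, n_input, n_kept, n_input - n_kept, reasons)
        sc.check()
        self.stages.append(sc)

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "config_hash": self.config_hash,
            "stages": [asdict(s) for s in self.stages],
            "audit": dict(sorted(self.audit.items())),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    entries: list[CatalogueEntry]
    merged: list[MergedLocus]
    verdicts: dict[str, Verdict]
    clusters: list
    family_of: dict[str, str]
    compositions: dict[int, str]
    summary: object
    manifest: RunManifest


def _read_hits_tsv(path: str | Path) -> list[HomologyHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cid, rid, qlen, span, mm, gaps, sig = line.split("\t")
            hits.append(HomologyHit(cid, rid, int(qlen), int(span),
                                    int(mm), int(gaps), float(sig)))
    return hits


def _read_structure_tsv(path: str | Path) -> dict[str, Triage]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            lid, verdict = line.split("\t")
            out[lid] = Triage(verdict)
    return out


def build_catalogue(
    genome: dict[str, str],
    per_tool_candidates: dict[str, list[CandidatePrediction]],
    libraries: dict[str, list[BedRecord]],
    cfg: PipelineConfig,
    annotation: list[Gff3Record] = (),
    mirbase_hits: list[HomologyHit] = (),
    structure_hits: dict[str, Triage] | None = None,
    reference: tuple[dict[str, str], dict[str, str]] | None = None,
) -> PipelineResult:
    """Run the full cascade in memory and return catalogue plus manifest."""
    manifest = RunManifest(config_hash=cfg.content_hash())
    structure_hits = structure_hits or {}

    # stage: ingestion with per-tool score gates
    pooled: list[CandidatePrediction] = []
    n_raw = 0
    gate_removed: dict[str, int] = {}
    for tool in sorted(per_tool_candidates):
        cands = per_tool_candidates[tool]
        n_raw += len(cands)
        gate = cfg.tool_min_score.get(tool, DEFAULT_TOOL_MIN_SCORE)
        if tool in cfg.expression_tools:
            gate = cfg.tool_min_score.get(tool, 0.0)  # its own >=7 rule applies later
        kept = [c for c in cands if c.score >= gate]
        for c in cands:
            if c.score < gate:
                manifest.audit.setdefault(c.id, f"tool_score_gate:{tool}")
        gate_removed[f"tool_score_gate:{tool}"] = len(cands) - len(kept)
        pooled.extend(kept)
    manifest.add_stage("ingest", n_raw, len(pooled),
                       extra_reasons={k: v for k, v in gate_removed.items() if v})

    # stage: gap-free re-anchoring
    log = FilterLog()
    anchored = anchor_gap_free(pooled, genome, cfg.anchor_max_mismatches, log)
    manifest.add_stage("anchor_gap_free", len(pooled), len(anchored), log)

    # stage: reliability rule for the expression-based predictor
    log = FilterLog()
    reliable: list[CandidatePrediction] = []
    rescue_ids = set()
    for cand in anchored:
        if cand.tool in cfg.expression_tools:
            keep, reason = reliability_filter(cand, mirbase_hits,
                                              cfg.score_threshold,
                                              cfg.reliability_max_mismatch)
            if not keep:
                log.drop(cand.id, "unreliable")
                continue
            if reason == "homology_rescue":
                rescue_ids.add(cand.id)
        reliable.append(cand)
    manifest.add_stage("reliability_filter", len(anchored), len(reliable), log)

    # stage: 100-nt overlap deduplication
    merged = deduplicate_overlaps(reliable, cfg.overlap_window, frozenset(rescue_ids))
    n_merged_away = len(reliable) - len(merged)
    manifest.add_stage("deduplicate_overlaps", len(reliable), len(merged),
                       extra_reasons={"merged_into_locus": n_merged_away} if n_merged_away else {})

    # stage: structure triage of 50-nt-extended loci
    log = FilterLog()
    triaged = []
    for locus in merged:
        verdict = extension_triage(locus, structure_hits, cfg.extension_flank, log)
        locus.triage = verdict
        if verdict is not Triage.OTHER_NCRNA_HIT:
            triaged.append(locus)
    manifest.add_stage("extension_triage", len(merged), len(triaged), log)

    # stage: annotation conflicts
    log = FilterLog()
    clean = remove_annotation_conflicts(triaged, list(annotation), log=log)
    manifest.add_stage("annotation_conflicts", len(triaged), len(clean), log)

    # stage: read-profile verification (alignments pre-binned by contig)
    log = FilterLog()
    entries: list[CatalogueEntry] = []
    verdicts: dict[str, Verdict] = {}
    by_contig: dict[str, dict[str, list[BedRecord]]] = {}
    for lib, recs in libraries.items():
        binned: dict[str, list[BedRecord]] = {}
        for rec in recs:
            binned.setdefault(rec.interval.contig, []).append(rec)
        by_contig[lib] = binned
    for locus in clean:
        window = locus.group_span
        local_libs = {lib: by_contig[lib].get(window.contig, [])
                      for lib in by_contig}
        best, _ = verify_locus(
            window, local_libs, locus_id=locus.id,
            flank=cfg.profile_flank, min_reads=cfg.min_reads,
            min_sharpness=cfg.min_sharpness,
            max_gap_coverage_fraction=cfg.max_gap_coverage_fraction,
            max_flank_coverage_fraction=cfg.max_flank_coverage_fraction,
            max_blocks=cfg.max_blocks,
        )
        verdicts[locus.id] = best.verdict
        if best.verdict is Verdict.VERIFIED:
            m5 = _fetch(genome, best.mature5p) if best.mature5p else ""
            m3 = _fetch(genome, best.mature3p) if best.mature3p else ""
            entries.append(CatalogueEntry(
                id=locus.id, precursor=window,
                mature5p_seq=m5, mature3p_seq=m3,
                mature5p=best.mature5p, mature3p=best.mature3p,
                status="verified",
            ))
        elif best.verdict is Verdict.NO_EXPRESSION:
            conservation_support = bool(set(locus.supporting_tools) - set(cfg.expression_tools))
            if conservation_support or locus.rescue:
                entries.append(CatalogueEntry(
                    id=locus.id, precursor=window, status="putative_unexpressed",
                    mature5p_seq=_fetch(genome, locus.interval),
                ))
            else:
                log.drop(locus.id, "no_expression_unsupported")
        else:
            log.drop(locus.id, best.verdict.value)
    manifest.add_stage("expression_verification", len(clean), len(entries), log)

    # catalogue structure
    clusters = call_clusters(entries, cfg.cluster_max_gap)
    if reference is not None:
        families, ref_seqs = reference
    else:
        families, ref_seqs = {}, {}
    family_of = assign_all_families(entries, families, ref_seqs,
                                    cfg.family_min_identity, cfg.require_seed_identity)
    compositions = {i: cluster_composition(c, family_of) for i, c in enumerate(clusters)}
    for c, comp in zip(clusters, compositions.values()):
        c.composition = comp
    summary = summarize_catalogue(entries, clusters, family_of)
    return PipelineResult(entries, merged, verdicts, clusters, family_of,
                          compositions, summary, manifest)


def synthetic_inputs(sim):
    """Bundle a simulated study into build_catalogue inputs.

    Returns (per_tool_candidates, libraries, mirbase_hits, reference, status).
    Homology hits against the reference mature set are emitted for candidates
    of the expression-based predictor at known-family loci (the rescue path),
    mirroring what an external alignment of hairpins to a curated database
    would return.
    """
    from .simulate import (reference_catalogue, simulate_read_alignments,
                           simulate_tool_predictions)

    preds = simulate_tool_predictions(sim)
    per_tool = {t: candidates_from_gff3(recs, tool=t) for t, recs in preds.items()}
    libraries, status = simulate_read_alignments(sim)
    reference = reference_catalogue(sim)
    by_id = {t.id: t for t in sim.truth}
    hits: list[HomologyHit] = []
    for cands in per_tool.values():
        for c in cands:
            tid = c.id.split(":", 1)[1]
            t = by_id.get(tid)
            if t is not None and t.family_label != "novel":
                qlen = len(c.hairpin_sequence)
                hits.append(HomologyHit(c.id, f"ref-{t.family_label}-{t.id}",
                                        qlen, qlen, 0, 0, 1e-30))
    return per_tool, libraries, hits, reference, status


def _fetch(genome: dict[str, str], iv) -> str:
    seq = genome[iv.contig][iv.start:iv.end]
    return revcomp(seq) if iv.strand == "-" else seq


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-driven wrapper: read all configured inputs, write all outputs.

    Outputs: catalogue GFF3, per-locus verdict TSV, cluster TSV, family TSV,
    summary TSV and the manifest JSON, all under ``cfg.outdir``.  Re-running
    with the same config and inputs writes byte-identical files.
    """
    genome = read_fasta(cfg.genome_fasta)
    per_tool = {
        tool: candidates_from_gff3(read_gff3(path), tool=tool)
        for tool, path in sorted(cfg.tool_predictions.items())
    }
    libraries = {lib: list(read_bed(path)) for lib, path in sorted(cfg.read_beds.items())}
    annotation = list(read_gff3(cfg.annotation_gff3)) if cfg.annotation_gff3 else []
    mirbase_hits = _read_hits_tsv(cfg.mirbase_hits_tsv) if cfg.mirbase_hits_tsv else []
    structure_hits = (_read_structure_tsv(cfg.structure_hits_tsv)
                      if cfg.structure_hits_tsv else {})
    reference = None
    if cfg.reference_fasta and cfg.reference_families_tsv:
        ref_seqs = read_fasta(cfg.reference_fasta)
        fam = {}
        with open(cfg.reference_families_tsv) as fh:
            for line in fh:
                rid, label = line.rstrip("\n").split("\t")
                fam[rid] = label
        reference = (fam, ref_seqs)

    result = build_catalogue(genome, per_tool, libraries, cfg,
                             annotation, mirbase_hits, structure_hits, reference)

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for e in sorted(result.entries, key=lambda e: (e.precursor.contig, e.precursor.start)):
        records.append(Gff3Record(e.precursor, "mirforge", "pre_miRNA", attributes={
            "ID": e.id, "status": e.status, "family": e.family,
        }))
        if e.mature5p:
            records.append(Gff3Record(e.mature5p, "mirforge", "miRNA",
                                      attributes={"ID": e.id + "-5p", "Parent": e.id}))
        if e.mature3p:
            records.append(Gff3Record(e.mature3p, "mirforge", "miRNA",
                                      attributes={"ID": e.id + "-3p", "Parent": e.id}))
    write_gff3(records, outdir / "catalogue.gff3")
    with open(outdir / "verdicts.tsv", "w") as fh:
        fh.write("locus_id\tverdict\n")
        for lid in sorted(result.verdicts):
            fh.write(f"{lid}\t{result.verdicts[lid].value}\n")
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("contig\tstart\tend\tn_members\tmembers\tcomposition\n")
        for c in result.clusters:
            fh.write(f"{c.contig}\t{c.span.start}\t{c.span.end}\t"
                     f"{len(c.member_ids)}\t{','.join(c.member_ids)}\t{c.composition}\n")
    with open(outdir / "families.tsv", "w") as fh:
        fh.write("entry_id\tfamily\n")
        for eid in sorted(result.family_of):
            fh.write(f"{eid}\t{result.family_of[eid]}\n")
    s = result.summary
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("n_mirnas\tn_clusters\tn_mirnas_in_clusters\t"
                 "n_known_families\tn_known_family_members\t"
                 "n_novel_families\tn_novel_family_members\n")
        fh.write(f"{s.n_mirnas}\t{s.n_clusters}\t{s.n_mirnas_in_clusters}\t"
                 f"{s.n_known_families}\t{s.n_known_family_members}\t"
                 f"{s.n_novel_families}\t{s.n_novel_family_members}\n")
    (outdir / "manifest.json").write_text(result.manifest.to_json() + "\n")
    return result


def summarize_run(manifest: RunManifest) -> str:
    """Human-readable per-stage attrition report (counts and percentages)."""
    lines = [f"mirforge {manifest.version}  config {manifest.config_hash}"]
    for s in manifest.stages:
        pct = 100.0 * s.n_kept / s.n_input if s.n_input else 0.0
        lines.append(f"{s.stage}: {s.n_input} in, {s.n_kept} kept ({pct:.1f}%), "
                     f"{s.n_removed} removed")
        for reason, count in sorted(s.removal_reasons.items()):
            lines.append(f"    {reason}: {count}")
    return "\n".join(lines)
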