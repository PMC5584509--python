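"""Synthetic small-RNA study generator with planted ground truth.

Emulates, at desk scale, the inputs of a multi-predictor miRNA annotation
study: a genome with planted hairpin loci (a ~60-120 nt precursor holding two
~22 nt mature arms around a read-free loop), decoy loci, per-tool candidate
predictions with jitter/false calls/scores, collapsed small-RNA read
alignments with the characteristic rectangular two-block profile, orthologous
3'-UTR alignments with planted conserved seed sites, and a species x miRNA
expression matrix whose presence/absence pattern evolves on a known tree.

No RNA folding is simulated: hairpins are built as a mature arm plus a noisy
reverse complement, which is all the downstream pipeline ever inspects
(thermodynamic plausibility was the job of the external predictors whose
output formats we emulate).

Every generator derives its random stream from ``config.seed`` plus a fixed
stage offset, so outputs are byte-identical under a fixed config regardless
of call order.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from Bio import Phylo

from .intervals import GenomicInterval
from .io import BedRecord, Gff3Record, write_bed, write_fasta, write_gff3

from .sequtils import revcomp

_BASES = np.array(list("ACGT"))

# (name, call type, mean score of true calls, mean score of false calls)
DEFAULT_TOOLS: tuple[tuple[str, str, float, float], ...] = (
    ("mirdeep_like", "precursor", 10.0, 3.0),
    ("infernal_like", "precursor", 10.0, 3.0),
    ("gorap_like", "precursor", 10.0, 3.0),
    ("blast_like", "mature", 10.0, 3.0),
    ("cid_like", "precursor", 10.0, 3.0),
)

# ultrametric (every leaf at depth 4): presence evolution is clock-like, the
# regime where average-linkage clustering of the presence matrix is consistent
DEFAULT_TREE = "((((sp1:1,sp2:1):1,(sp3:1,sp4:1):1):1,(sp5:2,sp6:2):1):1,sp7:4);"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study's default conditions."""

    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 1_500_000
    n_true_mirnas: int = 50
    n_decoys: int = 25
    hairpin_len_range: tuple[int, int] = (60, 120)
    mature_len: int = 22
    loop_len_range: tuple[int, int] = (10, 15)
    cluster_spec: list[tuple[int, int]] = field(default_factory=list)
    min_locus_separation: int = 15_000  # singletons never chain at the 10-kb rule
    tool_sensitivity: float = 0.8
    tool_fp_rate: float = 0.1
    positional_jitter_sd: float = 0.0
    tools: tuple[tuple[str, str, float, float], ...] = DEFAULT_TOOLS
    score_sd_true: float = 2.0
    score_sd_false: float = 1.5
    # expression
    n_libraries: int = 2
    read_depth_mean: float = 30.0
    read_start_jitter: int = 2
    expressed_fraction: float = 0.8
    extended_mapping_fraction: float = 0.05
    # families
    known_family_fraction: float = 0.45
    # UTR / enrichment
    n_genes: int = 500
    utr_len: int = 200
    utr_species: tuple[str, ...] = ("nfu", "dre", "mmu", "hsa")
    conserved_species: tuple[str, ...] = ("nfu", "dre")
    utr_mutation_rate: float = 0.05
    n_de_genes: int = 100
    site_base_rate: float = 0.12
    enrichment_odds: float = 1.0
    n_target_mirnas: int = 5
    # species expression / phylogeny
    n_species: int = 7
    planted_tree: str = DEFAULT_TREE
    presence_loss_prob: float = 0.15
    presence_gain_prob: float = 0.02

    def __post_init__(self) -> None:
        for name in ("tool_sensitivity", "tool_fp_rate", "expressed_fraction",
                     "extended_mapping_fraction", "known_family_fraction",
                     "site_base_rate", "utr_mutation_rate",
                     "presence_loss_prob", "presence_gain_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.hairpin_len_range
        if not (40 <= lo <= hi <= 200):
            raise ValueError(f"hairpin_len_range {self.hairpin_len_range} outside [40, 200]")
        min_hp = (self.mature_len * 2 + self.loop_len_range[0] + 4)
        if hi < min_hp:
            raise ValueError("hairpin_len_range cannot hold two mature arms plus loop")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("hairpin_len_range", "loop_len_range", "utr_species",
                    "conserved_species"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "tools" in raw and raw["tools"] is not None:
            raw["tools"] = tuple(tuple(t) for t in raw["tools"])
        if "cluster_spec" in raw and raw["cluster_spec"] is not None:
            raw["cluster_spec"] = [tuple(c) for c in raw["cluster_spec"]]
        return cls(**raw)


@dataclass
class PlantedMiRNA:
    """Ground-truth record of one planted hairpin locus."""

    id: str
    precursor: GenomicInterval
    mature5p: GenomicInterval
    mature3p: GenomicInterval
    mature5p_seq: str
    mature3p_seq: str
    family_label: str  # known family name or "novel"
    cluster_id: str | None = None

    def validate(self) -> None:
        if not (self.precursor.contains(self.mature5p) and self.precursor.contains(self.mature3p)):
            raise AssertionError("mature arms not nested in precursor")
        if self.mature5p.gap_to(self.mature3p) < 4:
            raise AssertionError("arm gap < 4 nt")
        rc = revcomp(self.mature5p_seq)
        mm = sum(a != b for a, b in zip(rc, self.mature3p_seq))
        if len(rc) != len(self.mature3p_seq) or mm > 3:
            raise AssertionError("3p arm not a (<=3-mismatch) reverse complement of 5p")


@dataclass
class SimulatedGenome:
    """Bundle returned by :func:`simulate_genome`."""

    config: SimulationConfig
    contigs: dict[str, str]
    truth: list[PlantedMiRNA]
    decoys: list[GenomicInterval]

    def fetch(self, iv: GenomicInterval) -> str:
        seq = self.contigs[iv.contig][iv.start:iv.end]
        return revcomp(seq) if iv.strand == "-" else seq


_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASE_CODES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    if n_mut == 0:
        return seq
    seq = list(seq)
    for pos in rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False):
        alts = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alts[rng.integers(0, 3)]
    return "".join(seq)


def _build_hairpin(rng: np.random.Generator, cfg: SimulationConfig):
    """Sense-strand precursor sequence plus arm offsets within it."""
    lo, hi = cfg.hairpin_len_range
    m = cfg.mature_len
    loop = int(rng.integers(cfg.loop_len_range[0], cfg.loop_len_range[1] + 1))
    min_len = max(lo, 2 * m + loop + 4)
    plen = int(rng.integers(min_len, hi + 1))
    slack = plen - (2 * m + loop)
    lead = int(rng.integers(2, max(3, slack - 1))) if slack > 4 else 2
    lead = min(lead, slack - 2)
    tail = slack - lead
    m5p = _random_seq(rng, m)
    n_mm = int(rng.integers(0, 4))
    m3p = _mutate(rng, revcomp(m5p), n_mm)
    seq = _random_seq(rng, lead) + m5p + _random_seq(rng, loop) + m3p + _random_seq(rng, tail)
    assert len(seq) == plen
    return seq, lead, lead + m, lead + m + loop, lead + m + loop + m, m5p, m3p


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Plant hairpin and decoy loci on random contigs.

    Clustered loci are laid out per ``cluster_spec`` (member count, intra-gap);
    all other spacings are at least ``min_locus_separation`` so that only the
    declared clusters chain at the 10-kb rule.  Raises a sizing error when the
    contigs cannot host the requested loci.
    """
    cfg = config
    rng = cfg.rng(1)
    n_clustered = sum(k for k, _ in cfg.cluster_spec)
    if n_clustered > cfg.n_true_mirnas:
        raise ValueError("cluster_spec members exceed n_true_mirnas")

    # build per-locus hairpins first (fixed draw order => determinism)
    hairpins = [_build_hairpin(rng, cfg) for _ in range(cfg.n_true_mirnas)]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(cfg.n_true_mirnas)]

    # placement units: declared clusters, then singleton loci, then decoys
    units: list[list[int]] = []
    idx = 0
    for k, _gap in cfg.cluster_spec:
        units.append(list(range(idx, idx + k)))
        idx += k
    for i in range(idx, cfg.n_true_mirnas):
        units.append([i])
    decoy_len = 80
    sep = cfg.min_locus_separation

    contig_names = [f"ctg{i + 1}" for i in range(cfg.n_contigs)]
    contigs = {name: list(_random_seq(rng, cfg.contig_length)) for name in contig_names}

    truth: list[PlantedMiRNA] = []
    decoys: list[GenomicInterval] = []
    ci = 0
    cursor = int(rng.integers(sep // 4, sep // 2))
    cluster_gaps = {u: g for u, (_, g) in zip(range(len(cfg.cluster_spec)), cfg.cluster_spec)}

    def advance(need: int) -> tuple[str, int]:
        nonlocal ci, cursor
        if cursor + need > cfg.contig_length:
            ci += 1
            if ci >= cfg.n_contigs:
                short = cursor + need - cfg.contig_length
                raise ValueError(
                    f"contigs too short to host requested loci: need {short} more nt "
                    f"on the last of {cfg.n_contigs} contigs of {cfg.contig_length} nt"
                )
            cursor = int(rng.integers(sep // 4, sep // 2))
            if cursor + need > cfg.contig_length:
                raise ValueError("contig_length smaller than a single locus span")
        return contig_names[ci], cursor

    for ui, members in enumerate(units):
        intra = cluster_gaps.get(ui, 0)
        spans = [len(hairpins[i][0]) for i in members]
        need = sum(spans) + intra * (len(members) - 1)
        contig, start = advance(need)
        pos = start
        cluster_id = f"cl{ui + 1:03d}" if len(members) > 1 else None
        for j, i in enumerate(members):
            seq, a5s, a5e, b3s, b3e, m5p, m3p = hairpins[i]
            plen = len(seq)
            strand = strands[i]
            planted = seq if strand == "+" else revcomp(seq)
            contigs[contig][pos:pos + plen] = list(planted)
            if strand == "+":
                iv5 = GenomicInterval(contig, pos + a5s, pos + a5e, "+")
                iv3 = GenomicInterval(contig, pos + b3s, pos + b3e, "+")
            else:
                iv5 = GenomicInterval(contig, pos + plen - a5e, pos + plen - a5s, "-")
                iv3 = GenomicInterval(contig, pos + plen - b3e, pos + plen - b3s, "-")
            truth.append(
                PlantedMiRNA(
                    id=f"mir{i + 1:04d}",
                    precursor=GenomicInterval(contig, pos, pos + plen, strand),
                    mature5p=iv5,
                    mature3p=iv3,
                    mature5p_seq=m5p,
                    mature3p_seq=m3p,
                    family_label="novel",
                    cluster_id=cluster_id,
                )
            )
            pos += plen + (intra if j < len(members) - 1 else 0)
        cursor = pos + sep + int(rng.integers(0, sep // 3))

    for d in range(cfg.n_decoys):
        contig, start = advance(decoy_len)
        strand = "+" if rng.random() < 0.5 else "-"
        decoys.append(GenomicInterval(contig, start, start + decoy_len, strand))
        cursor = start + decoy_len + sep + int(rng.integers(0, sep // 3))

    truth.sort(key=lambda t: (t.precursor.contig, t.precursor.start))
    # family labels: a fraction of loci match a "known" reference family
    fam_rng = cfg.rng(6)
    for t in truth:
        if fam_rng.random() < cfg.known_family_fraction:
            t.family_label = f"mir-k{int(fam_rng.integers(1, max(2, cfg.n_true_mirnas // 3))):03d}"
    return SimulatedGenome(cfg, {k: "".join(v) for k, v in contigs.items()}, truth, decoys)


def truth_to_gff3(truth: list[PlantedMiRNA], decoys: list[GenomicInterval] = ()) -> list[Gff3Record]:
    records = []
    for t in truth:
        attrs = {"ID": t.id, "family": t.family_label,
                 "mature5p_seq": t.mature5p_seq, "mature3p_seq": t.mature3p_seq}
        if t.cluster_id:
            attrs["cluster_id"] = t.cluster_id
        records.append(Gff3Record(t.precursor, "sim", "pre_miRNA", attributes=attrs))
        records.append(Gff3Record(t.mature5p, "sim", "miRNA",
                                  attributes={"ID": t.id + "-5p", "Parent": t.id}))
        records.append(Gff3Record(t.mature3p, "sim", "miRNA",
                                  attributes={"ID": t.id + "-3p", "Parent": t.id}))
    for i, d in enumerate(decoys):
        records.append(Gff3Record(d, "sim", "decoy", attributes={"ID": f"decoy{i + 1:04d}"}))
    return records


def truth_from_gff3(records) -> tuple[list[PlantedMiRNA], list[GenomicInterval]]:
    """Inverse of :func:`truth_to_gff3` (exact round-trip)."""
    pre: dict[str, Gff3Record] = {}
    arms: dict[str, dict[str, GenomicInterval]] = {}
    decoys: list[GenomicInterval] = []
    for rec in records:
        if rec.feature_type == "pre_miRNA":
            pre[rec.attributes["ID"]] = rec
        elif rec.feature_type == "miRNA":
            parent = rec.attributes["Parent"]
            arm = "5p" if rec.attributes["ID"].endswith("5p") else "3p"
            arms.setdefault(parent, {})[arm] = rec.interval
        elif rec.feature_type == "decoy":
            decoys.append(rec.interval)
    truth = []
    for pid, rec in pre.items():
        truth.append(
            PlantedMiRNA(
                id=pid,
                precursor=rec.interval,
                mature5p=arms[pid]["5p"],
                mature3p=arms[pid]["3p"],
                mature5p_seq=rec.attributes["mature5p_seq"],
                mature3p_seq=rec.attributes["mature3p_seq"],
                family_label=rec.attributes["family"],
                cluster_id=rec.attributes.get("cluster_id"),
            )
        )
    truth.sort(key=lambda t: (t.precursor.contig, t.precursor.start))
    return truth, decoys


def simulate_tool_predictions(sim: SimulatedGenome, config: SimulationConfig | None = None):
    """Per-tool candidate calls: jittered true hits plus decoy false positives.

    Tools emitting "precursor"-length calls report the hairpin interval; the
    "mature"-length tool reports the 5p arm only, mirroring how homology and
    read-based predictors differ in annotation length.  Scores of true calls
    are drawn high (mean 10) and of false calls low (mean 3), so true loci
    stochastically clear the reliability threshold of 7 while decoys rarely do.
    """
    cfg = config or sim.config
    rng = cfg.rng(2)
    out: dict[str, list[Gff3Record]] = {}
    for tool, call_type, mu_t, mu_f in cfg.tools:
        records: list[Gff3Record] = []
        for t in sim.truth:
            if rng.random() >= cfg.tool_sensitivity:
                continue
            base = t.precursor if call_type == "precursor" else t.mature5p
            jitter = (int(round(rng.normal(0, cfg.positional_jitter_sd)))
                      if cfg.positional_jitter_sd > 0 else 0)
            start = max(0, base.start + jitter)
            iv = GenomicInterval(base.contig, start, start + base.length, base.strand)
            score = max(0.1, float(rng.normal(mu_t, cfg.score_sd_true)))
            seq = sim.contigs[iv.contig][iv.start:iv.end]
            if iv.strand == "-":
                seq = revcomp(seq)
            records.append(Gff3Record(iv, tool, "miRNA_candidate", score=score,
                                      attributes={"ID": f"{tool}:{t.id}",
                                                  "hairpin_seq": seq,
                                                  "truth_id": t.id}))
        for di, d in enumerate(sim.decoys):
            if rng.random() >= cfg.tool_fp_rate:
                continue
            iv = d if call_type == "precursor" else GenomicInterval(
                d.contig, d.start, d.start + cfg.mature_len, d.strand)
            score = max(0.1, float(rng.normal(mu_f, cfg.score_sd_false)))
            seq = sim.contigs[iv.contig][iv.start:iv.end]
            if iv.strand == "-":
                seq = revcomp(seq)
            records.append(Gff3Record(iv, tool, "miRNA_candidate", score=score,
                                      attributes={"ID": f"{tool}:decoy{di + 1:04d}",
                                                  "hairpin_seq": seq,
                                                  "truth_id": f"decoy{di + 1:04d}"}))
        records.sort(key=lambda r: (r.interval.contig, r.interval.start))
        out[tool] = records
    return out


def simulate_read_alignments(sim: SimulatedGenome, config: SimulationConfig | None = None):
    """Collapsed read alignments per library, plus per-locus expression status.

    Expressed loci get two rectangular pileups: reads start within +/-2 nt of
    each mature arm's 5' end at Poisson depth, leaving the loop read-free.
    "Extended-mapping" negatives get uniform coverage across the precursor and
    50-nt flanks (the degraded-transcript signature).  The remaining loci get
    zero reads.  Returns ``(libraries, status)`` where status maps locus id to
    one of expressed / extended / silent.
    """
    cfg = config or sim.config
    rng = cfg.rng(3)
    status: dict[str, str] = {}
    for t in sim.truth:
        u = rng.random()
        if u < cfg.extended_mapping_fraction:
            status[t.id] = "extended"
        elif u < cfg.extended_mapping_fraction + (1 - cfg.extended_mapping_fraction) * cfg.expressed_fraction:
            status[t.id] = "expressed"
        else:
            status[t.id] = "silent"

    if cfg.read_start_jitter > 0:
        j = cfg.read_start_jitter
        offs = np.arange(-j, j + 1)
        off_p = np.full(2 * j + 1, 0.4 / (2 * j))
        off_p[j] = 0.6
    else:
        offs, off_p = np.array([0]), np.array([1.0])
    libraries: dict[str, list[BedRecord]] = {}
    for li in range(cfg.n_libraries):
        counts: dict[tuple, int] = {}
        for t in sim.truth:
            if status[t.id] == "silent":
                continue
            if status[t.id] == "extended":
                win = t.precursor.expand(50)
                for s in range(win.start, win.end - 30, 4):
                    key = (win.contig, s, s + 30, t.precursor.strand)
                    counts[key] = counts.get(key, 0) + 1 + int(rng.poisson(2))
                continue
            for arm in (t.mature5p, t.mature3p):
                depth = int(rng.poisson(cfg.read_depth_mean))
                if depth == 0:
                    continue
                for _ in range(depth):
                    off = int(rng.choice(offs, p=off_p))
                    length = arm.length + (int(rng.integers(-1, 2))
                                           if cfg.read_start_jitter > 0 else 0)
                    if arm.strand == "+":
                        s = max(0, arm.start + off)
                        key = (arm.contig, s, s + length, "+")
                    else:
                        e = arm.end - off
                        key = (arm.contig, max(0, e - length), e, "-")
                    counts[key] = counts.get(key, 0) + 1
        records = [
            BedRecord(GenomicInterval(c, s, e, st), name=f"read{j + 1}", count=n)
            for j, ((c, s, e, st), n) in enumerate(sorted(counts.items()))
        ]
        libraries[f"lib{li + 1}"] = records
    return libraries, status


@dataclass
class UtrSet:
    """Orthologous 3'-UTR alignments with a planted target map and DE labels."""

    alignments: dict[str, dict[str, str]]  # gene -> species -> aligned row
    target_map: dict[str, set[str]]        # miRNA id -> genes with planted sites
    de_sets: dict[str, list[str]]          # set name -> gene ids
    universe: list[str]
    mirna_seqs: dict[str, str]             # miRNA id -> mature sequence used


def simulate_utr_set(truth: list[PlantedMiRNA], config: SimulationConfig) -> UtrSet:
    """Plant conserved seed-match sites in orthologous UTRs, enriched in a
    designated down-regulated gene list with configurable odds.

    Site carriage probability is ``site_base_rate`` for background genes and
    the odds-scaled probability for DE genes, so ``enrichment_odds=1`` is the
    exact null.  Planted sites are written at identical alignment columns in
    all ``conserved_species`` rows.
    """
    cfg = config
    if not truth:
        raise ValueError("need at least one planted miRNA with a mature sequence")
    rng = cfg.rng(4)
    mirnas = truth[: cfg.n_target_mirnas]
    genes = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    de = sorted(rng.choice(cfg.n_genes, size=min(cfg.n_de_genes, cfg.n_genes), replace=False).tolist())
    de_set = {genes[i] for i in de}

    p0 = cfg.site_base_rate
    odds0 = p0 / (1 - p0)
    odds1 = odds0 * cfg.enrichment_odds
    p1 = odds1 / (1 + odds1)

    alignments: dict[str, dict[str, str]] = {}
    target_map: dict[str, set[str]] = {m.id: set() for m in mirnas}
    for g in genes:
        ancestral = _random_seq(rng, cfg.utr_len)
        rows = {}
        for sp in cfg.utr_species:
            n_mut = int(rng.binomial(cfg.utr_len, cfg.utr_mutation_rate))
            rows[sp] = _mutate(rng, ancestral, n_mut)
        p_site = p1 if g in de_set else p0
        for m in mirnas:
            if rng.random() >= p_site:
                continue
            seed = m.mature5p_seq[1:7]
            site = revcomp(seed)
            pos = int(rng.integers(0, cfg.utr_len - 6))
            for sp in cfg.conserved_species:
                rows[sp] = rows[sp][:pos] + site + rows[sp][pos + 6:]
            target_map[m.id].add(g)
        alignments[g] = rows
    return UtrSet(
        alignments=alignments,
        target_map=target_map,
        de_sets={"downregulated": sorted(de_set)},
        universe=genes,
        mirna_seqs={m.id: m.mature5p_seq for m in mirnas},
    )


def simulate_species_expression(truth: list[PlantedMiRNA], config: SimulationConfig):
    """Species x miRNA counts whose presence pattern evolves on the planted tree.

    All miRNAs are present at the root; along a branch of length L each miRNA
    is lost with probability ``1 - (1 - presence_loss_prob)**L`` (if present)
    or gained with the analogous gain probability (if absent) — i.e. the
    configured probabilities are per unit branch length, and trees without
    branch lengths behave as if every branch had length 1.  Each species gets
    two replicate libraries with Poisson counts for present miRNAs.  Returns
    ``(counts, presence)``: counts is a pandas DataFrame indexed by
    (species, library), presence the underlying boolean DataFrame by species.
    """
    import pandas as pd

    cfg = config
    rng = cfg.rng(5)
    tree = Phylo.read(_stdio.StringIO(cfg.planted_tree), "newick")
    leaves = [cl.name for cl in tree.get_terminals()]
    if len(leaves) != cfg.n_species:
        raise ValueError(
            f"planted_tree has {len(leaves)} leaves but n_species={cfg.n_species}")
    mirna_ids = [t if isinstance(t, str) else t.id for t in truth]
    n = len(mirna_ids)

    presence_at: dict[int, np.ndarray] = {id(tree.root): np.ones(n, dtype=bool)}

    def walk(clade):
        state = presence_at[id(clade)]
        for child in clade.clades:
            length = child.branch_length if child.branch_length is not None else 1.0
            p_loss = 1.0 - (1.0 - cfg.presence_loss_prob) ** length
            p_gain = 1.0 - (1.0 - cfg.presence_gain_prob) ** length
            loss = rng.random(n) < p_loss
            gain = rng.random(n) < p_gain
            child_state = np.where(state, ~loss, gain)
            presence_at[id(child)] = child_state
            walk(child)

    walk(tree.root)
    presence = pd.DataFrame(
        {leaf.name: presence_at[id(leaf)] for leaf in tree.get_terminals()},
        index=mirna_ids,
    ).T
    rows = {}
    for sp in leaves:
        for rep in (1, 2):
            counts = np.where(presence.loc[sp].to_numpy(),
                              rng.poisson(cfg.read_depth_mean, n), 0)
            rows[(sp, f"rep{rep}")] = counts
    counts = pd.DataFrame(rows, index=mirna_ids).T
    counts.index.names = ["species", "library"]
    return counts, presence


def reference_catalogue(sim: SimulatedGenome) -> tuple[dict[str, str], dict[str, str]]:
    """Labelled reference mature set emulating a curated miRNA database.

    For every planted locus with a known family label, one reference mature is
    emitted: the 5p arm with at most one mutation outside the seed (so the
    planted locus assigns back to its family under the 0.9-identity +
    exact-seed rule).  Returns (families, sequences) keyed by reference id.
    """
    rng = sim.config.rng(7)
    families: dict[str, str] = {}
    seqs: dict[str, str] = {}
    for t in sim.truth:
        if t.family_label == "novel":
            continue
        seq = t.mature5p_seq
        if rng.random() < 0.5:  # half the references differ by one non-seed base
            pos = int(rng.choice([0] + list(range(7, len(seq)))))
            alts = [b for b in "ACGT" if b != seq[pos]]
            seq = seq[:pos] + alts[int(rng.integers(0, 3))] + seq[pos + 1:]
        rid = f"ref-{t.family_label}-{t.id}"
        families[rid] = t.family_label
        seqs[rid] = seq
    return families, seqs


def write_study(sim: SimulatedGenome, outdir: str | Path) -> None:
    """Serialize genome, truth, per-tool predictions and read libraries."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.contigs, outdir / "genome.fa")
    write_gff3(truth_to_gff3(sim.truth, sim.decoys), outdir / "truth.gff3")
    preds = simulate_tool_predictions(sim)
    for tool, records in preds.items():
        write_gff3(records, outdir / f"pred_{tool}.gff3")
    families, ref_seqs = reference_catalogue(sim)
    write_fasta(ref_seqs, outdir / "reference_matures.fa")
    with open(outdir / "reference_families.tsv", "w") as fh:
        for rid in sorted(families):
            fh.write(f"{rid}\t{families[rid]}\n")
    libraries, status = simulate_read_alignments(sim)
    for lib, records in libraries.items():
        write_bed(records, outdir / f"reads_{lib}.bed")
    with open(outdir / "expression_status.tsv", "w") as fh:
        for k in sorted(status):
            fh.write(f"{k}\t{status[k]}\n")
    sim.config.to_yaml(outdir / "sim_config.yaml")
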