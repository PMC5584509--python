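"""Multi-predictor candidate merging and the reliability filter cascade.

The cascade mirrors how a consensus miRNA catalogue is assembled from
heterogeneous predictor output:

1.  ``anchor_gap_free`` — every candidate hairpin sequence is re-located in
    the genome; only gap-free placements (configurable mismatches, default 1)
    are accepted.
2.  ``reliability_filter`` — a read-based candidate is reliable if it has a
    reference-miRNA homology hit with at most one mismatch OR a score of at
    least 7.
3.  ``filter_homology_hits`` — homology evidence must span >=90% of the query
    with no gaps at significance < 1e-7.
4.  ``deduplicate_overlaps`` — hairpin loci overlapping or within 100 nt are
    collapsed to the highest-scoring call, pooling tool provenance.
5.  ``extension_triage`` — loci are looked up with 50-nt flanks against a
    structure reference; hits to non-miRNA ncRNAs are discarded.
6.  ``remove_annotation_conflicts`` — loci overlapping configured conflicting
    annotation classes (non-miRNA ncRNA genes, same-strand exons) are
    removed; intronic placement is allowed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .intervals import GenomicInterval, merge_chain
from .io import Gff3Record
from .sequtils import revcomp


@dataclass
class CandidatePrediction:
    id: str
    interval: GenomicInterval
    tool: str
    score: float
    hairpin_sequence: str = ""

    def __post_init__(self) -> None:
        if self.interval.length <= 0:
            raise ValueError("empty candidate interval")
        if not (self.score == self.score and abs(self.score) != float("inf")):
            raise ValueError("score must be finite")


@dataclass
class HomologyHit:
    candidate_id: str
    reference_id: str
    query_length: int
    aligned_span: int
    mismatches: int
    gaps: int
    significance: float

    def __post_init__(self) -> None:
        if self.aligned_span > self.query_length:
            raise ValueError("aligned_span exceeds query_length")
        if min(self.query_length, self.aligned_span, self.mismatches, self.gaps) < 0:
            raise ValueError("negative counts in homology hit")


class Triage(enum.Enum):
    MIRNA_STRUCTURE_HIT = "mirna_structure_hit"
    NO_HIT = "no_hit"
    OTHER_NCRNA_HIT = "other_ncrna_hit"


@dataclass
class MergedLocus:
    id: str
    interval: GenomicInterval
    supporting_tools: frozenset[str]
    best_score: float
    rescue: bool = False          # homology-rescued rather than score-passed
    triage: Triage = Triage.NO_HIT
    group_span: GenomicInterval | None = None  # union of all grouped calls
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.supporting_tools:
            raise ValueError("MergedLocus requires at least one supporting tool")
        if self.group_span is None:
            self.group_span = self.interval


@dataclass
class FilterLog:
    """Audit trail: candidate/locus id -> the one rule that removed it."""

    removed: dict[str, str] = field(default_factory=dict)

    def drop(self, cid: str, reason: str) -> None:
        self.removed.setdefault(cid, reason)


def candidates_from_gff3(records, tool: str | None = None,
                         min_score: float | None = None) -> list[CandidatePrediction]:
    """Ingest a predictor's GFF3, optionally applying its per-tool score gate."""
    out = []
    for rec in records:
        score = rec.score if rec.score is not None else 0.0
        if min_score is not None and score < min_score:
            continue
        out.append(CandidatePrediction(
            id=rec.attributes.get("ID", f"{rec.source}:{rec.interval.contig}:{rec.interval.start}"),
            interval=rec.interval,
            tool=tool or rec.source,
            score=score,
            hairpin_sequence=rec.attributes.get("hairpin_seq", ""),
        ))
    return out


def _exact_occurrences(haystack: str, needle: str) -> list[int]:
    hits = []
    pos = haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def _occurrences(haystack: str, needle: str, max_mismatch: int) -> list[int]:
    """Gap-free occurrences of needle with at most ``max_mismatch`` substitutions.

    Seed-and-extend by the pigeonhole principle: the needle is split into
    ``max_mismatch + 1`` chunks; any qualifying placement matches at least one
    chunk exactly, so candidate anchors come from fast exact search.
    """
    if max_mismatch <= 0:
        return _exact_occurrences(haystack, needle)
    n, m = len(haystack), len(needle)
    if m == 0 or m > n:
        return []
    k = max_mismatch + 1
    step = m // k
    candidates: set[int] = set()
    for c in range(k):
        lo = c * step
        hi = (c + 1) * step if c < k - 1 else m
        chunk = needle[lo:hi]
        for p in _exact_occurrences(haystack, chunk):
            s = p - lo
            if 0 <= s <= n - m:
                candidates.add(s)
    hits = []
    for s in sorted(candidates):
        mm = 0
        for a, b in zip(haystack[s:s + m], needle):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append(s)
    return hits


def anchor_gap_free(
    candidates: list[CandidatePrediction],
    genome: dict[str, str],
    max_mismatches: int = 1,
    log: FilterLog | None = None,
) -> list[CandidatePrediction]:
    """Re-anchor each candidate where its hairpin sequence occurs gap-free.

    Ties resolve to the originally reported interval when it is among the
    hits, else to the leftmost placement (first contig in sorted order,
    forward before reverse strand).  Candidates with no gap-free placement
    are dropped and logged.
    """
    out = []
    for cand in candidates:
        if cand.interval.contig not in genome:
            raise ValueError(f"candidate {cand.id}: contig {cand.interval.contig} missing from genome")
        seq = cand.hairpin_sequence.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"candidate {cand.id} has no hairpin sequence to anchor")
        # fast path: the stated interval itself is a gap-free placement, and
        # tie resolution would pick it over any other hit anyway
        iv = cand.interval
        segment = genome[iv.contig][iv.start:iv.end]
        if iv.strand == "-":
            segment = revcomp(segment)
        if len(segment) == len(seq) and sum(
                a != b for a, b in zip(segment, seq)) <= max_mismatches:
            out.append(cand)
            continue
        placements: list[GenomicInterval] = []
        for contig in sorted(genome):
            hay = genome[contig]
            for s in _occurrences(hay, seq, max_mismatches):
                placements.append(GenomicInterval(contig, s, s + len(seq), "+"))
            for s in _occurrences(hay, revcomp(seq), max_mismatches):
                placements.append(GenomicInterval(contig, s, s + len(seq), "-"))
        if not placements:
            if log is not None:
                log.drop(cand.id, "no gap-free placement")
            continue
        if cand.interval in placements:
            chosen = cand.interval
        else:
            chosen = min(placements, key=lambda iv: (iv.contig, iv.start, iv.strand == "-"))
        out.append(replace(cand, interval=chosen))
    return out


def filter_homology_hits(
    hits: list[HomologyHit],
    min_span_fraction: float = 0.9,
    max_gaps: int = 0,
    significance_cutoff: float = 1e-7,
) -> list[HomologyHit]:
    """Keep hits spanning >=90% of the query, gap-free, significance < 1e-7.

    Redundant hits per (candidate, reference) pair collapse to the best
    (lowest) significance.
    """
    best: dict[tuple[str, str], HomologyHit] = {}
    for hit in hits:
        if hit.aligned_span / hit.query_length < min_span_fraction:
            continue
        if hit.gaps > max_gaps:
            continue
        if not hit.significance < significance_cutoff:
            continue
        key = (hit.candidate_id, hit.reference_id)
        if key not in best or hit.significance < best[key].significance:
            best[key] = hit
    return list(best.values())


def reliability_filter(
    candidate: CandidatePrediction,
    reference_hits: list[HomologyHit],
    score_threshold: float = 7.0,
    max_mismatch: int = 1,
) -> tuple[bool, str]:
    """Keep a candidate with a <=1-mismatch reference hit OR score >= 7.

    Returns (keep, reason); reason is one of "homology_rescue",
    "score_pass", or "unreliable".
    """
    for hit in reference_hits:
        if hit.candidate_id == candidate.id and hit.gaps == 0 and hit.mismatches <= max_mismatch:
            return True, "homology_rescue"
    if candidate.score >= score_threshold:
        return True, "score_pass"
    return False, "unreliable"


def deduplicate_overlaps(
    candidates: list[CandidatePrediction],
    window: int = 100,
    rescue_ids: frozenset[str] = frozenset(),
) -> list[MergedLocus]:
    """Collapse hairpin loci overlapping or within ``window`` nt (edge gap).

    Single-linkage on the same contig regardless of strand (opposite-strand
    calls at one locus are the same physical hairpin).  The highest-scoring
    candidate survives; ties break toward more supporting tools at that
    interval, then the leftmost start.  The union of tools over the group and
    the union span are recorded.
    """
    if not candidates:
        return []
    ivs = [c.interval for c in candidates]
    groups = merge_chain(ivs, max_gap=window - 1)
    loci: list[MergedLocus] = []
    for gi, idxs in enumerate(groups):
        members = [candidates[i] for i in idxs]
        tool_count = {}
        for c in members:
            key = (c.interval.start, c.interval.end)
            tool_count.setdefault(key, set()).add(c.tool)
        winner = max(
            members,
            key=lambda c: (
                c.score,
                len(tool_count[(c.interval.start, c.interval.end)]),
                -c.interval.start,
            ),
        )
        span = members[0].interval
        for c in members[1:]:
            span = span.span_with(c.interval)
        span = replace(span, strand=winner.interval.strand)
        loci.append(MergedLocus(
            id=winner.id,
            interval=winner.interval,
            supporting_tools=frozenset(c.tool for c in members),
            best_score=winner.score,
            rescue=winner.id in rescue_ids,
            group_span=span,
            members=tuple(sorted(c.id for c in members)),
        ))
    loci.sort(key=lambda l: (l.interval.contig, l.interval.start))
    return loci


def extension_triage(
    locus: MergedLocus,
    structure_hits: dict[str, Triage | str],
    flank: int = 50,
    log: FilterLog | None = None,
) -> Triage:
    """Verdict for the 50-nt-extended locus against a structure reference.

    The comparison engine is external; ``structure_hits`` maps locus id to its
    verdict.  Missing entries are treated as no-hit (kept) with a warning.
    Loci hitting other (non-miRNA) ncRNA structures are discarded.
    """
    raw = structure_hits.get(locus.id, Triage.NO_HIT)
    verdict = Triage(raw) if not isinstance(raw, Triage) else raw
    if verdict is Triage.OTHER_NCRNA_HIT and log is not None:
        log.drop(locus.id, "other_ncrna_structure_hit")
    return verdict


DEFAULT_CONFLICT_CLASSES = ("rRNA", "tRNA", "snoRNA", "snRNA", "ncRNA_gene", "exon")


def remove_annotation_conflicts(
    loci: list[MergedLocus],
    annotation: list[Gff3Record],
    conflict_classes: tuple[str, ...] = DEFAULT_CONFLICT_CLASSES,
    log: FilterLog | None = None,
) -> list[MergedLocus]:
    """Drop loci overlapping conflicting annotation features.

    Defaults conflict with non-miRNA ncRNA genes and same-strand exons only;
    intronic placement inside protein-coding genes is explicitly allowed
    (miRNA genes are frequently intragenic).
    """
    conflicts = [rec for rec in annotation if rec.feature_type in conflict_classes]
    kept = []
    for locus in loci:
        hit = None
        for rec in conflicts:
            if not locus.interval.overlaps(rec.interval):
                continue
            if rec.feature_type == "exon" and rec.interval.strand != locus.interval.strand:
                continue
            hit = rec
            break
        if hit is None:
            kept.append(locus)
        elif log is not None:
            log.drop(locus.id, f"annotation_conflict:{hit.feature_type}")
    return kept
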