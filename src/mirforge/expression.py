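"""Read-profile verification of candidate miRNA loci.

A genuine miRNA locus shows one or two rectangular read blocks — the mature
5p and/or 3p products — separated by a read-free loop gap, with essentially
no coverage on the flanks.  Continuous coverage running across the precursor
and into the flanks is the signature of a degraded longer transcript
("extended mapping") and is rejected.  This module turns that curation rule
into an explicit, threshold-parameterized classifier.

All shape thresholds are fractions of observed peak height, so verdicts are
invariant to overall sequencing depth; only the absolute ``min_reads`` gate
depends on depth.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval
from .io import BedRecord
from .read_processing import ReadBlock, build_blocks


class Verdict(enum.Enum):
    VERIFIED = "verified"
    REJECTED_EXTENDED = "rejected_extended"
    REJECTED_DIFFUSE = "rejected_diffuse"
    NO_EXPRESSION = "no_expression"


@dataclass
class ExpressionProfile:
    locus_id: str
    window: GenomicInterval          # locus +/- flank
    flank: int
    coverage: np.ndarray             # per-position depth over the window
    blocks: list[ReadBlock]
    total_reads: int


@dataclass
class ProfileVerdict:
    verdict: Verdict
    mature5p: GenomicInterval | None = None
    mature3p: GenomicInterval | None = None
    gap_ok: bool = False
    detail: str = ""

    def __post_init__(self) -> None:
        if self.verdict is Verdict.VERIFIED and self.mature5p is None and self.mature3p is None:
            raise ValueError("verified verdict requires at least one mature arm")


def profile_locus(
    locus: GenomicInterval,
    alignments: list[BedRecord],
    flank: int = 20,
    locus_id: str = "",
) -> ExpressionProfile:
    """Coverage and read blocks over the locus +/- ``flank``.

    Only reads overlapping the window and on the locus contig contribute;
    both strands are counted (collapsed small-RNA alignments at a hairpin are
    strand-coherent in practice, and strand is kept on the blocks).
    """
    window = locus.expand(flank)
    cov = np.zeros(window.length, dtype=np.int64)
    members: list[tuple[GenomicInterval, int]] = []
    for rec in alignments:
        iv = rec.interval
        if iv.contig != window.contig or not iv.overlaps(window):
            continue
        lo = max(iv.start, window.start) - window.start
        hi = min(iv.end, window.end) - window.start
        cov[lo:hi] += rec.count
        members.append((iv, rec.count))
    blocks: list[ReadBlock] = []
    for strand in ("+", "-"):
        sel = [(iv, n) for iv, n in members if iv.strand == strand]
        if sel:
            blocks.extend(build_blocks(sel, min_block_reads=1, merge_gap=0))
    blocks.sort(key=lambda b: b.interval.start)
    return ExpressionProfile(
        locus_id=locus_id,
        window=window,
        flank=flank,
        coverage=cov,
        blocks=blocks,
        total_reads=sum(n for _, n in members),
    )


def classify_profile(
    profile: ExpressionProfile,
    locus: GenomicInterval,
    min_reads: int = 5,
    min_sharpness: float = 0.6,
    max_gap_coverage_fraction: float = 0.1,
    max_flank_coverage_fraction: float = 0.1,
    max_blocks: int = 2,
    edge_tolerance: int = 5,
) -> ProfileVerdict:
    """Classify a read profile as verified / extended / diffuse / silent.

    Order of rules: (1) below ``min_reads`` total -> no_expression; (2) flank
    coverage above ``max_flank_coverage_fraction`` x peak height -> extended
    mapping; (3) more than ``max_blocks`` blocks, or no block reaching
    ``min_sharpness`` -> diffuse; (4) otherwise verified when the inter-block
    gap coverage stays below ``max_gap_coverage_fraction`` x the smaller block
    height.  Mature arms are annotated from the (up to two) sharp blocks,
    5p/3p assigned by strand-aware position within the precursor.
    """
    if profile.total_reads < min_reads:
        return ProfileVerdict(Verdict.NO_EXPRESSION, detail=f"{profile.total_reads} reads")
    cov = profile.coverage
    window = profile.window
    peak = int(cov.max()) if cov.size else 0
    # flank coverage is judged beyond a short edge tolerance: mature products
    # overhang annotation boundaries by a few nt, degraded transcripts tile
    # the whole flank
    lo = max(0, locus.start - window.start - edge_tolerance)
    hi = min(len(cov), locus.end - window.start + edge_tolerance)
    left = cov[:lo]
    right = cov[hi:]
    flank_max = max([arr.max() for arr in (left, right) if arr.size], default=0)
    if peak > 0 and flank_max > max_flank_coverage_fraction * peak:
        return ProfileVerdict(Verdict.REJECTED_EXTENDED,
                              detail=f"flank coverage {flank_max}/{peak}")
    blocks = [b for b in profile.blocks if b.interval.overlaps(locus)]
    if len(blocks) > max_blocks:
        return ProfileVerdict(Verdict.REJECTED_DIFFUSE, detail=f"{len(blocks)} blocks")
    sharp = [b for b in blocks if b.sharpness >= min_sharpness]
    if not sharp:
        return ProfileVerdict(Verdict.REJECTED_DIFFUSE, detail="no sharp block")
    sharp.sort(key=lambda b: b.interval.start)
    gap_ok = True
    if len(sharp) == 2:
        lo = sharp[0].interval.end - window.start
        hi = sharp[1].interval.start - window.start
        gap_cov = int(cov[lo:hi].max()) if hi > lo else 0
        gap_ok = gap_cov <= max_gap_coverage_fraction * min(b.height for b in sharp)
        if not gap_ok:
            return ProfileVerdict(Verdict.REJECTED_DIFFUSE,
                                  detail=f"gap coverage {gap_cov}")
    # mature arms from the modal read interval, clipped into the locus;
    # 5p arm is genomically leftmost on '+', rightmost on '-'
    def clip(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(iv.contig, max(iv.start, locus.start),
                               min(iv.end, locus.end), iv.strand)

    arms = [clip(b.modal_interval()) for b in sharp]
    if locus.strand == "-":
        arms = arms[::-1]
    m5p = arms[0]
    m3p = arms[1] if len(arms) > 1 else None
    return ProfileVerdict(Verdict.VERIFIED, mature5p=m5p, mature3p=m3p, gap_ok=gap_ok)


@dataclass
class ExpressionCall:
    locus_id: str
    per_library: dict[str, bool] = field(default_factory=dict)

    @property
    def expressed_any(self) -> bool:
        return any(self.per_library.values())


def call_expressed(
    locus_id: str,
    library_profiles: dict[str, ExpressionProfile],
    min_reads: int = 5,
) -> ExpressionCall:
    """Per-library and any-library expression booleans (>= min_reads total)."""
    if not library_profiles:
        raise ValueError("call_expressed requires at least one library")
    call = ExpressionCall(locus_id)
    for lib, prof in library_profiles.items():
        call.per_library[lib] = prof.total_reads >= min_reads
    return call


def verify_locus(
    locus: GenomicInterval,
    library_alignments: dict[str, list[BedRecord]],
    locus_id: str = "",
    flank: int = 20,
    min_reads: int = 5,
    **classify_kwargs,
) -> tuple[ProfileVerdict, dict[str, ProfileVerdict]]:
    """Classify a locus in every library; catalogue verdict is the best one.

    A locus is catalogue-verified if ANY library verifies it (expression may
    be tissue-restricted).  Extended-mapping rejection likewise dominates
    silence, so a degraded-transcript signature in one library is not washed
    out by empty libraries.
    """
    order = {Verdict.VERIFIED: 0, Verdict.REJECTED_EXTENDED: 1,
             Verdict.REJECTED_DIFFUSE: 2, Verdict.NO_EXPRESSION: 3}
    per_lib: dict[str, ProfileVerdict] = {}
    for lib, alignments in library_alignments.items():
        prof = profile_locus(locus, alignments, flank=flank, locus_id=locus_id)
        per_lib[lib] = classify_profile(prof, locus, min_reads=min_reads, **classify_kwargs)
    best = min(per_lib.values(), key=lambda v: order[v.verdict])
    return best, per_lib
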