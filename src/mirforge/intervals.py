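"""Genomic interval primitives.

All coordinates in this package are 0-based, half-open ``[start, end)`` on a
named contig, with strand ``'+'`` or ``'-'``.  GFF3 serialization converts to
1-based inclusive coordinates at the file boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval (0-based, half-open)."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge gap in nt between two intervals on one contig.

        Overlapping or abutting intervals have gap 0.  Raises if the intervals
        are on different contigs (a gap is then undefined).
        """
        if self.contig != other.contig:
            raise ValueError("gap undefined across contigs")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def expand(self, flank: int) -> "GenomicInterval":
        """Return the interval widened by ``flank`` nt on both sides (clipped at 0)."""
        return replace(self, start=max(0, self.start - flank), end=self.end + flank)

    def span_with(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.contig != other.contig:
            raise ValueError("span undefined across contigs")
        return replace(
            self, start=min(self.start, other.start), end=max(self.end, other.end)
        )


def merge_chain(intervals, max_gap: int):
    """Group intervals on one contig by single-linkage with edge gap <= max_gap.

    Returns a list of lists of indices into ``intervals`` (sorted by start
    within and between groups).  Strand is ignored; contigs must match between
    chained members (intervals from different contigs never chain).
    """
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].contig, intervals[i].start, intervals[i].end))
    groups: list[list[int]] = []
    cur: list[int] = []
    cur_end = None
    cur_contig = None
    for i in order:
        iv = intervals[i]
        if cur and iv.contig == cur_contig and iv.start - cur_end <= max_gap:
            cur.append(i)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                groups.append(cur)
            cur = [i]
            cur_end = iv.end
            cur_contig = iv.contig
    if cur:
        groups.append(cur)
    return groups
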