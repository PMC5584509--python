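"""Reading and writing the tab-separated genomic formats used by the pipeline.

GFF3 files are 1-based inclusive on disk; BED files are 0-based half-open.
Both are converted to :class:`~mirforge.intervals.GenomicInterval` (0-based,
half-open) on read.  FASTA/FASTQ pass through Biopython.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval


@dataclass
class Gff3Record:
    interval: GenomicInterval
    source: str = "."
    feature_type: str = "."
    score: float | None = None
    phase: str = "."
    attributes: dict[str, str] = field(default_factory=dict)


def _fmt_attrs(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    enc = urllib.parse.quote
    return ";".join(f"{k}={enc(str(v), safe=' /|,:_-.')}" for k, v in attrs.items())


def _parse_attrs(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if text in (".", ""):
        return attrs
    for part in text.rstrip(";").split(";"):
        if not part:
            continue
        key, _, val = part.partition("=")
        attrs[key.strip()] = urllib.parse.unquote(val)
    return attrs


def write_gff3(records: Iterable[Gff3Record], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            iv = rec.interval
            score = "." if rec.score is None else f"{rec.score:g}"
            fh.write(
                "\t".join(
                    [
                        iv.contig,
                        rec.source,
                        rec.feature_type,
                        str(iv.start + 1),
                        str(iv.end),
                        score,
                        iv.strand,
                        rec.phase,
                        _fmt_attrs(rec.attributes),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> Iterator[Gff3Record]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            contig, source, ftype, start, end, score, strand, phase, attrs = fields
            yield Gff3Record(
                interval=GenomicInterval(contig, int(start) - 1, int(end), strand),
                source=source,
                feature_type=ftype,
                score=None if score == "." else float(score),
                phase=phase,
                attributes=_parse_attrs(attrs),
            )


@dataclass
class BedRecord:
    """A BED6(+) line; ``count`` rides in the score column (collapsed reads)."""

    interval: GenomicInterval
    name: str = "."
    count: int = 1
    extra: tuple[str, ...] = ()


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            cols = [iv.contig, str(iv.start), str(iv.end), rec.name, str(rec.count), iv.strand]
            cols.extend(rec.extra)
            fh.write("\t".join(cols) + "\n")


def read_bed(path: str | Path) -> Iterator[BedRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BED columns")
            contig, start, end, name, count, strand = fields[:6]
            yield BedRecord(
                interval=GenomicInterval(contig, int(start), int(end), strand),
                name=name,
                count=int(float(count)),
                extra=tuple(fields[6:]),
            )


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
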