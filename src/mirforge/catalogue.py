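"""Catalogue structure: genomic clusters, family assignment, composition.

A miRNA *cluster* is a genomic arrangement — at least two catalogue entries
on one contig chained by edge gaps of at most 10 kb (often co-transcribed).
A miRNA *family* is a homology grouping of mature sequences, independent of
genomic position.  Known families are assigned by ungapped identity to a
labelled reference; the remainder is partitioned into novel families by
single-linkage identity clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval, merge_chain


@dataclass
class CatalogueEntry:
    id: str
    precursor: GenomicInterval
    mature5p_seq: str = ""
    mature3p_seq: str = ""
    mature5p: GenomicInterval | None = None
    mature3p: GenomicInterval | None = None
    family: str = "unassigned"
    status: str = "verified"  # verified | putative_unexpressed

    @property
    def primary_mature(self) -> str:
        return self.mature5p_seq or self.mature3p_seq


@dataclass
class MiRNACluster:
    contig: str
    member_ids: list[str]
    span: GenomicInterval
    composition: str = ""

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("a miRNA cluster needs at least two members")


def call_clusters(entries: list[CatalogueEntry], max_gap: int = 10_000) -> list[MiRNACluster]:
    """Chain entries along each contig; edge gap <= max_gap joins a cluster.

    Strand is ignored for membership (clusters may mix strands); singletons
    are not clusters.  Members are ordered by genomic start.
    """
    ivs = [e.precursor for e in entries]
    clusters = []
    for idxs in merge_chain(ivs, max_gap=max_gap):
        if len(idxs) < 2:
            continue
        members = sorted((entries[i] for i in idxs), key=lambda e: e.precursor.start)
        span = members[0].precursor
        for e in members[1:]:
            span = span.span_with(e.precursor)
        clusters.append(MiRNACluster(
            contig=span.contig,
            member_ids=[e.id for e in members],
            span=span,
        ))
    clusters.sort(key=lambda c: (c.contig, c.span.start))
    return clusters


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def sequence_identity(a: str, b: str) -> float:
    """Best ungapped sliding identity of the shorter sequence in the longer.

    Identity = matches / length of the shorter sequence, maximized over all
    ungapped offsets.  Zero if either sequence is empty.
    """
    a, b = _norm(a), _norm(b)
    if len(a) > len(b):
        a, b = b, a
    if not a:
        return 0.0
    best = 0
    for off in range(len(b) - len(a) + 1):
        matches = sum(x == y for x, y in zip(a, b[off:off + len(a)]))
        best = max(best, matches)
    return best / len(a)


def _seed(seq: str) -> str:
    return _norm(seq)[1:7]


def assign_family(
    entry: CatalogueEntry,
    reference: dict[str, str],  # reference mature id -> family label
    reference_seqs: dict[str, str],  # reference mature id -> sequence
    min_identity: float = 0.9,
    require_seed_identity: bool = True,
) -> str:
    """Assign the family of the best-identity reference mature, or "unassigned".

    Requires identity >= ``min_identity`` and (by default) an exactly
    identical seed (nt 2-7).  Ties go to the highest identity, then the
    lexicographically smallest family name.
    """
    mature = entry.primary_mature
    if not mature:
        return "unassigned"
    best: tuple[float, str] | None = None
    for ref_id in sorted(reference_seqs):
        ref_seq = reference_seqs[ref_id]
        ident = sequence_identity(mature, ref_seq)
        if ident < min_identity:
            continue
        if require_seed_identity and _seed(mature) != _seed(ref_seq):
            continue
        fam = reference[ref_id]
        if best is None or (ident, ) > (best[0], ) or (ident == best[0] and fam < best[1]):
            best = (ident, fam)
    return best[1] if best else "unassigned"


def cluster_novel_families(
    entries: list[CatalogueEntry],
    min_identity: float = 0.9,
) -> dict[str, str]:
    """Partition unassigned entries into novel families by single linkage.

    Two entries link when their mature-sequence identity is >= min_identity;
    connected components become families labelled NF0001... in order of the
    genomic position of their first member (deterministic).
    """
    order = sorted(range(len(entries)),
                   key=lambda i: (entries[i].precursor.contig, entries[i].precursor.start,
                                  entries[i].id))
    parent = list(range(len(entries)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for ai in range(len(entries)):
        for bi in range(ai + 1, len(entries)):
            if sequence_identity(entries[ai].primary_mature, entries[bi].primary_mature) >= min_identity:
                union(ai, bi)

    labels: dict[int, str] = {}
    result: dict[str, str] = {}
    counter = 0
    for i in order:
        root = find(i)
        if root not in labels:
            counter += 1
            labels[root] = f"NF{counter:04d}"
        result[entries[i].id] = labels[root]
    return result


def cluster_composition(
    cluster: MiRNACluster,
    family_of: dict[str, str],
    reverse: bool = False,
) -> str:
    """5'->3' ordered family-label string of the cluster, e.g. "29a/29b".

    ``reverse`` flips the string for a reflected contig orientation.
    """
    labels = [family_of.get(mid, "unassigned") for mid in cluster.member_ids]
    if reverse:
        labels = labels[::-1]
    return "/".join(labels)


@dataclass
class CatalogueSummary:
    n_mirnas: int = 0
    n_clusters: int = 0
    n_mirnas_in_clusters: int = 0
    n_known_families: int = 0
    n_known_family_members: int = 0
    n_novel_families: int = 0
    n_novel_family_members: int = 0
    cluster_sizes: list[int] = field(default_factory=list)


def summarize_catalogue(
    entries: list[CatalogueEntry],
    clusters: list[MiRNACluster],
    family_of: dict[str, str],
) -> CatalogueSummary:
    """Counts table: totals, cluster counts, known/novel family counts."""
    known = [mid for mid, fam in family_of.items()
             if fam != "unassigned" and not fam.startswith("NF")]
    novel = [mid for mid, fam in family_of.items() if fam.startswith("NF")]
    return CatalogueSummary(
        n_mirnas=len(entries),
        n_clusters=len(clusters),
        n_mirnas_in_clusters=sum(len(c.member_ids) for c in clusters),
        n_known_families=len({family_of[m] for m in known}),
        n_known_family_members=len(known),
        n_novel_families=len({family_of[m] for m in novel}),
        n_novel_family_members=len(novel),
        cluster_sizes=[len(c.member_ids) for c in clusters],
    )


def assign_all_families(
    entries: list[CatalogueEntry],
    reference: dict[str, str],
    reference_seqs: dict[str, str],
    min_identity: float = 0.9,
    require_seed_identity: bool = True,
) -> dict[str, str]:
    """Known-family assignment followed by novel-family clustering of the rest."""
    family_of: dict[str, str] = {}
    unassigned: list[CatalogueEntry] = []
    for e in entries:
        fam = assign_family(e, reference, reference_seqs, min_identity, require_seed_identity)
        if fam == "unassigned":
            unassigned.append(e)
        else:
            family_of[e.id] = fam
            e.family = fam
    novel = cluster_novel_families(unassigned, min_identity)
    for e in unassigned:
        e.family = novel[e.id]
    family_of.update(novel)
    return family_of
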