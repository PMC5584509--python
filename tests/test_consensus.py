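"""Filter cascade rules: anchoring, homology filters, dedup, triage."""

import random

import pytest

from mirforge.consensus import (CandidatePrediction, FilterLog, HomologyHit,
                                Triage, anchor_gap_free, deduplicate_overlaps,
                                extension_triage, filter_homology_hits,
                                reliability_filter, remove_annotation_conflicts)
from mirforge.intervals import GenomicInterval
from mirforge.io import Gff3Record
from mirforge.sequtils import revcomp


def cand(start, end, score=8.0, tool="mirdeep_like", cid=None, seq="", contig="ctg1",
         strand="+"):
    return CandidatePrediction(
        id=cid or f"{tool}:{start}",
        interval=GenomicInterval(contig, start, end, strand),
        tool=tool, score=score, hairpin_sequence=seq)


def _random_genome(seed=5, n=600):
    rng = random.Random(seed)
    return {"ctg1": "".join(rng.choice("ACGT") for _ in range(n))}


class TestAnchorGapFree:
    GENOME = _random_genome()

    def test_verbatim_sequence_stays_put(self):
        seq = self.GENOME["ctg1"][100:180]
        c = cand(100, 180, seq=seq)
        out = anchor_gap_free([c], self.GENOME)
        assert out[0].interval == c.interval

    def test_absent_sequence_dropped_with_reason(self):
        log = FilterLog()
        c = cand(100, 130, seq="TTTTTTTTTTGGGGGGGGGGCCCCCCCCCC")
        out = anchor_gap_free([c], self.GENOME, max_mismatches=0, log=log)
        assert out == []
        assert log.removed[c.id] == "no gap-free placement"

    def test_insertion_breaks_gap_free_placement(self):
        base = self.GENOME["ctg1"][200:260]
        gapped = base[:30] + "A" + base[30:]  # occurs only with a 1-nt insertion
        if gapped in self.GENOME["ctg1"]:
            pytest.skip("random genome accidentally contains the gapped form")
        c = cand(200, 261, seq=gapped)
        assert anchor_gap_free([c], self.GENOME, max_mismatches=0) == []

    def test_one_mismatch_tolerated_and_reanchored(self):
        seq = list(self.GENOME["ctg1"][300:360])
        seq[25] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[25]]
        c = cand(0, 60, seq="".join(seq))
        out = anchor_gap_free([c], self.GENOME, max_mismatches=1)
        assert len(out) == 1 and out[0].interval.start == 300

    def test_reverse_strand_placement_found(self):
        seq = revcomp(self.GENOME["ctg1"][400:460])
        c = cand(0, 60, seq=seq)
        out = anchor_gap_free([c], self.GENOME)
        assert out[0].interval == GenomicInterval("ctg1", 400, 460, "-")

    def test_missing_contig_is_input_error(self):
        with pytest.raises(ValueError, match="contig"):
            anchor_gap_free([cand(0, 10, seq="ACGT", contig="nope")], self.GENOME)


class TestHomologyHitFilter:
    def hit(self, span=95, qlen=100, gaps=0, sig=1e-8, cid="c1", rid="r1"):
        return HomologyHit(cid, rid, qlen, span, 0, gaps, sig)

    def test_span_boundary_inclusive_at_90_percent(self):
        assert filter_homology_hits([self.hit(span=90)]) != []
        assert filter_homology_hits([self.hit(span=89)]) == []

    def test_any_gap_disqualifies(self):
        assert filter_homology_hits([self.hit(gaps=1)]) == []

    def test_significance_strictly_below_cutoff(self):
        assert filter_homology_hits([self.hit(sig=1e-6)]) == []
        assert filter_homology_hits([self.hit(sig=1e-7)]) == []
        assert filter_homology_hits([self.hit(sig=9.9e-8)]) != []

    def test_redundant_hits_keep_best_significance(self):
        hits = [self.hit(sig=1e-8), self.hit(sig=1e-12)]
        out = filter_homology_hits(hits)
        assert len(out) == 1 and out[0].significance == 1e-12


class TestReliabilityFilter:
    def test_score_threshold_inclusive(self):
        keep, reason = reliability_filter(cand(0, 60, score=7.0), [])
        assert keep and reason == "score_pass"
        keep, reason = reliability_filter(cand(0, 60, score=6.99), [])
        assert not keep and reason == "unreliable"

    def test_homology_rescue_with_one_mismatch(self):
        c = cand(0, 60, score=2.0, cid="x")
        hit = HomologyHit("x", "mir-1", 22, 22, 1, 0, 1e-20)
        keep, reason = reliability_filter(c, [hit])
        assert keep and reason == "homology_rescue"

    def test_two_mismatches_do_not_rescue(self):
        c = cand(0, 60, score=2.0, cid="x")
        hit = HomologyHit("x", "mir-1", 22, 22, 2, 0, 1e-20)
        keep, _ = reliability_filter(c, [hit])
        assert not keep


class TestDeduplicateOverlaps:
    def test_gap_99_merges_keeping_best_score(self):
        a, b = cand(0, 60, 9.0), cand(159, 220, 7.0)
        loci = deduplicate_overlaps([a, b])
        assert len(loci) == 1
        assert loci[0].best_score == 9.0
        assert loci[0].supporting_tools == {"mirdeep_like"}
        assert loci[0].group_span.end == 220

    def test_gap_150_stays_separate(self):
        loci = deduplicate_overlaps([cand(0, 60), cand(210, 270)])
        assert len(loci) == 2

    def test_gap_exactly_100_stays_separate(self):
        loci = deduplicate_overlaps([cand(0, 60), cand(160, 220)])
        assert len(loci) == 2

    def test_five_tools_one_locus(self):
        cands = [cand(0, 60, 5.0 + i, tool=f"t{i}", cid=f"t{i}:0") for i in range(5)]
        loci = deduplicate_overlaps(cands)
        assert len(loci) == 1
        assert len(loci[0].supporting_tools) == 5
        assert loci[0].best_score == 9.0

    def test_opposite_strands_same_locus_merge(self):
        loci = deduplicate_overlaps([cand(0, 60), cand(10, 70, strand="-")])
        assert len(loci) == 1

    def test_brute_force_oracle_small(self):
        rng = random.Random(11)
        for _ in range(50):
            cands = []
            for i in range(rng.randint(1, 15)):
                s = rng.randrange(0, 2000)
                cands.append(cand(s, s + rng.randint(20, 120),
                                  rng.random() * 10, cid=f"c{i}"))
            got = deduplicate_overlaps(cands, window=100)
            assert _oracle_groups(cands, 100) == sorted(
                tuple(l.members) for l in got)

    def test_order_stability(self):
        rng = random.Random(2)
        cands = []
        for i in range(30):
            s = rng.randrange(0, 5000)
            cands.append(cand(s, s + rng.randint(20, 120), rng.random() * 10,
                              cid=f"c{i}"))
        ref = deduplicate_overlaps(cands)
        shuffled = cands[:]
        rng.shuffle(shuffled)
        got = deduplicate_overlaps(shuffled)
        assert [(l.id, l.interval, l.supporting_tools) for l in ref] == \
               [(l.id, l.interval, l.supporting_tools) for l in got]


def _oracle_groups(cands, window):
    """O(n^2) transitive closure on 'overlap or edge gap < window'."""
    n = len(cands)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = cands[i].interval, cands[j].interval
            if a.overlaps(b) or a.gap_to(b) < window:
                parent[find(j)] = find(i)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(cands[i].id)
    return sorted(tuple(sorted(g)) for g in groups.values())


def test_raising_score_threshold_never_grows_kept_set():
    rng = random.Random(31)
    cands = [cand(i * 300, i * 300 + 60, rng.random() * 12, cid=f"c{i}")
             for i in range(40)]
    prev = None
    for thr in (0.0, 3.0, 7.0, 10.0, 15.0):
        kept = {c.id for c in cands if reliability_filter(c, [], thr)[0]}
        if prev is not None:
            assert kept <= prev
        prev = kept


class TestExtensionTriage:
    def locus(self):
        return deduplicate_overlaps([cand(0, 60, cid="L1")])[0]

    def test_other_ncrna_hit_discarded(self):
        log = FilterLog()
        verdict = extension_triage(self.locus(), {"L1": "other_ncrna_hit"}, log=log)
        assert verdict is Triage.OTHER_NCRNA_HIT
        assert "L1" in log.removed

    @pytest.mark.parametrize("raw", ["no_hit", "mirna_structure_hit"])
    def test_kept_verdicts(self, raw):
        assert extension_triage(self.locus(), {"L1": raw}) is Triage(raw)

    def test_missing_entry_treated_as_no_hit(self):
        assert extension_triage(self.locus(), {}) is Triage.NO_HIT


class TestAnnotationConflicts:
    def gff(self, ftype, start, end, strand="+"):
        return Gff3Record(GenomicInterval("ctg1", start, end, strand),
                          feature_type=ftype)

    def test_rrna_overlap_removed(self):
        locus = deduplicate_overlaps([cand(100, 160, cid="L1")])[0]
        log = FilterLog()
        kept = remove_annotation_conflicts([locus], [self.gff("rRNA", 50, 300)],
                                           log=log)
        assert kept == [] and log.removed["L1"].startswith("annotation_conflict")

    def test_intronic_locus_kept(self):
        locus = deduplicate_overlaps([cand(500, 560, cid="L1")])[0]
        annotation = [self.gff("gene", 0, 2000), self.gff("mRNA", 0, 2000),
                      self.gff("exon", 0, 300), self.gff("exon", 1000, 2000)]
        assert remove_annotation_conflicts([locus], annotation) == [locus]

    def test_antisense_exon_overlap_kept(self):
        locus = deduplicate_overlaps([cand(100, 160, cid="L1")])[0]
        annotation = [self.gff("exon", 0, 300, strand="-")]
        assert remove_annotation_conflicts([locus], annotation) == [locus]

    def test_same_strand_exon_overlap_removed(self):
        locus = deduplicate_overlaps([cand(100, 160, cid="L1")])[0]
        annotation = [self.gff("exon", 0, 300, strand="+")]
        assert remove_annotation_conflicts([locus], annotation) == []

    def test_empty_annotation_keeps_everything(self):
        loci = deduplicate_overlaps([cand(0, 60), cand(500, 560)])
        assert remove_annotation_conflicts(loci, []) == loci
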