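"""Synthetic study generator: planted geometry, determinism, calibration."""

import dataclasses
from collections import Counter

import numpy as np
import pytest

from mirforge.io import read_gff3, write_gff3
from mirforge.simulate import (PlantedMiRNA, SimulationConfig,
                               simulate_genome, simulate_read_alignments,
                               simulate_species_expression,
                               simulate_tool_predictions, simulate_utr_set,
                               truth_from_gff3, truth_to_gff3, write_study)


def cfg(**kw):
    base = dict(seed=1, n_contigs=2, contig_length=300_000,
                n_true_mirnas=10, n_decoys=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateGenome:
    def test_empty_truth_set(self):
        sim = simulate_genome(cfg(n_true_mirnas=0, n_decoys=0))
        assert sim.truth == [] and sim.decoys == []

    def test_cluster_spec_gaps_exact(self):
        sim = simulate_genome(cfg(cluster_spec=[(3, 5000)]))
        clustered = [t for t in sim.truth if t.cluster_id]
        assert len(clustered) == 3
        assert len({t.precursor.contig for t in clustered}) == 1
        clustered.sort(key=lambda t: t.precursor.start)
        gaps = [b.precursor.start - a.precursor.end
                for a, b in zip(clustered, clustered[1:])]
        assert gaps == [5000, 5000]

    def test_deterministic_under_seed(self, tmp_path):
        for name in ("a", "b"):
            sim = simulate_genome(cfg(seed=9))
            write_study(sim, tmp_path / name)
        for f in ["genome.fa", "truth.gff3", "pred_mirdeep_like.gff3",
                  "reads_lib1.bed", "reference_matures.fa"]:
            assert (tmp_path / "a" / f).read_bytes() == \
                   (tmp_path / "b" / f).read_bytes(), f

    def test_sizing_error_names_shortfall(self):
        with pytest.raises(ValueError, match="too short"):
            simulate_genome(cfg(n_contigs=1, contig_length=50_000,
                                n_true_mirnas=20))

    def test_truth_gff3_round_trip(self):
        sim = simulate_genome(cfg())
        records = truth_to_gff3(sim.truth, sim.decoys)
        back, decoys = truth_from_gff3(records)
        assert back == sim.truth
        assert decoys == sim.decoys

    def test_planted_geometry_invariants_random_configs(self):
        rng = np.random.default_rng(77)
        for _ in range(15):
            c = cfg(seed=int(rng.integers(0, 10_000)),
                    n_true_mirnas=int(rng.integers(1, 15)),
                    hairpin_len_range=(int(rng.integers(60, 80)),
                                       int(rng.integers(90, 121))))
            for t in simulate_genome(c).truth:
                t.validate()  # nesting, >=4-nt arm gap, <=3-mismatch revcomp

    def test_planted_sequence_matches_genome(self):
        sim = simulate_genome(cfg())
        for t in sim.truth:
            assert sim.fetch(t.mature5p) == t.mature5p_seq
            assert sim.fetch(t.mature3p) == t.mature3p_seq

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            cfg(tool_sensitivity=1.2)


class TestToolPredictions:
    def test_noiseless_limit_equals_truth(self):
        c = cfg(tool_sensitivity=1.0, tool_fp_rate=0.0, positional_jitter_sd=0.0)
        sim = simulate_genome(c)
        preds = simulate_tool_predictions(sim)
        truth_pre = {(t.precursor.contig, t.precursor.start, t.precursor.end)
                     for t in sim.truth}
        for tool, recs in preds.items():
            assert len(recs) == len(sim.truth)
        got = {(r.interval.contig, r.interval.start, r.interval.end)
               for r in preds["mirdeep_like"]}
        assert got == truth_pre

    def test_zero_sensitivity_and_fp_empty(self):
        c = cfg(tool_sensitivity=0.0, tool_fp_rate=0.0)
        sim = simulate_genome(c)
        assert all(not recs for recs in simulate_tool_predictions(sim).values())

    def test_recovery_fraction_within_binomial_ci(self):
        c = SimulationConfig(seed=3, n_true_mirnas=200, n_decoys=0,
                             tool_sensitivity=0.8, tool_fp_rate=0.0)
        sim = simulate_genome(c)
        preds = simulate_tool_predictions(sim)
        # 99.9% binomial CI half-width for p=0.8, n=200 is ~0.093
        for tool, recs in preds.items():
            frac = len(recs) / 200
            assert abs(frac - 0.8) < 0.095, tool

    def test_mature_length_tool_differs_from_precursor_tools(self):
        sim = simulate_genome(cfg(tool_sensitivity=1.0))
        preds = simulate_tool_predictions(sim)
        mature_lens = {r.interval.length for r in preds["blast_like"]}
        precursor_lens = {r.interval.length for r in preds["gorap_like"]}
        assert mature_lens == {22}
        assert all(l >= 60 for l in precursor_lens)


class TestReadAlignments:
    def test_noiseless_reads_equal_mature_intervals(self):
        c = cfg(read_start_jitter=0, expressed_fraction=1.0,
                extended_mapping_fraction=0.0)
        sim = simulate_genome(c)
        libs, status = simulate_read_alignments(sim)
        arm_ivs = {(t.mature5p.contig, t.mature5p.start, t.mature5p.end)
                   for t in sim.truth} | \
                  {(t.mature3p.contig, t.mature3p.start, t.mature3p.end)
                   for t in sim.truth}
        for recs in libs.values():
            for rec in recs:
                assert (rec.interval.contig, rec.interval.start,
                        rec.interval.end) in arm_ivs

    def test_extended_fraction_one_covers_flanks(self):
        c = cfg(extended_mapping_fraction=1.0)
        sim = simulate_genome(c)
        libs, status = simulate_read_alignments(sim)
        assert set(status.values()) == {"extended"}
        recs = libs["lib1"]
        for t in sim.truth:
            win_start, win_end = t.precursor.start - 50, t.precursor.end + 50
            cover = [r for r in recs
                     if r.interval.contig == t.precursor.contig
                     and r.interval.start >= win_start - 4
                     and r.interval.end <= win_end + 30]
            assert min(r.interval.start for r in cover) <= win_start + 4
            assert max(r.interval.end for r in cover) >= win_end - 34

    def test_poisson_depth_mean(self):
        c = SimulationConfig(seed=5, n_true_mirnas=100, n_decoys=0,
                             read_depth_mean=30.0, expressed_fraction=1.0,
                             extended_mapping_fraction=0.0, n_libraries=1)
        sim = simulate_genome(c)
        libs, _ = simulate_read_alignments(sim)
        per_arm = Counter()
        for rec in libs["lib1"]:
            per_arm[(rec.interval.contig, rec.interval.start // 200)] += rec.count
        mean = sum(per_arm.values()) / (2 * 100)
        assert 25 < mean < 35

    def test_silent_loci_have_no_reads(self):
        c = cfg(expressed_fraction=0.0, extended_mapping_fraction=0.0)
        sim = simulate_genome(c)
        libs, status = simulate_read_alignments(sim)
        assert set(status.values()) == {"silent"}
        assert all(not recs for recs in libs.values())


class TestUtrSet:
    def test_null_odds_sites_independent_of_de(self):
        c = cfg(enrichment_odds=1.0, n_genes=300, seed=11)
        sim = simulate_genome(c)
        utr = simulate_utr_set(sim.truth, c)
        de = set(utr.de_sets["downregulated"])
        targeted = set().union(*utr.target_map.values())
        # same carriage rate expected in/out of DE set (loose 3-sigma check)
        p_in = len(targeted & de) / len(de)
        p_out = len(targeted - de) / (len(utr.universe) - len(de))
        assert abs(p_in - p_out) < 0.2

    def test_zero_site_rate_empty_map(self):
        c = cfg(site_base_rate=0.0, n_genes=50)
        sim = simulate_genome(c)
        utr = simulate_utr_set(sim.truth, c)
        assert all(not genes for genes in utr.target_map.values())

    def test_alignment_rows_cover_requested_species(self):
        c = cfg(n_genes=20)
        sim = simulate_genome(c)
        utr = simulate_utr_set(sim.truth, c)
        for rows in utr.alignments.values():
            assert set(rows) == set(c.utr_species)
            assert {len(r) for r in rows.values()} == {c.utr_len}

    def test_requires_truth(self):
        with pytest.raises(ValueError):
            simulate_utr_set([], cfg())


class TestSpeciesExpression:
    def test_zero_rates_all_species_share_root_set(self):
        c = cfg(presence_loss_prob=0.0, presence_gain_prob=0.0)
        sim = simulate_genome(c)
        counts, presence = simulate_species_expression(sim.truth, c)
        assert presence.all(axis=None)

    def test_two_replicates_per_species(self):
        c = cfg()
        sim = simulate_genome(c)
        counts, _ = simulate_species_expression(sim.truth, c)
        libs_per_species = counts.groupby(level="species").size()
        assert (libs_per_species == 2).all()

    def test_sister_species_share_more(self):
        c = dataclasses.replace(
            cfg(n_true_mirnas=100, contig_length=1_200_000),
            n_species=3, planted_tree="((spA,spB),spC);",
            presence_loss_prob=0.2, presence_gain_prob=0.02)
        hits = 0
        for seed in range(20):
            c2 = dataclasses.replace(c, seed=seed)
            sim_truth = simulate_genome(c2).truth
            _, presence = simulate_species_expression(sim_truth, c2)
            ab = (presence.loc["spA"] == presence.loc["spB"]).sum()
            ac = (presence.loc["spA"] == presence.loc["spC"]).sum()
            bc = (presence.loc["spB"] == presence.loc["spC"]).sum()
            hits += ab > max(ac, bc)
        assert hits >= 18

    def test_leaf_count_mismatch_rejected(self):
        c = cfg()  # default 7-leaf tree
        c2 = dataclasses.replace(c, n_species=4)
        sim = simulate_genome(c2)
        with pytest.raises(ValueError, match="leaves"):
            simulate_species_expression(sim.truth, c2)
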