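"""Simulator ground-truth closure and determinism."""
import dataclasses

import numpy as np
import pytest

from texpress import io
from texpress.conserved_te import conserved_set, conserved_te_ids, filter_read_pairs
from texpress.synthetic_data import (
    SimConfig,
    simulate_all,
    simulate_counts,
    simulate_genome_pair,
    simulate_population_reads,
    simulate_similarity_scores,
    simulate_te_landscape,
)
from texpress.orthology import aggregate_max, reciprocal_best_pairs
from texpress.te_annotation import classify_te_insertions


class TestGenomePair:
    def test_basic_and_deterministic(self):
        cfg = SimConfig(seed=1, n_genes=10)
        ga1, gb1, t1 = simulate_genome_pair(cfg)
        ga2, gb2, t2 = simulate_genome_pair(cfg)
        assert len(t1) >= 9
        assert ga1.keys() == ga2.keys()
        assert t1 == t2
        for g in ga1:
            assert ga1[g].cds_intervals == ga2[g].cds_intervals

    def test_gff3_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=1, n_genes=15)
        for run in (1, 2):
            ga, _, _ = simulate_genome_pair(cfg)
            io.write_gff3(ga, tmp_path / f"run{run}.gff3")
        assert (tmp_path / "run1.gff3").read_bytes() == (
            tmp_path / "run2.gff3"
        ).read_bytes()

    def test_no_crowding_gaps_exceed_4kb(self):
        cfg = SimConfig(seed=2, n_genes=30)
        ga, gb, _ = simulate_genome_pair(cfg)
        for genes in (ga, gb):
            by_chrom = {}
            for g in genes.values():
                by_chrom.setdefault(g.chrom, []).append(g.gene_region)
            for regions in by_chrom.values():
                regions.sort()
                for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
                    assert s2 - e1 > 4000

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=0, n_genes=0)

    def test_similarity_recovers_truth(self):
        cfg = SimConfig(seed=3, n_genes=40)
        ga, gb, truth = simulate_genome_pair(cfg)
        sim = simulate_similarity_scores(cfg, ga, gb, truth)
        pairs = reciprocal_best_pairs(aggregate_max(sim))
        assert dict(pairs) == truth


class TestTELandscape:
    def test_zero_rates_zero_tes(self):
        cfg = SimConfig(seed=1, n_genes=10, te_rates={})
        ga, gb, _ = simulate_genome_pair(cfg)
        tes_a, tes_b, cons, _ = simulate_te_landscape(cfg, ga, gb)
        assert tes_a == [] and tes_b == [] and cons == {}

    def test_forced_intron_insertion(self):
        cfg = SimConfig(
            seed=1, n_genes=20, te_rates={("INTRON", "DNA"): (1.0, 0.0)}
        )
        ga, gb, truth = simulate_genome_pair(cfg)
        tes_a, tes_b, _, gt = simulate_te_landscape(cfg, ga, gb)
        assert tes_b == []
        genes_hit = {g for g, *_ in gt.te_placements_a}
        assert set(ga) <= genes_hit  # every multi-CDS A gene got one

    def test_planted_regions_match_classifier(self):
        cfg = SimConfig(
            seed=5,
            n_genes=40,
            te_rates={
                ("INTRON", "DNA"): (0.6, 0.3),
                ("UP2000", "LINE"): (0.5, 0.5),
                ("CDS", "LTR"): (0.4, 0.2),
                ("DOWN200", "RC"): (0.5, 0.5),
            },
        )
        ga, gb, _ = simulate_genome_pair(cfg)
        tes_a, tes_b, _, gt = simulate_te_landscape(cfg, ga, gb)
        for genes, tes, placements in (
            (ga, tes_a, gt.te_placements_a),
            (gb, tes_b, gt.te_placements_b),
        ):
            got = {
                (r.gene_id, r.te_id, r.region)
                for r in classify_te_insertions(genes.values(), tes)
            }
            for gene_id, te_id, te_type, region in placements:
                assert (gene_id, te_id, region) in got

    def test_te_within_chromosome_bounds(self):
        cfg = SimConfig(
            seed=6, n_genes=30, te_rates={("UP2000", "SINE"): (0.8, 0.8)}
        )
        ga, gb, _ = simulate_genome_pair(cfg)
        tes_a, tes_b, _, _ = simulate_te_landscape(cfg, ga, gb)
        for te in tes_a + tes_b:
            assert te.start >= 0


class TestCounts:
    def test_poisson_limit(self):
        cfg = SimConfig(
            seed=7, n_genes=3000, nb_dispersion=0.0, frac_deg=0.0,
            lib_factor_sd=0.0,
        )
        _, _, truth = simulate_genome_pair(SimConfig(seed=7, n_genes=1))
        ortho = {f"gA{i:05d}": f"gB{i:05d}" for i in range(3000)}
        counts, meta, _ = simulate_counts(cfg, ortho)
        cols = meta.index[(meta.species == "A") & (meta.stage == "L4")]
        x = counts[cols].to_numpy(dtype=float)
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        ok = m > 5
        # Poisson limit: within-condition variance/mean ratio averages to 1
        assert (v[ok] / m[ok]).mean() == pytest.approx(1.0, rel=0.1)

    def test_null_model_empty_truth(self):
        cfg = SimConfig(seed=8, n_genes=50, logfc_effect=0.0, te_effect_beta=1.0)
        ortho = {f"gA{i:05d}": f"gB{i:05d}" for i in range(50)}
        _, _, truth = simulate_counts(cfg, ortho)
        assert all(not v for v in truth.true_deg.values())

    def test_library_factor_doubles_column(self):
        cfg = SimConfig(
            seed=9, n_genes=4000, nb_dispersion=0.0, frac_deg=0.0,
            lib_factor_sd=0.0,
            lib_factors={"A_L4_r1": 2.0, "A_L4_r2": 1.0},
        )
        ortho = {f"gA{i:05d}": f"gB{i:05d}" for i in range(4000)}
        counts, _, _ = simulate_counts(cfg, ortho)
        ratio = counts["A_L4_r1"].sum() / counts["A_L4_r2"].sum()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=0, n_genes=5, nb_dispersion=-0.1)

    def test_deterministic(self):
        cfg = SimConfig(seed=10, n_genes=30)
        ortho = {f"gA{i:05d}": f"gB{i:05d}" for i in range(30)}
        c1, _, _ = simulate_counts(cfg, ortho)
        c2, _, _ = simulate_counts(cfg, ortho)
        assert c1.equals(c2)


class TestPopulationReads:
    def _landscape(self, conserved_fraction=1.0, seed=11):
        cfg = SimConfig(
            seed=seed,
            n_genes=25,
            te_rates={("INTRON", "DNA"): (0.8, 0.0)},
            conserved_fraction=conserved_fraction,
            n_populations=4,
        )
        ga, gb, _ = simulate_genome_pair(cfg)
        tes_a, _, cons, _ = simulate_te_landscape(cfg, ga, gb)
        return cfg, tes_a, cons

    def test_full_conservation_recovered(self):
        cfg, tes_a, cons = self._landscape(1.0)
        reads = simulate_population_reads(cfg, tes_a, cons)
        calls = conserved_set(tes_a, reads)
        assert conserved_te_ids(calls) == {t.te_id for t in tes_a}

    def test_empty_conservation_map(self):
        cfg, tes_a, _ = self._landscape(1.0)
        reads = simulate_population_reads(cfg, tes_a, {})
        calls = conserved_set(tes_a, reads)
        assert conserved_te_ids(calls) == set()

    def test_partial_patterns_recovered(self):
        cfg, tes_a, cons = self._landscape(0.3, seed=12)
        reads = simulate_population_reads(cfg, tes_a, cons)
        calls = {c.te_id: c for c in conserved_set(tes_a, reads)}
        pops = {f"pop{i+1}" for i in range(cfg.n_populations)}
        for te in tes_a:
            present = {p for p, ok in calls[te.te_id].presence.items() if ok}
            assert present == cons[te.te_id]

    def test_decoy_unmapped_pair_filtered(self):
        cfg, tes_a, cons = self._landscape(1.0)
        reads = simulate_population_reads(cfg, tes_a, cons)
        repeat_ivs = {}
        for t in tes_a:
            repeat_ivs.setdefault(t.chrom, []).append(t.interval)
        for pop, pairs in reads.items():
            kept = filter_read_pairs(pairs, repeat_ivs)
            assert all(all(m.mapped for m in p.mates) for p in kept)
            assert len(kept) < len(pairs)  # decoys removed

    def test_read_length_precondition(self):
        cfg, tes_a, cons = self._landscape(1.0)
        bad = dataclasses.replace(cfg, read_length=10)
        with pytest.raises(ValueError):
            simulate_population_reads(bad, tes_a, cons)


class TestSimulateAll:
    def test_bundle_consistency(self):
        cfg = SimConfig(
            seed=13, n_genes=60, te_rates={("INTRON", "DNA"): (0.4, 0.2)}
        )
        b = simulate_all(cfg)
        assert set(b.counts.index) == set(b.truth.ortholog_map)
        assert b.counts.shape[1] == len(b.meta)
        assert b.truth.conserved_te_ids <= {t.te_id for t in b.tes_a}
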