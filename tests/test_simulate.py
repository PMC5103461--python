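"""Synthetic-data generators: determinism, planted-truth conservation,
statistical structure (GC, divergence, depth linearity, gene architecture)."""

import math

import numpy as np
import pytest

import straindiverge as sd
from straindiverge.simulate import depth_profile, jc_p_from_d


class TestMakeAncestor:
    def test_gc_fraction_and_determinism(self):
        cfg = sd.SimulationConfig(seed=5, scaffold_lengths=(1_000_000,), gc=0.47)
        a = sd.make_ancestor(cfg)
        b = sd.make_ancestor(cfg)
        assert a.records[0].residues == b.records[0].residues
        s = a.records[0].residues
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 0.47) < 0.002

    def test_extreme_gc(self):
        cfg = sd.SimulationConfig(seed=1, scaffold_lengths=(5000,), gc=0.999999)
        s = sd.make_ancestor(cfg).records[0].residues
        assert set(s) <= {"G", "C"}

    def test_zero_length_scaffold_rejected(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(seed=1, scaffold_lengths=(0,))


class TestEvolve:
    def test_jc_conversion_identity(self):
        # p = (3/4)(1 - exp(-4d/3))
        assert jc_p_from_d(0.073) == pytest.approx(0.0695598, abs=5e-7)
        assert sd.jc_d_from_p(jc_p_from_d(0.2)) == pytest.approx(0.2, rel=1e-12)

    def test_zero_divergence_is_identity(self):
        cfg = sd.SimulationConfig(seed=2, scaffold_lengths=(10_000,),
                                  divergence_d=0.0)
        anc = sd.make_ancestor(cfg)
        der, truth = sd.evolve(anc, cfg)
        assert der.records[0].residues == anc.records[0].residues
        assert truth.n_substitutions == 0

    def test_jc_distance_regime(self):
        # d=0.073 -> planted fraction 0.0703 within binomial error at 1 Mb
        cfg = sd.SimulationConfig(seed=3, scaffold_lengths=(1_000_000,),
                                  divergence_d=0.073)
        anc = sd.make_ancestor(cfg)
        _, truth = sd.evolve(anc, cfg)
        p = jc_p_from_d(0.073)
        se = math.sqrt(p * (1 - p) / truth.mapped_sites)
        assert abs(truth.planted_fraction - p) < 3 * se

    def test_conservation_exact(self, small_pair):
        anc, der, truth = small_pair
        assert truth.count_mismatch_columns(anc, der) == truth.n_substitutions

    def test_conservation_with_indels_and_n_runs(self):
        cfg = sd.SimulationConfig(seed=8, scaffold_lengths=(100_000,),
                                  difference_p=0.03, indel_rate=1e-4,
                                  n_run_rate=1e-5, n_run_mean_len=30)
        anc = sd.make_ancestor(cfg)
        der, truth = sd.evolve(anc, cfg)
        assert truth.count_mismatch_columns(anc, der) == truth.n_substitutions
        t = truth.scaffolds["scaffold_1"]
        assert np.all(np.diff(t.seg_anc) > 0) and np.all(np.diff(t.seg_der) > 0)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(seed=1, difference_p=0.8)

    def test_exactly_one_divergence_knob(self):
        cfg = sd.SimulationConfig(seed=1, scaffold_lengths=(100,),
                                  divergence_d=0.1, difference_p=0.1)
        with pytest.raises(ValueError, match="exactly one"):
            cfg.resolved_p()


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self):
        cfg = sd.SimulationConfig(seed=4, base_coverage=5, read_error_rate=0.0)
        plan = [sd.RepliconSpec(name="c", length=5000, circular=True)]
        reads, truth, seqs = sd.simulate_reads(plan, cfg)
        doubled = seqs["c"].residues * 2
        rc = sd.kr.__dict__  # noqa: F841  (namespace warm-up not needed)
        from straindiverge.seqarray import revcomp_str
        doubled_rc = revcomp_str(seqs["c"].residues) * 2
        for r in reads:
            assert r.bases in doubled or r.bases in doubled_rc

    def test_depth_matches_coverage(self):
        cfg = sd.SimulationConfig(seed=4, base_coverage=30, read_error_rate=0.0)
        plan = [sd.RepliconSpec(name="c", length=100_000)]
        _, truth, _ = sd.simulate_reads(plan, cfg)
        depth = depth_profile(truth, plan[0], cfg.read_length)
        interior = depth[200:-200]
        assert abs(interior.mean() - 30) / 30 < 0.05

    def test_depth_linearity_in_copy_number(self):
        # realized depth proportional to copy number (slope within 5%)
        cfg = sd.SimulationConfig(seed=6, base_coverage=20, read_error_rate=0.0)
        plan = [sd.RepliconSpec(name="n", length=50_000, copy_number=1),
                sd.RepliconSpec(name="m", length=20_000, copy_number=10,
                                circular=True),
                sd.RepliconSpec(name="r", length=10_000, copy_number=100,
                                circular=True)]
        _, truth, _ = sd.simulate_reads(plan, cfg)
        d = sd.median_depths(truth, plan, cfg.read_length)
        assert abs(d["m"] / d["n"] - 10) / 10 < 0.05
        assert abs(d["r"] / d["n"] - 100) / 100 < 0.05

    def test_read_longer_than_replicon_rejected(self):
        cfg = sd.SimulationConfig(seed=1, read_length=115)
        with pytest.raises(ValueError, match="read_length"):
            sd.simulate_reads([sd.RepliconSpec(name="x", length=50)], cfg)

    def test_determinism(self):
        cfg = sd.SimulationConfig(seed=9, base_coverage=3)
        plan = [sd.RepliconSpec(name="c", length=2000)]
        r1, t1, _ = sd.simulate_reads(plan, cfg)
        r2, t2, _ = sd.simulate_reads(plan, cfg)
        assert [x.bases for x in r1] == [x.bases for x in r2]
        assert t1.equals(t2)


class TestPlantGenes:
    def test_architecture_statistics_recovered(self, planted_annotation):
        planted, cfg = planted_annotation
        stats = sd.annotation_stats(planted.models, planted.assembly)
        assert stats.genes == 200
        assert abs(stats.introns_per_gene - 7.5) / 7.5 < 0.10
        assert abs(stats.mean_intron_len - 110) / 110 < 0.10
        assert abs(stats.mean_exon_len - 199) / 199 < 0.10

    def test_all_planted_cds_extractable(self, planted_annotation):
        planted, _ = planted_annotation
        by_id = {c.id: c.residues for c in planted.cds}
        for m in planted.models:
            assert m.spliced_cds(planted.assembly) == by_id[m.gene_id]

    def test_degenerate_intron_distribution_gives_single_exon_genes(self):
        cfg = sd.SimulationConfig(seed=11, scaffold_lengths=(200_000,),
                                  n_genes=50, ipg_mean=0.0)
        planted = sd.plant_genes(sd.make_ancestor(cfg), cfg)
        stats = sd.annotation_stats(planted.models, planted.assembly)
        assert stats.pct_ilg == 100.0
        assert stats.introns_per_gene == 0.0

    def test_noncanonical_fraction_planted(self):
        cfg = sd.SimulationConfig(seed=12, scaffold_lengths=(2_000_000,),
                                  n_genes=300, noncanonical_fraction=0.2)
        planted = sd.plant_genes(sd.make_ancestor(cfg), cfg)
        frac_truth = 1.0 - planted.truth["canonical"].mean()
        se = math.sqrt(0.2 * 0.8 / 300)
        assert abs(frac_truth - 0.2) < 3 * se

    def test_overfull_plan_rejected(self):
        cfg = sd.SimulationConfig(seed=13, scaffold_lengths=(5_000,), n_genes=100)
        with pytest.raises(ValueError, match="does not fit"):
            sd.plant_genes(sd.make_ancestor(cfg), cfg)


class TestMakeHitTables:
    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            sd.make_hit_tables({"A": ["a1"], "B": ["b1"]},
                               [{"A": "a1", "B": "zzz"}], [], seed=1)

    def test_empty_ortholog_map_gives_only_decoys(self):
        tabs = sd.make_hit_tables({"A": [f"a{i}" for i in range(5)],
                                   "B": [f"b{i}" for i in range(5)]},
                                  [], [], seed=2)
        assert all(h.evalue > 1e-40 for h in tabs.cross[("A", "B")])
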