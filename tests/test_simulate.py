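"""Generator contracts: determinism, planted truth, marginal statistics."""

import numpy as np
import pandas as pd
import pytest

from cachexnet.motifs import MotifModel, extract_promoters
from cachexnet.simulate import (
    SimulationConfig,
    embed_promoters_in_genome,
    sierpinski_carpet,
    simulate_fractal_image,
    simulate_paired_counts,
    simulate_promoters,
    simulate_target_tables,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_control": 1},
            {"n_case": 1},
            {"frac_de": 0.6},
            {"frac_de": -0.1},
            {"lfc_sd_uniform": -1},
            {"dispersion": -0.5},
            {"n_genes": 2.5},
            {"library_size_range": (0, 1e6)},
            {"motif_plant_rate": 1.5},
        ],
    )
    def test_rejects_out_of_range(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestPairedCounts:
    def test_same_seed_identical_outputs(self, small_config):
        a_mrna, a_mirna, a_truth = simulate_paired_counts(small_config)
        b_mrna, b_mirna, b_truth = simulate_paired_counts(small_config)
        pd.testing.assert_frame_equal(a_mrna.counts, b_mrna.counts)
        pd.testing.assert_frame_equal(a_mirna.counts, b_mirna.counts)
        assert a_truth.target_pairs == b_truth.target_pairs

    def test_different_seeds_differ(self, small_config):
        other = SimulationConfig(seed=small_config.seed + 1, n_genes=600, n_mirnas=80)
        a, _, _ = simulate_paired_counts(small_config)
        b, _, _ = simulate_paired_counts(other)
        assert not a.counts.equals(b.counts)

    def test_frac_de_zero_plants_nothing(self):
        cfg = SimulationConfig(seed=3, n_genes=200, n_mirnas=20,
                               frac_de=0.0, frac_de_mirna=0.0)
        _, _, truth = simulate_paired_counts(cfg)
        assert truth.genes_of("up") == [] and truth.genes_of("down") == []
        assert (truth.mirna_de_status == "null").all()
        assert truth.target_pairs == set()
        assert (truth.true_log2fc.values == 0).all()

    def test_zero_uniform_sd_gives_constant_lfc(self):
        cfg = SimulationConfig(seed=3, n_genes=300, n_mirnas=20,
                               lfc_sd_uniform=0.0)
        _, _, truth = simulate_paired_counts(cfg)
        uniform = truth.genes_of("up", "uniform") + truth.genes_of("down", "uniform")
        assert uniform
        lfc = truth.true_log2fc.loc[uniform]
        assert (lfc.nunique(axis=1) == 1).all()

    def test_target_pairs_have_opposite_signs(self, small_simulation):
        _, _, truth = small_simulation
        assert truth.target_pairs
        for m, g in truth.target_pairs:
            assert {truth.mirna_de_status[m], truth.de_status[g]} == {"up", "down"}

    def test_regulation_class_only_for_de_genes(self, small_simulation):
        _, _, truth = small_simulation
        has_class = truth.regulation_class.notna()
        is_de = truth.de_status != "null"
        assert (has_class == is_de).all()

    def test_null_gene_dispersion_matches_config(self):
        # equal library sizes so null-gene means are flat across samples
        cfg = SimulationConfig(seed=5, n_genes=4000, n_mirnas=20,
                               dispersion=0.1, library_size_range=(1e6, 1e6))
        cm, _, truth = simulate_paired_counts(cfg)
        null = truth.genes_of("null")
        x = cm.counts.loc[null].values
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        keep = m > 50  # excess term dominated by noise at low counts
        alpha_hat = np.mean((v[keep] - m[keep]) / m[keep] ** 2)
        assert 0.07 < alpha_hat < 0.13

    def test_subgroup_mode_plants_attenuated_samples(self, subgroup_simulation):
        _, _, truth = subgroup_simulation
        assert truth.subgroup_samples == ["L2", "L3", "L4"]
        variable = truth.genes_of("up", "variable")
        lfc = truth.true_log2fc.loc[variable]
        responders = [s for s in lfc.columns if s not in truth.subgroup_samples]
        assert (
            lfc[responders].mean(axis=1) > lfc[truth.subgroup_samples].mean(axis=1)
        ).all()


class TestPromoters:
    def make(self, plant_rate, seed=2, n=40):
        cfg = SimulationConfig(seed=seed, motif_plant_rate=plant_rate)
        genes = [f"g{i}" for i in range(n)]
        motif = MotifModel.from_consensus("GGGACTTTCC")
        return genes, motif, cfg

    def test_forced_planting_inserts_consensus(self):
        genes, motif, cfg = self.make(1.0)
        ps, planted = simulate_promoters(genes, {"g1"}, motif, cfg)
        assert planted == {"g1"}
        assert motif.consensus in ps.sequences["g1"]

    def test_one_record_per_gene(self):
        genes, motif, cfg = self.make(0.5)
        ps, _ = simulate_promoters(genes, set(), motif, cfg)
        assert ps.genes == genes
        assert all(len(s) == 350 for s in ps.sequences.values())

    def test_motif_longer_than_promoter_rejected(self):
        genes, _, cfg = self.make(1.0)
        long_motif = MotifModel.from_consensus("A" * 400)
        with pytest.raises(ValueError, match="longer than promoter"):
            simulate_promoters(genes, set(), long_motif, cfg, length=350)

    def test_background_kmer_count_matches_closed_form(self):
        # without planting, consensus occurrences follow the i.i.d. base
        # model: E = n_seqs * (L - w + 1) * prod(base freq)
        cfg = SimulationConfig(seed=9, motif_plant_rate=0.0)
        genes = [f"g{i}" for i in range(1500)]
        motif = MotifModel.from_consensus("ACGT")
        gc = 0.42
        ps, planted = simulate_promoters(genes, set(genes), motif, cfg, gc=gc)
        assert planted == set()
        count = sum(
            s.count("ACGT") for s in ps.sequences.values()
        )
        p_word = ((1 - gc) / 2) ** 2 * (gc / 2) ** 2
        expect = len(genes) * (350 - 4 + 1) * p_word
        sd = np.sqrt(expect)
        assert abs(count - expect) < 5 * sd

    def test_genome_embedding_roundtrip(self):
        genes, motif, cfg = self.make(1.0, n=12)
        ps, _ = simulate_promoters(genes, set(genes), motif, cfg)
        genome, bed = embed_promoters_in_genome(ps, cfg)
        extracted = extract_promoters(bed, genome)
        assert extracted.sequences == ps.sequences
        assert set(bed["strand"]) == {"+", "-"}


class TestTargetTables:
    def test_no_decoys_union_equals_truth(self, small_simulation):
        _, _, truth = small_simulation
        cfg = SimulationConfig(seed=7, n_genes=600, n_mirnas=80)
        tm = simulate_target_tables(truth, cfg, decoy_rate=0.0)
        assert tm.union() == truth.target_pairs
        assert tm.validated == {"validated"}

    def test_single_source_holds_every_pair(self, small_simulation):
        _, _, truth = small_simulation
        cfg = SimulationConfig(seed=7, n_genes=600, n_mirnas=80)
        tm = simulate_target_tables(truth, cfg, n_sources=1, decoy_rate=0.0)
        assert tm.sources["pred1"] == truth.target_pairs

    def test_decoys_only_among_null_genes(self, small_simulation):
        _, _, truth = small_simulation
        cfg = SimulationConfig(seed=7, n_genes=600, n_mirnas=80)
        tm = simulate_target_tables(truth, cfg, decoy_rate=0.5)
        decoys = tm.union() - truth.target_pairs
        assert decoys
        assert all(truth.de_status[g] == "null" for _, g in decoys)


class TestImages:
    def test_carpet_depth3_pixel_count(self):
        img, dim = simulate_fractal_image("sierpinski_carpet", 3)
        assert img.mask.shape == (27, 27)
        assert img.mask.sum() == 512
        assert dim == pytest.approx(np.log(8) / np.log(3))

    def test_carpet_recursion_is_self_similar(self):
        c2 = sierpinski_carpet(2)
        c3 = sierpinski_carpet(3)
        assert c3[:9, :9].sum() == 8 * c2[:3, :3].sum()

    def test_filled_square_all_foreground(self):
        img, dim = simulate_fractal_image("filled", 64)
        assert img.foreground_fraction == 1.0
        assert dim == 2.0

    def test_random_fiber_fraction(self, rng):
        img, _ = simulate_fractal_image(
            "random_fiber", 256, area_fraction=0.25, rng=rng
        )
        assert abs(img.foreground_fraction - 0.25) < 0.02

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown image kind"):
            simulate_fractal_image("blob", 8)
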