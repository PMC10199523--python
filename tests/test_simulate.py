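"""Synthetic genome, pedigree, haplotype, gene-drop and trait generation."""

import numpy as np
import pandas as pd
import pytest

from radseq_gs.genome import GenomeAssembly
from radseq_gs.simulate import (
    ChromosomePlan,
    MatingPlan,
    SimConfig,
    TraitPlan,
    UNKNOWN_PARENT,
    default_config,
    gene_drop,
    sample_hd_panel,
    simulate_all,
    simulate_founder_haplotypes,
    simulate_genome,
    simulate_pedigree,
    simulate_traits,
)

from conftest import small_config


def one_chrom_config(length=10_000, gc=0.5, seed=1, **kw):
    cfg = SimConfig(
        seed=seed,
        chromosome_plan=[ChromosomePlan("c", "macro", length, gc)],
        n_founders=kw.pop("n_founders", 10),
        **kw,
    )
    return cfg


class TestGenome:
    def test_length_and_gc_within_band(self):
        g = simulate_genome(one_chrom_config())
        assert g.length("c") == 10_000
        assert 0.48 <= g.gc_content("c") <= 0.52

    def test_same_seed_identical_sequences(self):
        g1 = simulate_genome(one_chrom_config())
        g2 = simulate_genome(one_chrom_config())
        assert g1.sequences == g2.sequences

    def test_micro_gc_exceeds_macro_gc(self):
        cfg = SimConfig(
            seed=3,
            chromosome_plan=[
                ChromosomePlan("macro1", "macro", 2_000_000, 0.40),
                ChromosomePlan("micro1", "micro", 200_000, 0.55),
            ],
            n_founders=4,
        )
        g = simulate_genome(cfg)
        assert g.gc_content("micro1") > g.gc_content("macro1")

    def test_invalid_gc_raises(self):
        with pytest.raises(ValueError, match="GC"):
            simulate_genome(one_chrom_config(gc=1.2))

    def test_micro_longer_than_macro_rejected(self):
        cfg = SimConfig(
            seed=0,
            chromosome_plan=[
                ChromosomePlan("m", "macro", 100_000, 0.4),
                ChromosomePlan("u", "micro", 200_000, 0.5),
            ],
            n_founders=4,
        )
        with pytest.raises(ValueError, match="shorter"):
            cfg.validate()


class TestPedigree:
    def test_founders_have_unknown_parents_and_counts_add_up(self):
        cfg = one_chrom_config(
            n_founders=10, generations=2, mating=MatingPlan(2, 5, 4)
        )
        ped = simulate_pedigree(cfg)
        assert len(ped) == 30
        founders = ped[ped["generation"] == 0]
        assert (founders["sire"] == UNKNOWN_PARENT).all()
        assert (founders["dam"] == UNKNOWN_PARENT).all()
        g1 = ped[ped["generation"] == 1]
        assert len(g1) == 20
        assert g1["sire"].isin(founders["id"]).all()
        assert g1["dam"].isin(founders["id"]).all()

    def test_sire_reuse_yields_ten_plus_offspring(self):
        cfg = one_chrom_config(
            n_founders=50, generations=2, mating=MatingPlan(5, 20, 3)
        )
        ped = simulate_pedigree(cfg)
        per_sire = ped[ped["generation"] == 1]["sire"].value_counts()
        assert (per_sire >= 10).any()

    def test_infeasible_plan_raises(self):
        cfg = one_chrom_config(
            n_founders=4, generations=2, mating=MatingPlan(10, 10, 2)
        )
        with pytest.raises(ValueError, match="infeasible"):
            simulate_pedigree(cfg)


class TestFounderHaplotypes:
    def test_shapes_and_alphabet(self):
        cfg = one_chrom_config(n_founders=2, marker_density=500.0)
        genome = simulate_genome(cfg)
        haps, markers = simulate_founder_haplotypes(genome, cfg)
        assert haps["c"].shape == (2, 2, len(markers))
        assert set(np.unique(haps["c"])) <= {0, 1}
        assert markers["pos"].is_monotonic_increasing

    def test_ld_decays_with_distance(self):
        cfg = SimConfig(
            seed=5,
            chromosome_plan=[ChromosomePlan("c", "macro", 2_000_000, 0.45)],
            n_founders=400,
            marker_density=200.0,
            ld_decay_bp=50_000.0,
        )
        genome = simulate_genome(cfg)
        haps, markers = simulate_founder_haplotypes(genome, cfg)
        flat = haps["c"].reshape(-1, len(markers)).astype(float)
        pos = markers["pos"].to_numpy()
        r2 = np.corrcoef(flat, rowvar=False) ** 2
        iu = np.triu_indices(len(pos), k=1)
        dist = np.abs(pos[iu[1]] - pos[iu[0]])
        vals = r2[iu]
        near = vals[(dist > 0) & (dist <= cfg.ld_decay_bp)]
        far = vals[dist >= 5 * cfg.ld_decay_bp]
        assert np.nanmean(near) > np.nanmean(far)

    def test_zero_ld_limit_behaves_like_independent_markers(self):
        cfg = SimConfig(
            seed=6,
            chromosome_plan=[ChromosomePlan("c", "macro", 500_000, 0.45)],
            n_founders=300,
            marker_density=100.0,
            ld_decay_bp=0.0,
        )
        genome = simulate_genome(cfg)
        haps, markers = simulate_founder_haplotypes(genome, cfg)
        flat = haps["c"].reshape(-1, len(markers)).astype(float)
        r = np.corrcoef(flat, rowvar=False)
        adj = np.array([r[i, i + 1] for i in range(len(markers) - 1)])
        # adjacent-marker correlation within 3 SE of zero on average
        se = 1 / np.sqrt(flat.shape[0])
        assert abs(np.nanmean(adj)) < 3 * se / np.sqrt(len(adj))

    def test_excessive_marker_density_raises(self):
        cfg = one_chrom_config(length=100, marker_density=2e7)
        genome = simulate_genome(cfg)
        with pytest.raises(ValueError, match="density"):
            simulate_founder_haplotypes(genome, cfg)


class TestGeneDrop:
    def setup_drop(self, recombination_rate, seed=7):
        cfg = one_chrom_config(
            length=500_000,
            n_founders=10,
            generations=3,
            mating=MatingPlan(2, 4, 3),
            marker_density=100.0,
            seed=seed,
        )
        genome = simulate_genome(cfg)
        ped = simulate_pedigree(cfg)
        fh, markers = simulate_founder_haplotypes(genome, cfg)
        haps = gene_drop(ped, fh, markers, recombination_rate, seed=seed)
        return cfg, ped, fh, markers, haps

    def test_zero_recombination_copies_a_parental_haplotype(self):
        _, ped, _, markers, haps = self.setup_drop(0.0)
        row_of = {i: k for k, i in enumerate(ped["id"])}
        h = haps["c"]
        for rec in ped.itertuples(index=False):
            if rec.sire == UNKNOWN_PARENT:
                continue
            for which, parent in enumerate((rec.sire, rec.dam)):
                child = h[row_of[rec.id], which]
                par = h[row_of[parent]]
                assert (child == par[0]).all() or (child == par[1]).all()

    def test_transmitted_allele_always_from_parent(self):
        _, ped, _, markers, haps = self.setup_drop(1e-6)  # many crossovers
        row_of = {i: k for k, i in enumerate(ped["id"])}
        h = haps["c"]
        for rec in ped.itertuples(index=False):
            if rec.sire == UNKNOWN_PARENT:
                continue
            for which, parent in enumerate((rec.sire, rec.dam)):
                child = h[row_of[rec.id], which]
                par = h[row_of[parent]]
                ok = (child == par[0]) | (child == par[1])
                assert ok.all()

    def test_mendelian_consistency_full_population(self, sim_small):
        ped = sim_small.pedigree
        codes = sim_small.genotypes.codes
        row_of = {i: k for k, i in enumerate(ped["id"])}
        for rec in ped.itertuples(index=False):
            if rec.sire == UNKNOWN_PARENT:
                continue
            off = codes[row_of[rec.id]]
            s = codes[row_of[rec.sire]]
            d = codes[row_of[rec.dam]]
            assert not (((off == 0) & ((s == 2) | (d == 2)))
                        | ((off == 2) & ((s == 0) | (d == 0)))).any()

    def test_negative_rate_rejected(self):
        _, ped, fh, markers, _ = self.setup_drop(0.0)
        with pytest.raises(ValueError):
            gene_drop(ped, fh, markers, -1.0)


@pytest.fixture(scope="module")
def big_population():
    cfg = SimConfig(
        seed=21,
        chromosome_plan=[ChromosomePlan("c", "macro", 300_000, 0.45)],
        n_founders=200,
        generations=4,
        mating=MatingPlan(20, 100, 6),
        marker_density=400.0,
        ld_decay_bp=50_000.0,
        trait_plan=[TraitPlan("T", 0.4, batch_sd=0.0)],
    )
    return simulate_all(cfg)


class TestTraits:
    def test_h2_one_no_fixed_effects_phenotype_equals_mean_plus_tbv(self, sim_small):
        plan = [TraitPlan("pure", 1.0, mean=5.0, batch_sd=0.0)]
        phen, tbv = simulate_traits(
            sim_small.genotypes, sim_small.pedigree, plan, seed=9
        )
        merged = phen.merge(tbv, on="individual")
        assert np.allclose(merged["value"], 5.0 + merged["pure"])

    def test_regression_of_phenotype_on_tbv_near_unit_slope(self, big_population):
        phen = big_population.phenotypes
        tbv = big_population.true_breeding_values
        merged = phen.merge(tbv, on="individual")
        assert len(merged) >= 2000
        slope = np.polyfit(merged["T"], merged["value"], 1)[0]
        assert 0.8 <= slope <= 1.2

    def test_heritability_recovered_in_phenotypic_variance(self, big_population):
        phen = big_population.phenotypes
        tbv = big_population.true_breeding_values
        ratio = tbv["T"].var() / phen["value"].var()
        assert abs(ratio - 0.4) < 0.1

    def test_identical_genotypes_identical_tbv(self, sim_small):
        gm = sim_small.genotypes
        dup = gm.codes.copy()
        dup[1] = dup[0]  # clone individual 0 into row 1
        from radseq_gs.qc import GenotypeMatrix

        gm2 = GenotypeMatrix(gm.individuals, gm.markers, dup)
        _, tbv = simulate_traits(
            gm2, sim_small.pedigree, [TraitPlan("T", 0.5)], seed=4
        )
        assert tbv["T"].iloc[0] == tbv["T"].iloc[1]


class TestPanel:
    def test_full_fraction_returns_all_markers(self, sim_small):
        panel = sample_hd_panel(sim_small.markers, 1.0, seed=1)
        assert len(panel) == len(sim_small.markers)

    def test_half_fraction_subset_of_markers(self, sim_small):
        panel = sample_hd_panel(sim_small.markers, 0.5, seed=1)
        assert len(panel) == round(0.5 * len(sim_small.markers))
        assert panel.isin(sim_small.markers["marker_id"]).all()

    def test_different_seeds_overlap_about_half(self, sim_small):
        p1 = set(sample_hd_panel(sim_small.markers, 0.5, seed=1))
        p2 = set(sample_hd_panel(sim_small.markers, 0.5, seed=2))
        frac = len(p1 & p2) / len(p1)
        assert 0.35 < frac < 0.65

    def test_empty_panel_rejected(self, sim_small):
        with pytest.raises(ValueError):
            sample_hd_panel(sim_small.markers, 1e-9, seed=1)


class TestDeterminism:
    def test_identical_config_identical_outputs(self):
        cfg = small_config(seed=33)
        a = simulate_all(cfg)
        b = simulate_all(small_config(seed=33))
        assert a.genome.sequences == b.genome.sequences
        pd.testing.assert_frame_equal(a.pedigree, b.pedigree)
        pd.testing.assert_frame_equal(a.markers, b.markers)
        assert all(
            np.array_equal(a.haplotypes[c], b.haplotypes[c]) for c in a.haplotypes
        )
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert list(a.hd_panel) == list(b.hd_panel)

    def test_genotypes_equal_haplotype_sums(self, sim_small):
        codes = np.concatenate(
            [sim_small.haplotypes[c].sum(axis=1)
             for c in sim_small.markers["chrom"].unique()],
            axis=1,
        )
        assert (codes == sim_small.genotypes.codes).all()
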