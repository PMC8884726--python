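"""Simulator: meiosis, segregation, counts model, pooled reads, GO fixture."""

import numpy as np
import pandas as pd
import pytest

from asemap.sim import (
    STRAIN_A,
    STRAIN_B,
    ConfigError,
    CrossConfig,
    EmbryoGenome,
    HaplotypeCopy,
    simulate_counts,
    simulate_embryos,
    simulate_go,
    simulate_incross,
    simulate_meiosis,
    simulate_parents,
    simulate_pool_sites,
)

L = 10_000_000


def het_parent(n_chrom=1, length=L):
    chroms = [
        (HaplotypeCopy.uniform(length, STRAIN_A), HaplotypeCopy.uniform(length, STRAIN_B))
        for _ in range(n_chrom)
    ]
    return EmbryoGenome(chroms)


class TestMeiosis:
    def test_zero_map_length_gives_intact_parental_copy(self, rng):
        gamete = simulate_meiosis(het_parent(), 0.0, rng)
        assert len(gamete[0].breaks) == 1
        assert gamete[0].labels[0] in (STRAIN_A, STRAIN_B)

    def test_negative_map_length_rejected(self, rng):
        with pytest.raises(ConfigError):
            simulate_meiosis(het_parent(), -0.5, rng)

    def test_crossover_count_is_poisson_with_map_length_mean(self, rng):
        # parent copies are pure A / pure B, so every crossover is visible
        parent = het_parent()
        n = 10_000
        counts = np.array(
            [len(simulate_meiosis(parent, 1.0, rng)[0].breaks) - 1 for _ in range(n)]
        )
        se = np.sqrt(1.0 / n)  # Poisson(1) mean has SD 1
        assert abs(counts.mean() - 1.0) < 3 * se

    def test_mendelian_transmission_at_mid_chromosome(self, rng):
        parent = het_parent()
        n = 10_000
        hits = sum(
            simulate_meiosis(parent, 1.0, rng)[0].strain_at([L // 2])[0] == STRAIN_B
            for _ in range(n)
        )
        se = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * se

    def test_gamete_segments_cover_chromosome(self, rng):
        parent = het_parent()
        for _ in range(50):
            copy = simulate_meiosis(parent, 2.0, rng)[0]
            segs = copy.segments()
            assert segs[0][0] == 1 and segs[-1][1] == L
            for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
                assert s2 == e1 + 1
            assert all(lab in (STRAIN_A, STRAIN_B) for _, _, lab in segs)

    def test_haldane_linkage_decay_matches_two_locus_oracle(self, rng):
        """Recombinant fraction between two loci follows r = (1 - e^(-2d)) / 2.

        Oracle: the closed-form Haldane map function, checked against the
        fraction of gametes whose alleles at the two loci disagree.
        """
        parent = het_parent()
        pos = np.array([L // 4, 3 * L // 4])  # d = 0.5 Morgans apart on a 1-M chromosome
        d = 0.5
        r_expected = 0.5 * (1.0 - np.exp(-2.0 * d))
        n = 4000
        rec = 0
        for _ in range(n):
            strains = simulate_meiosis(parent, 1.0, rng)[0].strain_at(pos)
            rec += strains[0] != strains[1]
        se = np.sqrt(r_expected * (1 - r_expected) / n)
        assert abs(rec / n - r_expected) < 4 * se


class TestIncross:
    def test_recessive_fraction_near_one_quarter(self):
        cfg = CrossConfig(n_embryos=4000, n_chromosomes=1, n_genes=0,
                          n_snps_per_chrom=0, causal_locus=(0, L // 2),
                          chrom_length=L, seed=3)
        exp = simulate_incross(cfg, include_counts=False, include_pools=False,
                               include_embryo_snps=False)
        frac = exp.mutant.mean()
        se = np.sqrt(0.25 * 0.75 / cfg.n_embryos)
        assert abs(frac - 0.25) < 3 * se

    def test_identical_homozygous_parents_give_identical_embryos(self, rng):
        cfg = CrossConfig(n_embryos=20, n_chromosomes=1, chrom_length=L,
                          n_genes=0, n_snps_per_chrom=0, causal_locus=None, seed=0)
        mono = EmbryoGenome([(HaplotypeCopy.uniform(L, STRAIN_A),
                              HaplotypeCopy.uniform(L, STRAIN_A))])
        genomes, _ = simulate_embryos(cfg, rng, parents=(mono, mono))
        pos = np.linspace(1, L, 50).astype(int)
        for g in genomes:
            assert (g.n_b_alleles(0, pos) == 0).all()

    def test_zero_map_length_transmits_intact_haplotypes(self, rng):
        cfg = CrossConfig(n_embryos=10, n_chromosomes=2, map_length=0.0,
                          n_genes=0, n_snps_per_chrom=0, causal_locus=(0, 100), seed=1)
        genomes, _ = simulate_embryos(cfg, rng)
        for g in genomes:
            for c1, c2 in g.chromosomes:
                assert len(c1.breaks) == 1 and len(c2.breaks) == 1

    def test_mendelian_ratio_at_unlinked_locus(self):
        cfg = CrossConfig(n_embryos=3000, n_chromosomes=2, n_genes=0,
                          n_snps_per_chrom=0, causal_locus=(0, 12_500_000), seed=9)
        exp = simulate_incross(cfg, include_counts=False, include_pools=False,
                               include_embryo_snps=False)
        # locus on the other chromosome, unlinked to selection
        doses = np.array([g.n_b_alleles(1, [12_500_000])[0] for g in exp.genomes])
        freqs = np.bincount(doses, minlength=3) / len(doses)
        expected = np.array([0.25, 0.5, 0.25])
        se = np.sqrt(expected * (1 - expected) / len(doses))
        assert (np.abs(freqs - expected) < 4 * se).all()

    def test_identical_seed_reproduces_experiment_exactly(self):
        cfg = CrossConfig(n_embryos=30, n_chromosomes=2, n_genes=60,
                          n_snps_per_chrom=60, seed=17)
        a = simulate_incross(cfg)
        b = simulate_incross(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.pool_sites, b.pool_sites)
        pd.testing.assert_frame_equal(a.embryo_snp_calls, b.embryo_snp_calls)
        assert (a.mutant == b.mutant).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            CrossConfig(n_embryos=0)
        with pytest.raises(ConfigError):
            CrossConfig(causal_locus=(9, 1))
        with pytest.raises(ConfigError):
            CrossConfig(frac_ase_genes=1.5)
        with pytest.raises(ConfigError):
            CrossConfig(baseline_mean=-1)


class TestCountsModel:
    def make_genomes(self):
        """Three embryos: hom-A, het, hom-B on one chromosome."""
        a = HaplotypeCopy.uniform(L, STRAIN_A)
        b = HaplotypeCopy.uniform(L, STRAIN_B)
        return [EmbryoGenome([(a, a)]), EmbryoGenome([(a, b)]), EmbryoGenome([(b, b)])]

    def gene_table(self, cis):
        return pd.DataFrame(
            {"chrom": "1", "start": [L // 2], "chrom_idx": [0],
             "cis_effect": [cis], "is_ase": [cis != 0], "trans_effect": [0.0]},
            index=pd.Index(["g0"], name="gene_id"),
        )

    def test_null_cis_effect_equal_expectation_across_genotypes(self, rng):
        cfg = CrossConfig(n_chromosomes=1, chrom_length=L, n_genes=1,
                          causal_locus=None, baseline_mean=100_000, dispersion=0.0, seed=0)
        counts = simulate_counts(self.make_genomes(), self.gene_table(0.0), cfg, rng)
        vals = counts.iloc[0].to_numpy(dtype=float)
        assert np.allclose(vals / vals[0], 1.0, atol=0.02)

    def test_unit_cis_effect_doubles_homozygote_and_sets_het_mean(self, rng):
        cfg = CrossConfig(n_chromosomes=1, chrom_length=L, n_genes=1,
                          causal_locus=None, baseline_mean=200_000, dispersion=0.0, seed=0)
        counts = simulate_counts(self.make_genomes(), self.gene_table(1.0), cfg, rng)
        hom_a, het, hom_b = counts.iloc[0].to_numpy(dtype=float)
        assert abs(hom_b / hom_a - 2.0) < 0.02          # log2FC = 1
        assert abs(het / hom_a - 1.5) < 0.02            # baseline * (1 + 2) / 2

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ConfigError):
            CrossConfig(dispersion=-0.1)


class TestPools:
    def test_all_het_pool_balance_near_half(self, rng):
        a = HaplotypeCopy.uniform(L, STRAIN_A)
        b = HaplotypeCopy.uniform(L, STRAIN_B)
        genomes = [EmbryoGenome([(a, b)]) for _ in range(40)]
        snp = pd.DataFrame({"chrom": "1", "pos": [L // 2], "alt_strain": [STRAIN_B],
                            "chrom_idx": [0]})
        cfg = CrossConfig(n_chromosomes=1, chrom_length=L, read_depth=5000,
                          causal_locus=None, seed=0)
        sites = simulate_pool_sites(genomes, np.array([True] * 20 + [False] * 20),
                                    snp, cfg, rng)
        bal = sites["alt_mut"][0] / (sites["ref_mut"][0] + sites["alt_mut"][0])
        assert abs(bal - 0.5) < 0.03

    def test_fixed_mutant_pool_balance_tends_to_one(self, rng):
        a = HaplotypeCopy.uniform(L, STRAIN_A)
        b = HaplotypeCopy.uniform(L, STRAIN_B)
        muts = [EmbryoGenome([(b, b)]) for _ in range(20)]
        sibs = [EmbryoGenome([(a, b)]) for _ in range(40)]
        snp = pd.DataFrame({"chrom": "1", "pos": [L // 2], "alt_strain": [STRAIN_B],
                            "chrom_idx": [0]})
        cfg = CrossConfig(n_chromosomes=1, chrom_length=L, read_depth=10_000,
                          causal_locus=None, seed=0)
        sites = simulate_pool_sites(muts + sibs, np.array([True] * 20 + [False] * 40),
                                    snp, cfg, rng)
        bal_mut = sites["alt_mut"][0] / (sites["ref_mut"][0] + sites["alt_mut"][0])
        assert bal_mut > 0.99

    def test_empty_pool_rejected(self, rng):
        a = HaplotypeCopy.uniform(L, STRAIN_A)
        genomes = [EmbryoGenome([(a, a)])]
        snp = pd.DataFrame({"chrom": "1", "pos": [10], "alt_strain": [1], "chrom_idx": [0]})
        cfg = CrossConfig(n_chromosomes=1, chrom_length=L, causal_locus=None, seed=0)
        with pytest.raises(ConfigError):
            simulate_pool_sites(genomes, np.array([True]), snp, cfg, rng)


class TestGoFixture:
    def test_spiked_term_is_strongly_enriched(self, rng):
        from asemap.go import go_enrich

        genes = [f"g{i:05d}" for i in range(500)]
        de = genes[:25]
        ann = simulate_go(500, 20, (10, 30), rng, spiked_terms={"GO:spike": de})
        res = go_enrich(de, genes, ann, alpha=0.05)
        assert res["term_id"].iloc[0] == "GO:spike"
        assert res["pvalue"].iloc[0] < 1e-20

    def test_no_terms_gives_empty_annotation(self, rng):
        ann = simulate_go(100, 0, (5, 10), rng)
        assert ann.empty

    def test_oversized_terms_rejected(self, rng):
        with pytest.raises(ConfigError):
            simulate_go(10, 5, (5, 50), rng)

    def test_null_enrichment_p_values_near_uniform(self, rng):
        """Random DE sets: ~5% of term tests pass unadjusted p < 0.05.

        Hypergeometric p-values are discrete, so the observed fraction sits
        slightly below nominal; the band reflects that.
        """
        from scipy import stats

        genes = np.arange(2000)
        ann = simulate_go(2000, 50, (30, 60), rng)
        term_sizes = ann.groupby("term_id")["gene_id"].nunique()
        frac = []
        for _ in range(200):
            lst = set(rng.choice(2000, 200, replace=False))
            members = ann["gene_id"].str.slice(1).astype(int)
            hits = ann.assign(hit=members.isin(lst)).groupby("term_id")["hit"].sum()
            p = stats.hypergeom.sf(hits - 1, 2000, term_sizes, 200)
            frac.append((p < 0.05).mean())
        assert 0.015 <= np.mean(frac) <= 0.075
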