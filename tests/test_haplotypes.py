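"""Haplotype calling, informative regions, embryo grouping, ASE scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asemap import haplotypes as hp
from asemap.haplotypes import (
    HET,
    HOM_A,
    HOM_B,
    NA,
    NC,
    HaplotypeMap,
    InformativeRegion,
    call_window_haplotype,
    define_informative_regions,
    genotype_embryo_site,
    group_embryos,
    possible_offspring,
    select_informative_snps,
    strain_dosage,
    window_start,
)


class TestInformativeSnps:
    def founder(self, gts, gq=200, depth=50):
        return pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, len(gts) + 1) * 1000,
             "gt": gts, "gq": gq, "depth": depth}
        )

    def test_opposite_homozygotes_retained_with_alt_strain(self):
        out = select_informative_snps(self.founder([0, 2]), self.founder([2, 0]))
        assert len(out) == 2
        assert out["alt_strain"].tolist() == [1, 0]  # alt rides B then A

    def test_heterozygous_founders_removed(self):
        out = select_informative_snps(self.founder([1]), self.founder([1]))
        assert out.empty

    def test_low_mean_depth_removed(self):
        a = self.founder([0], depth=8)
        b = self.founder([2], depth=10)
        assert select_informative_snps(a, b).empty  # mean depth 9 < 10

    def test_low_genotype_quality_removed(self):
        out = select_informative_snps(self.founder([0], gq=50), self.founder([2]))
        assert out.empty

    def test_disjoint_positions_rejected(self):
        a = self.founder([0])
        b = self.founder([2])
        b["pos"] += 7
        with pytest.raises(ValueError):
            select_informative_snps(a, b)


class TestSiteGenotyping:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [(10, 0, 0), (6, 6, 1), (0, 10, 2), (1, 9, 2), (2, 1, NA), (2, 8, NA)],
    )
    def test_threshold_rules(self, ref, alt, expected):
        assert genotype_embryo_site(ref, alt, min_depth=5) == expected

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            genotype_embryo_site(-1, 5)

    def test_strain_conversion_respects_alt_polarity(self):
        # alt on strain B keeps dosage; alt on strain A mirrors it
        assert strain_dosage([0, 1, 2], [1, 1, 1]).tolist() == [0, 1, 2]
        assert strain_dosage([0, 1, 2], [0, 0, 0]).tolist() == [2, 1, 0]
        assert strain_dosage([NA], [1])[0] == NA


class TestWindowCall:
    def test_unanimous_and_majority(self):
        assert call_window_haplotype([HET] * 10) == HET
        assert call_window_haplotype([HOM_A] * 6 + [HET] * 4) == HOM_A

    def test_tie_and_min_calls_give_na(self):
        assert call_window_haplotype([HOM_A] * 5 + [HET] * 5) == NA
        assert call_window_haplotype([HET] * 3) == NA

    def test_inconsistent_with_parents_gives_nc(self):
        assert call_window_haplotype([HOM_B] * 8, possible={HOM_A, HET}) == NC

    def test_window_tiling_is_bijective(self):
        pos = np.array([1, 999_999, 1_000_000, 1_000_001, 5_500_000])
        starts = window_start(pos)
        assert starts.tolist() == [1, 1, 1, 1_000_001, 5_000_001]
        # each position lies inside its window
        assert ((pos >= starts) & (pos <= starts + 999_999)).all()


class TestPossibleOffspring:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (HOM_A, HOM_A, {HOM_A}),
            (HOM_A, HET, {HOM_A, HET}),
            (HET, HET, {HOM_A, HET, HOM_B}),
            (HOM_A, HOM_B, {HET}),
            (HOM_B, HET, {HET, HOM_B}),
        ],
    )
    def test_genotype_algebra(self, p1, p2, expected):
        assert possible_offspring(p1, p2) == expected

    def test_uncalled_parent_yields_empty(self):
        assert possible_offspring(NA, HET) == frozenset()


def region(possible, n_windows=6, chrom="1"):
    starts = [1 + i * 1_000_000 for i in range(n_windows)]
    return InformativeRegion(chrom, starts[0], starts[-1] + 999_999, starts,
                             frozenset(possible))


def hap_map_from_rows(rows, chrom="1"):
    n_windows = len(rows[0])
    cols = pd.MultiIndex.from_tuples(
        [(chrom, 1 + i * 1_000_000) for i in range(n_windows)],
        names=["chrom", "window_start"],
    )
    frame = pd.DataFrame(rows, columns=cols,
                         index=pd.Index([f"e{i}" for i in range(len(rows))], name="embryo"))
    return HaplotypeMap(frame.astype(np.int8))


class TestGroupEmbryos:
    def test_pure_and_majority_rules(self):
        hm = hap_map_from_rows([
            [HET] * 6,                                  # pure heterozygote
            [HOM_A] * 4 + [HET] * 2,                    # recombinant: longest run wins
            [HOM_A, HOM_A, HOM_A, NA, HOM_A, HET],      # NA breaks runs but cannot win
        ])
        out = group_embryos(region({HOM_A, HET, HOM_B}), hm)
        assert out.tolist() == [HET, HOM_A, HOM_A]

    def test_tied_longest_runs_left_unassigned(self):
        hm = hap_map_from_rows([[HOM_A, HOM_A, NA, HET, HET, NA]])
        out = group_embryos(region({HOM_A, HET, HOM_B}), hm)
        assert out.tolist() == [NA]

    def test_calls_outside_possible_ignored(self):
        hm = hap_map_from_rows([[HOM_B, HET, HET, HET, HET, HET]])
        out = group_embryos(region({HOM_A, HET}), hm)  # HOM_B impossible here
        assert out.tolist() == [HET]


class TestInformativeRegions:
    def windows(self, pairs, chrom="1"):
        idx = pd.MultiIndex.from_tuples(
            [(chrom, 1 + i * 1_000_000) for i in range(len(pairs))],
            names=["chrom", "window_start"],
        )
        return pd.DataFrame(pairs, index=idx, columns=["gt_p1", "gt_p2"])

    def full_map(self, n_windows, n_embryos=10, chrom="1"):
        return hap_map_from_rows([[HET] * n_windows] * n_embryos, chrom)

    def test_monomorphic_run_excluded(self):
        pw = self.windows([(HOM_A, HOM_A)] * 4)
        assert define_informative_regions(pw, self.full_map(4)) == []

    def test_het_by_het_run_included_with_three_genotypes(self):
        pw = self.windows([(HET, HET)] * 4)
        regions = define_informative_regions(pw, self.full_map(4))
        assert len(regions) == 1
        assert regions[0].possible == {HOM_A, HET, HOM_B}
        assert len(regions[0].window_starts) == 4

    def test_run_breaks_when_possible_set_changes(self):
        pw = self.windows([(HET, HET), (HET, HET), (HOM_A, HET), (HOM_A, HET)])
        regions = define_informative_regions(pw, self.full_map(4))
        assert [len(r.window_starts) for r in regions] == [2, 2]
        assert regions[1].possible == {HOM_A, HET}

    def test_uncallable_windows_break_regions(self):
        pw = self.windows([(HET, HET)] * 3)
        hm = self.full_map(3)
        hm.calls[("1", 1_000_001)] = NA  # middle window uncallable everywhere
        regions = define_informative_regions(pw, hm, min_callable_fraction=0.8)
        assert [r.window_starts for r in regions] == [[1], [2_000_001]]


class TestOnSimulatedSatCross:
    def test_callable_windows_match_truth(self, sat_experiment, sat_haplotypes):
        """Callable (non-NA) window calls agree with the generating genomes.

        Truth per window is the modal true genotype over the window's
        informative SNP positions — the quantity the majority-vote caller
        estimates (windows containing a breakpoint have no single genotype).
        """
        exp = sat_experiment
        _, hap_map, _ = sat_haplotypes
        snps = exp.snp_table
        total = correct = 0
        for (chrom, wstart) in hap_map.calls.columns:
            ci = int(chrom) - 1
            in_win = snps[
                (snps["chrom"] == chrom)
                & (snps["pos"] >= wstart)
                & (snps["pos"] <= wstart + hap_map.window_size - 1)
            ]
            if in_win.empty:
                continue
            pos = in_win["pos"].to_numpy()
            col = hap_map.calls.columns.get_loc((chrom, wstart))
            for ei, embryo in enumerate(hap_map.embryos):
                call = hap_map.calls.iat[ei, col]
                if call < 0:
                    continue
                doses = exp.genomes[ei].n_b_alleles(ci, pos)
                truth = np.bincount(doses, minlength=3).argmax()
                total += 1
                correct += call == truth
        assert total > 5000
        assert correct / total >= 0.99

    def test_recombination_breakpoints_localised_within_one_window(
        self, sat_experiment, sat_haplotypes
    ):
        """Isolated true breakpoints appear as call changes in an adjacent window."""
        exp = sat_experiment
        _, hap_map, _ = sat_haplotypes
        w = hap_map.window_size
        checked = hits = 0
        for ei, genome in enumerate(exp.genomes):
            for ci, (c1, c2) in enumerate(genome.chromosomes):
                breaks = sorted(
                    set(c1.breaks[:-1].tolist()) | set(c2.breaks[:-1].tolist())
                )
                if len(breaks) != 1:
                    continue  # only isolated, unambiguously visible breakpoints
                bp = breaks[0]
                if bp <= w or bp > exp.config.chrom_length - w:
                    continue  # below window resolution at the chromosome ends
                chrom = str(ci + 1)
                calls = hap_map.calls.loc[
                    hap_map.embryos[ei],
                    hap_map.calls.columns.get_level_values(0) == chrom,
                ]
                starts = calls.index.get_level_values(1).to_numpy()
                vals = calls.to_numpy()
                ok = vals >= 0
                if ok.sum() < 2:
                    continue
                changes = [
                    (s1, s2)
                    for s1, s2, v1, v2 in zip(
                        starts[ok][:-1], starts[ok][1:], vals[ok][:-1], vals[ok][1:]
                    )
                    if v1 != v2
                ]
                # genotype change may be masked if both flanks share a diploid state
                dose_left = genome.n_b_alleles(ci, [max(bp - w, 1)])[0]
                dose_right = genome.n_b_alleles(ci, [min(bp + w, exp.config.chrom_length)])[0]
                if dose_left == dose_right:
                    continue
                checked += 1
                hits += any(
                    s1 - w <= bp <= s2 + w - 1 for s1, s2 in changes
                )
        assert checked >= 20
        assert hits / checked >= 0.95

    def test_het_regions_show_one_two_one_genotype_ratio(self, sat_haplotypes):
        pw, hap_map, regions = sat_haplotypes
        counts = np.zeros(3)
        for r in regions:
            if r.possible != {HOM_A, HET, HOM_B}:
                continue
            groups = group_embryos(r, hap_map)
            for g in (HOM_A, HET, HOM_B):
                counts[g] += (groups == g).sum()
        assert counts.sum() > 500
        freqs = counts / counts.sum()
        assert stats.chisquare(counts, counts.sum() * np.array([0.25, 0.5, 0.25])).pvalue > 0.001
        assert abs(freqs[1] - 0.5) < 0.05

    def test_embryo_order_permutation_invariance(self, sat_experiment):
        exp = sat_experiment
        snps = exp.snp_table[["chrom", "pos", "alt_strain"]]
        lengths = {c: exp.config.chrom_length for c in exp.config.chrom_names()}
        shuffled = exp.embryo_snp_calls.sample(frac=1.0, random_state=0)
        a = hp.build_haplotype_map(exp.embryo_snp_calls, snps, chrom_lengths=lengths)
        b = hp.build_haplotype_map(shuffled, snps, chrom_lengths=lengths)
        pd.testing.assert_frame_equal(a.calls, b.calls)

    def test_ase_scan_finds_planted_cis_gene_with_correct_sign(
        self, sat_experiment, sat_haplotypes
    ):
        exp = sat_experiment
        _, hap_map, regions = sat_haplotypes
        scan = hp.ase_scan(regions, hap_map, exp.counts, exp.gene_table)
        hh = scan[scan["contrast"] == "hom_vs_hom"]
        strong = exp.gene_table[
            exp.gene_table["is_ase"] & (exp.gene_table["cis_effect"].abs() > 0.8)
        ]
        found = with_sign = 0
        for gene, row in strong.iterrows():
            rows = hh[(hh["gene_id"] == gene) & hh["inside_region"]]
            if rows.empty:
                continue
            found += 1
            with_sign += (np.sign(rows["log2fc"]) == np.sign(row["cis_effect"])).all()
        assert found >= 5
        assert with_sign / found >= 0.9

    def test_hom_contrast_fold_changes_exceed_het_contrast(
        self, sat_experiment, sat_haplotypes
    ):
        """Homozygote-vs-homozygote |log2FC| stochastically larger than het-vs-hom."""
        exp = sat_experiment
        _, hap_map, regions = sat_haplotypes
        scan = hp.ase_scan(regions, hap_map, exp.counts, exp.gene_table)
        ase = scan[scan["gene_id"].isin(set(exp.ase_genes))]
        hom = ase.loc[ase["contrast"] == "hom_vs_hom", "log2fc"].abs()
        het = ase.loc[ase["contrast"] != "hom_vs_hom", "log2fc"].abs()
        assert len(hom) >= 30 and len(het) >= 30
        assert stats.mannwhitneyu(hom, het, alternative="greater").pvalue < 0.05

    def test_null_region_de_rate_at_bh_levels(self, rng):
        """A cross with no cis effects yields (almost) no DE in the scan."""
        from asemap.sim import CrossConfig, simulate_incross

        cfg = CrossConfig.sat_cross(seed=77, n_chromosomes=3, n_genes=300,
                                    frac_ase_genes=0.0)
        exp = simulate_incross(cfg, include_pools=False)
        snps = exp.snp_table[["chrom", "pos", "alt_strain"]]
        pw = hp.parental_window_genotypes(exp.parent_snp_genotypes, snps)
        lengths = {c: cfg.chrom_length for c in cfg.chrom_names()}
        hap_map = hp.build_haplotype_map(exp.embryo_snp_calls, snps,
                                         parental_windows=pw, chrom_lengths=lengths)
        regions = hp.define_informative_regions(pw, hap_map)
        scan = hp.ase_scan(regions, hap_map, exp.counts, exp.gene_table)
        n_contrasts = max(
            sum(1 for r in regions for c in ({HOM_A, HOM_B} <= r.possible,) if c), 1
        )
        assert len(scan) <= 2 * max(n_contrasts, 5)  # BH null: a stray call or two
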