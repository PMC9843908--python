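"""Pedigree simulator: recombination, IBD truth, ROH tracts, reads."""

import numpy as np
import pytest

from kinhmm.simulate import (
    PEDIGREE_RELATIONS,
    SimConfig,
    ascertain_sites,
    build_pedigree,
    generate_reads,
    mate,
    simulate_founders,
    true_roh_fraction,
    true_states,
)

SMALL = SimConfig(n_chromosomes=3, chrom_length=30_000_000, window_size=10_000_000,
                  sites_per_mb=300.0)


@pytest.fixture(scope="module")
def small_cohort():
    config = SMALL
    founders = simulate_founders(config, 7)
    return build_pedigree(founders, config, 7)


class TestFounders:
    def test_p0_calibration(self):
        config = SimConfig(n_chromosomes=2, chrom_length=50_000_000, sites_per_mb=2600)
        fs = simulate_founders(config, 11)
        assert fs.realized_p0() == pytest.approx(config.target_p0, abs=0.01)

    def test_p0_calibration_other_target(self):
        config = SimConfig(n_chromosomes=2, chrom_length=50_000_000,
                           target_p0=0.2, target_phi=0.35, sites_per_mb=2600)
        fs = simulate_founders(config, 11)
        assert fs.realized_p0() == pytest.approx(0.2, abs=0.01)

    def test_phi_calibration(self):
        config = SimConfig(n_chromosomes=2, chrom_length=50_000_000,
                           sites_per_mb=2600, contamination=True)
        fs = simulate_founders(config, 11)
        assert fs.realized_phi() == pytest.approx(config.target_phi, abs=0.015)

    def test_same_seed_identical(self):
        a = simulate_founders(SMALL, 5)
        b = simulate_founders(SMALL, 5)
        for chrom in a.chroms:
            np.testing.assert_array_equal(a.positions[chrom], b.positions[chrom])
            np.testing.assert_array_equal(a.alleles[chrom], b.alleles[chrom])

    def test_msprime_engine_diversity(self):
        # tiny genome through the coalescent engine: founder pairwise
        # difference rate matches the frequency-engine target regime
        config = SimConfig(n_chromosomes=2, chrom_length=4_000_000, engine="msprime")
        fs = simulate_founders(config, 13)
        assert 0.10 < fs.realized_p0() < 0.22
        assert fs.realized_phi() > fs.realized_p0()


class TestMate:
    def test_no_recombination_passes_whole_haplotypes(self):
        config = SimConfig(n_chromosomes=2, chrom_length=10_000_000, r=0.0)
        founders = simulate_founders(SMALL, 1)
        ped = build_pedigree(founders, SMALL, 1)
        child = mate(ped.genomes["F1"], ped.genomes["F2"], config,
                     np.random.default_rng(0), "kid")
        for chrom in ("1", "2"):
            (e0, l0), (e1, l1) = child.haps[chrom]
            assert len(l0) == 1 and l0[0] in (0, 1)
            assert len(l1) == 1 and l1[0] in (2, 3)

    def test_poisson_breakpoint_count(self):
        founders = simulate_founders(SMALL, 1)
        ped = build_pedigree(founders, SMALL, 1)
        rng = np.random.default_rng(3)
        n_segments = []
        for _ in range(1000):
            child = mate(ped.genomes["F1"], ped.genomes["F2"], SMALL, rng, "kid")
            ends, labels = child.haps["1"][0]
            n_segments.append(len(labels))
        # segments - 1 = realized crossovers; E = r * L = 0.3 per 30 Mb
        mean_bp = np.mean(n_segments) - 1
        assert mean_bp == pytest.approx(SMALL.r * SMALL.chrom_length, abs=0.06)

    def test_parent_child_share_exactly_one_chromosome(self, small_cohort):
        center, occ = true_states(small_cohort, "F1", "C1", SMALL.layout())
        assert np.all(center == 1)
        np.testing.assert_allclose(occ[:, 1], 1.0)


class TestPedigreeTruth:
    def test_seventeen_individuals(self, small_cohort):
        assert len(small_cohort.individuals) == 17

    def test_identical_pair_everywhere_state2(self, small_cohort):
        center, _ = true_states(small_cohort, "C1", "C1b", SMALL.layout())
        assert np.all(center == 2)

    def test_founder_pairs_unrelated(self, small_cohort):
        center, _ = true_states(small_cohort, "F5", "F6", SMALL.layout())
        assert np.all(center == 0)

    def test_genomewide_ibd_fractions_match_canonical_k(self):
        # mean occupancy over replicated pedigrees, all canonical relations
        config = SimConfig(n_chromosomes=6)
        grid = config.layout()
        rng = np.random.default_rng(202)
        sums = {rel: np.zeros(3) for rel in PEDIGREE_RELATIONS}
        n = 12
        from kinhmm.simulate import FounderSet

        dummy = FounderSet(
            positions={c: np.empty(0, np.int64) for c, _ in config.chromosomes()},
            alleles={c: np.empty((16, 0), np.uint8) for c, _ in config.chromosomes()},
            panel={c: np.empty((4, 0), np.uint8) for c, _ in config.chromosomes()},
            contaminant={c: np.empty((10, 0), np.uint8) for c, _ in config.chromosomes()},
        )
        for _ in range(n):
            cohort = build_pedigree(dummy, config, rng)
            for rel, pairs in cohort.relations.items():
                accs = [true_states(cohort, i, j, grid)[1].mean(axis=0) for i, j in pairs]
                sums[rel] += np.mean(accs, axis=0)
        expected = {
            "identical": (0, 0, 1), "parent_child": (0, 1, 0),
            "siblings": (0.25, 0.5, 0.25), "half_siblings": (0.5, 0.5, 0),
            "avuncular": (0.5, 0.5, 0), "grandparent_grandchild": (0.5, 0.5, 0),
            "third_degree": (0.75, 0.25, 0), "fourth_degree": (0.875, 0.125, 0),
            "fifth_degree": (0.9375, 0.0625, 0), "unrelated": (1, 0, 0),
        }
        for rel, k in expected.items():
            np.testing.assert_allclose(sums[rel] / n, k, atol=0.06)


class TestROHTracts:
    def test_stationary_fraction_and_zero_heterozygosity(self):
        config = SimConfig(n_chromosomes=6, roh=True, sites_per_mb=200.0)
        founders = simulate_founders(config, 3)
        cohort = build_pedigree(founders, config, 3)
        grid = config.layout()
        fracs = [true_roh_fraction(cohort, f"F{k}", grid).mean() for k in range(1, 9)]
        assert np.mean(fracs) == pytest.approx(1 / 6, abs=0.1)
        # inside true ROH the two haplotypes are identical at every site
        g = cohort.genotypes("F1")
        (e0, l0), (e1, l1) = cohort.genomes["F1"].haps["1"]
        pos0 = cohort.founders.positions["1"] - 1
        lab0 = l0[np.searchsorted(e0, pos0, side="right")]
        lab1 = l1[np.searchsorted(e1, pos0, side="right")]
        in_roh = lab0 == lab1
        assert np.all(g["1"][in_roh] % 2 == 0)  # genotype 0 or 2, never het

    def test_tracts_align_to_windows(self):
        config = SimConfig(n_chromosomes=4, roh=True, sites_per_mb=50.0)
        founders = simulate_founders(config, 9)
        cohort = build_pedigree(founders, config, 9)
        frac = true_roh_fraction(cohort, "F2", config.layout())
        # window-aligned tracts: per-window ROH fraction is 0 or 1
        assert np.all((frac < 1e-9) | (frac > 1 - 1e-9))


class TestAscertainment:
    def test_panel_polymorphism_rule(self):
        config = SimConfig(n_chromosomes=2, chrom_length=20_000_000,
                           sites_per_mb=500, ascertainment=True)
        fs = simulate_founders(config, 21)
        masks = ascertain_sites(fs)
        for chrom in fs.chroms:
            x = fs.panel[chrom].sum(axis=0)
            kept = masks[chrom]
            assert np.all(x[kept] > 0) and np.all(x[kept] < 4)
            dropped = ~kept
            assert np.all((x[dropped] == 0) | (x[dropped] == 4))

    def test_ascertainment_raises_p0(self):
        config = SimConfig(n_chromosomes=2, chrom_length=30_000_000,
                           sites_per_mb=1000, ascertainment=True)
        fs = simulate_founders(config, 33)
        asc = fs.subset(ascertain_sites(fs))
        assert asc.realized_p0() > fs.realized_p0()


class TestReads:
    def test_depth_and_count_conservation(self, small_cohort):
        reads = generate_reads(small_cohort, "C1", 4.0, 5)
        tot_all = np.concatenate([t for _, _, t in reads.data.values()])
        der_all = np.concatenate([d for _, d, _ in reads.data.values()])
        assert np.all(der_all <= tot_all)
        assert tot_all.mean() == pytest.approx(4.0, abs=0.02)

    def test_no_contamination_homozygous_sites_pure(self, small_cohort):
        reads = generate_reads(small_cohort, "F1", 2.0, 6)
        g = small_cohort.genotypes("F1")["1"]
        pos, der, tot = reads.data["1"]
        hom_anc = (g == 0) & (tot > 0)
        hom_der = (g == 2) & (tot > 0)
        assert np.all(der[hom_anc] == 0)
        assert np.all(der[hom_der] == tot[hom_der])

    def test_full_contamination_reflects_contaminant(self):
        config = SimConfig(n_chromosomes=2, chrom_length=20_000_000,
                           sites_per_mb=400, contamination=True)
        founders = simulate_founders(config, 17)
        cohort = build_pedigree(founders, config, 17)
        reads = generate_reads(cohort, "F1", 3.0, 8, contamination_rate=1.0)
        k = cohort.contaminant_of.get("F1", 0)
        gc = (cohort.founders.contaminant["1"][2 * k]
              + cohort.founders.contaminant["1"][2 * k + 1])
        pos, der, tot = reads.data["1"]
        hom0 = (gc == 0) & (tot > 0)
        assert np.all(der[hom0] == 0)

    def test_determinism(self, small_cohort):
        r1 = generate_reads(small_cohort, "H1", 0.5, 99)
        r2 = generate_reads(small_cohort, "H1", 0.5, 99)
        for chrom in r1.data:
            np.testing.assert_array_equal(r1.data[chrom][1], r2.data[chrom][1])
            np.testing.assert_array_equal(r1.data[chrom][2], r2.data[chrom][2])
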