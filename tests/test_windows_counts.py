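"""Window grid construction and windowed difference statistics."""

import itertools

import numpy as np
import pytest

from kinhmm.counts import (
    PairWindowData,
    SiteReadCounts,
    aggregate_pair_windows,
    cohort_pair_totals,
    estimate_p0,
    pair_site_difference,
    read_counts_tsv,
    within_individual_diffs,
    write_counts_tsv,
)
from kinhmm.layout import build_window_grid


class TestWindowGrid:
    @pytest.mark.parametrize(
        "chroms, wsize, expected_L",
        [
            ([("1", 96_000_000)], 10_000_000, 10),
            ([(str(i), 96_000_000) for i in range(1, 23)], 10_000_000, 220),
            ([("1", 10_000_000)], 10_000_000, 1),
        ],
    )
    def test_window_counts(self, chroms, wsize, expected_L):
        grid = build_window_grid(chroms, wsize)
        assert grid.L == expected_L

    def test_last_window_short(self):
        grid = build_window_grid([("1", 96_000_000)], 10_000_000)
        assert grid.window_end[-1] - grid.window_start[-1] == 6_000_000

    def test_windows_tile_without_overlap(self):
        grid = build_window_grid([("1", 47), ("2", 30)], 10)
        for chrom in grid.chrom_names:
            sel = grid.window_chrom == chrom
            starts, ends = grid.window_start[sel], grid.window_end[sel]
            assert starts[0] == 0
            assert np.all(starts[1:] == ends[:-1])
            assert ends[-1] == grid.chrom_length(chrom)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            build_window_grid([], 10)


class TestPairSiteDifference:
    @pytest.mark.parametrize(
        "ni, nj, expected",
        [(1.0, 0.0, 1.0), (0.5, 0.5, 0.5), (1.0, 1.0, 0.0), (0.0, 0.0, 0.0)],
    )
    def test_examples(self, ni, nj, expected):
        assert pair_site_difference(ni, nj) == pytest.approx(expected)

    def test_matches_single_read_sampling_enumeration(self, rng):
        # expected pseudo-haploid mismatch over exhaustive read samplings
        for _ in range(20):
            da, ta = rng.integers(0, 4), rng.integers(1, 5)
            db, tb = rng.integers(0, 4), rng.integers(1, 5)
            da, db = min(da, ta), min(db, tb)
            reads_a = [1] * da + [0] * (ta - da)
            reads_b = [1] * db + [0] * (tb - db)
            brute = np.mean([a != b for a in reads_a for b in reads_b])
            assert pair_site_difference(da / ta, db / tb) == pytest.approx(brute)


class TestAggregatePairWindows:
    def test_hand_worked_window(self, small_grid):
        pos = np.array([1, 2, 3])
        a = SiteReadCounts("a", {"1": (pos, np.array([2.0, 0, 1]), np.array([2.0, 1, 2])),
                                "2": (np.array([5]), np.array([0.0]), np.array([0.0]))})
        b = SiteReadCounts("b", {"1": (pos, np.array([1.0, 2, 0]), np.array([1.0, 2, 3])),
                                "2": (np.array([5]), np.array([1.0]), np.array([1.0]))})
        out = aggregate_pair_windows(a, b, small_grid)
        # (nu_a, nu_b) = (1,1), (0,1), (0.5,0) -> D = 0 + 1 + 0.5
        assert out.N[0] == 3
        assert out.D[0] == pytest.approx(1.5)
        # chromosome-2 site covered in b only: excluded
        assert out.N[5:].sum() == 0 and out.D[5:].sum() == 0

    def test_diploid_genotypes_match_brute_force(self, rng):
        # nu in {0, .5, 1}: D equals exhaustive single-read-sampling mismatch
        grid = build_window_grid([("1", 20)], 20)
        n = 12
        pos = np.arange(1, n + 1)
        ga = rng.integers(0, 3, n)
        gb = rng.integers(0, 3, n)
        a = SiteReadCounts("a", {"1": (pos, ga.astype(float), np.full(n, 2.0))})
        b = SiteReadCounts("b", {"1": (pos, gb.astype(float), np.full(n, 2.0))})
        out = aggregate_pair_windows(a, b, grid)
        brute = 0.0
        for s in range(n):
            alleles_a = [int(x < ga[s]) for x in range(2)]
            alleles_b = [int(x < gb[s]) for x in range(2)]
            brute += np.mean([x != y for x, y in itertools.product(alleles_a, alleles_b)])
        assert out.D[0] == pytest.approx(brute)
        assert out.N[0] == n

    def test_site_order_permutation_invariant(self, small_grid, toy_counts):
        a, b, _ = toy_counts
        ref = aggregate_pair_windows(a, b, small_grid)
        perm = np.array([3, 0, 5, 1, 4, 2])
        pos, der, tot = a.data["1"]
        a2 = SiteReadCounts("a2", {"1": (pos[perm], der[perm], tot[perm])})
        pos, der, tot = b.data["1"]
        b2 = SiteReadCounts("b2", {"1": (pos[perm], der[perm], tot[perm])})
        out = aggregate_pair_windows(a2, b2, small_grid)
        np.testing.assert_allclose(out.D, ref.D)
        np.testing.assert_allclose(out.N, ref.N)

    def test_mismatched_chromosomes_rejected(self, small_grid, toy_counts):
        a, _, _ = toy_counts
        odd = SiteReadCounts("odd", {"7": (np.array([1]), np.array([0.0]), np.array([1.0]))})
        with pytest.raises(ValueError):
            aggregate_pair_windows(a, odd, small_grid)

    def test_matches_cohort_totals(self, small_grid, toy_counts):
        totals = cohort_pair_totals(list(toy_counts))
        for x, y in itertools.combinations(toy_counts, 2):
            d, n = aggregate_pair_windows(x, y, small_grid).totals()
            td, tn = totals[(x.individual, y.individual)]
            assert d == pytest.approx(td, abs=1e-5)
            assert n == pytest.approx(tn, abs=1e-5)


class TestWithinIndividualDiffs:
    def test_depth_rule_and_values(self, small_grid):
        pos = np.array([1, 2, 3])
        a = SiteReadCounts(
            "a", {"1": (pos, np.array([2.0, 5, 1]), np.array([4.0, 5, 1])),
                  "2": (np.array([1]), np.array([0.0]), np.array([0.0]))}
        )
        plugin = within_individual_diffs(a, small_grid, estimator="plugin")
        # 2 nu (1-nu): site1 0.5; site2 homozygous 0; site3 single read excluded
        assert plugin.M[0] == 2
        assert plugin.Delta[0] == pytest.approx(0.5)
        unbiased = within_individual_diffs(a, small_grid)
        # without replacement: d(n-d)/C(n,2) = 4/6
        assert unbiased.Delta[0] == pytest.approx(2 / 3)

    def test_unbiased_estimator_is_depth_free_at_het_sites(self, rng):
        # expectation at a true heterozygous site is 1/2 at every depth
        g = build_window_grid([("1", 4000)], 4000)
        pos = np.arange(1, 4001)
        for depth in (2, 3, 6):
            d = rng.binomial(depth, 0.5, size=4000).astype(float)
            c = SiteReadCounts("i", {"1": (pos, d, np.full(4000, float(depth)))})
            out = within_individual_diffs(c, g)
            assert out.Delta[0] / out.M[0] == pytest.approx(0.5, abs=0.03)


class TestEstimateP0:
    def _pair(self, ratio, n=100.0):
        return PairWindowData(("i", "j"), np.array([ratio * n]), np.array([n]))

    def test_median_examples(self):
        ratios = [0.10, 0.20, 0.21, 0.22, 0.50]
        pairs = [self._pair(r) for r in ratios]
        assert estimate_p0(pairs) == pytest.approx(0.21)
        assert estimate_p0([self._pair(0.18)]) == pytest.approx(0.18)
        assert estimate_p0([self._pair(0.1), self._pair(0.2)]) == pytest.approx(0.15)

    def test_pair_order_invariance_and_outlier_robustness(self, rng):
        ratios = [0.18, 0.20, 0.21, 0.19, 0.22]
        pairs = [self._pair(r) for r in ratios]
        base = estimate_p0(pairs)
        perm = list(rng.permutation(len(pairs)))
        assert estimate_p0([pairs[i] for i in perm]) == base
        assert estimate_p0(pairs + [self._pair(0.49)]) == pytest.approx(base, abs=0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_p0([self._pair(0.8)])
        with pytest.raises(ValueError):
            estimate_p0([PairWindowData(("i", "j"), np.zeros(1), np.zeros(1))])


def test_counts_tsv_roundtrip(tmp_path, toy_counts):
    a = toy_counts[0]
    write_counts_tsv(a, tmp_path / "A.tsv")
    back = read_counts_tsv(tmp_path / "A.tsv")
    assert back.individual == "A"
    np.testing.assert_array_equal(back.data["1"][0], a.data["1"][0])
    np.testing.assert_allclose(back.data["1"][1], a.data["1"][1])


def test_window_table_written_half_open(tmp_path, small_grid, toy_counts):
    import pandas as pd

    from kinhmm.counts import write_window_table

    a, b, _ = toy_counts
    data = aggregate_pair_windows(a, b, small_grid)
    write_window_table(data, small_grid, tmp_path / "win.tsv")
    df = pd.read_csv(tmp_path / "win.tsv", sep="\t")
    assert list(df.columns) == ["chrom", "start", "end", "D", "N"]
    assert len(df) == small_grid.L
    assert df["start"].iloc[0] == 0 and df["end"].iloc[0] == 10


def test_invalid_counts_rejected():
    with pytest.raises(ValueError):
        SiteReadCounts("x", {"1": (np.array([1]), np.array([3.0]), np.array([2.0]))})
    with pytest.raises(ValueError):
        SiteReadCounts("x", {"1": (np.array([1, 1]), np.array([0.0, 0]), np.array([1.0, 1]))})
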