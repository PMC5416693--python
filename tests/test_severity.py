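"""Exact contingency tests, LOF percentages, subset permutation test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from nscnet.severity import (
    SEVERITY_CATEGORIES,
    detect_severity_gradient,
    fisher_exact_2x2,
    fisher_exact_rxc,
    lof_odds_ratio,
    lof_percentage,
    mutation_tuples_from_table,
    permutation_lof_distribution,
    round_half_up,
    severity_summary,
)
from nscnet.synthetic import SyntheticConfig, generate_mutation_catalog, make_gene_lengths
from nscnet.severity import mutation_tuples_from_catalog


def oracle_2x2(table):
    """Hypergeometric enumeration of every table with the observed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {
        x: math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        for x in range(lo, hi + 1)
    }
    return sum(p for p in pmf.values() if p <= pmf[a] * (1 + 1e-12))


def oracle_rx2(table):
    """Exhaustive enumeration over all r x 2 tables with the same margins."""
    t = np.asarray(table)
    row_sums = t.sum(axis=1)
    c1 = t[:, 0].sum()
    n = t.sum()
    denom = math.comb(int(n), int(c1))

    def prob(cols):
        return math.prod(math.comb(int(r), int(x)) for r, x in zip(row_sums, cols)) / denom

    obs = prob(t[:, 0])
    total = 0.0
    for cols in itertools.product(*[range(int(r) + 1) for r in row_sums]):
        if sum(cols) == c1:
            p = prob(cols)
            if p <= obs * (1 + 1e-12):
                total += p
    return total


class TestLofPercentage:
    def test_fixture_percentages(self, table1):
        expected = {"ASD-lowIQ": 43, "ASD-normIQ": 17, "SZ": 11}
        for cat, pct in expected.items():
            assert round_half_up(lof_percentage(table1.mutations(cat))) == pct

    def test_all_lof(self):
        assert lof_percentage(["LOF", "LOF"]) == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lof_percentage([])

    def test_half_up_rounding(self):
        assert round_half_up(42.5) == 43
        assert round_half_up(42.49) == 42


class TestFisher2x2:
    def test_balanced_table(self):
        p, orr = fisher_exact_2x2([[1, 1], [1, 1]])
        assert p == 1.0 and orr == 1.0

    def test_perfect_separation(self):
        p, orr = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252)
        assert math.isinf(orr)

    def test_zero_margin(self):
        p, _ = fisher_exact_2x2([[0, 0], [3, 4]])
        assert p == 1.0

    @pytest.mark.parametrize("table", [
        [[2, 3], [4, 1]], [[1, 7], [6, 2]], [[3, 3], [3, 3]], [[8, 1], [2, 9]],
        [[0, 5], [5, 0]], [[4, 0], [6, 10]], [[2, 2], [9, 8]],
    ])
    def test_matches_enumeration_oracle(self, table):
        p, _ = fisher_exact_2x2(table)
        assert p == pytest.approx(oracle_2x2(table), rel=1e-9)


class TestFisherRxC:
    def test_near_expected_table(self):
        res = fisher_exact_rxc([[5, 5], [5, 5], [5, 5]])
        assert res.p == 1.0

    def test_degenerate_single_column(self):
        assert fisher_exact_rxc([[3, 0], [4, 0]]).p == 1.0

    def test_single_nonempty_row(self):
        assert fisher_exact_rxc([[3, 4], [0, 0]]).p == 1.0

    @pytest.mark.parametrize("table", [
        [[5, 1], [1, 5], [3, 3]],
        [[2, 8], [7, 1], [4, 4]],
        [[1, 1], [2, 2], [3, 3], [4, 4]],
        [[6, 0], [0, 6], [3, 3]],
        [[2, 3], [4, 1]],
        [[1, 4], [2, 2], [5, 0]],
    ])
    def test_matches_enumeration_oracle(self, table):
        res = fisher_exact_rxc(table)
        assert res.method == "exact"
        assert res.p == pytest.approx(oracle_rx2(table), rel=1e-9)

    def test_exhaustive_small_margin_agreement(self):
        """All 3x2 tables with every margin <= 4 agree with the oracle."""
        for rows in itertools.product(range(5), repeat=3):
            if sum(rows) == 0:
                continue
            for cols in itertools.product(*[range(r + 1) for r in rows]):
                table = [[c, r - c] for r, c in zip(rows, cols)]
                assert fisher_exact_rxc(table).p == pytest.approx(
                    oracle_rx2(table), rel=1e-9
                )

    def test_monte_carlo_fallback_close_to_exact(self):
        table = [[13, 17], [2, 10], [2, 16]]
        exact = fisher_exact_rxc(table)
        mc = fisher_exact_rxc(table, max_exact_tables=1, n_mc=20000, seed=2)
        assert mc.method == "monte-carlo"
        assert mc.p == pytest.approx(exact.p, abs=4 * mc.se)


class TestLofOddsRatio:
    def test_identical_proportions(self):
        orr, p = lof_odds_ratio((10, 20), (30, 60))
        assert orr == pytest.approx(1.0) and p == 1.0

    def test_definition(self):
        orr, _ = lof_odds_ratio((13, 17), (50, 150))
        assert orr == pytest.approx((13 * 150) / (17 * 50))

    def test_small_counts_match_enumeration(self):
        table = [[4, 1], [2, 6]]
        orr, p = lof_odds_ratio((4, 1), (2, 6))
        assert p == pytest.approx(oracle_2x2(table), rel=1e-9)

    def test_zero_cell_conventions(self):
        orr, _ = lof_odds_ratio((3, 0), (2, 5))
        assert math.isinf(orr)
        orr, _ = lof_odds_ratio((0, 3), (2, 5))
        assert orr == 0.0


class TestSeverityGradient:
    def test_fixture_gradient_set(self, table1):
        gradient, opposite = detect_severity_gradient(table1)
        assert gradient == {"ZEB2", "RFX3", "CUL3", "EP300", "AHDC1", "SETD2"}
        assert opposite == set()

    def test_empty_table(self):
        from nscnet.annotation import MDAnnotationTable

        gradient, opposite = detect_severity_gradient(MDAnnotationTable([]))
        assert gradient == set() and opposite == set()


class TestPermutationTest:
    def _pool(self, seed=21, counts=None):
        cfg = SyntheticConfig(
            seed=seed,
            mutation_counts_per_category=counts
            or {"ASD-lowIQ": 800, "ASD-normIQ": 600, "SZ": 400},
        )
        catalog, _ = generate_mutation_catalog(cfg, make_gene_lengths(cfg))
        return mutation_tuples_from_catalog(catalog)

    def test_seed_determinism(self):
        pool = self._pool()
        net = pool[:60]
        a = permutation_lof_distribution(net, pool, n_perm=300, seed=5)
        b = permutation_lof_distribution(net, pool, n_perm=300, seed=5)
        assert a == b

    def test_null_calibration(self):
        """Network subsets drawn from the total itself give uniform p."""
        pool = self._pool()
        pvals = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            net = [pool[i] for i in rng.choice(len(pool), 60, replace=False)]
            res = permutation_lof_distribution(
                net, pool, n_perm=400, seed=seed, add_one=True
            )
            pvals.append(res.permutation_p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_effect_detected(self):
        """An exaggerated lowIQ LOF excess in the network subset is flagged."""
        pool = self._pool(
            seed=31, counts={"ASD-lowIQ": 800, "ASD-normIQ": 600, "SZ": 400}
        )
        # network: 30 lowIQ nearly all LOF vs 15+15 others nearly all missense
        net = (
            [("ASD-lowIQ", True)] * 26 + [("ASD-lowIQ", False)] * 4
            + [("ASD-normIQ", False)] * 14 + [("ASD-normIQ", True)] * 1
            + [("SZ", False)] * 15
        )
        res = permutation_lof_distribution(net, pool, n_perm=1000, seed=3)
        assert res.permutation_p < 0.05

    def test_matched_distribution_not_extreme(self):
        """A network mirroring the total's category-wise LOF pattern exactly
        should not look unusual."""
        pool = self._pool(seed=41)
        # expected-count subset per category at the pool's own LOF rates
        net = []
        for cat in SEVERITY_CATEGORIES:
            cat_pool = [t for t in pool if t[0] == cat]
            n_cat = round(60 * len(cat_pool) / len(pool))
            n_lof = round(n_cat * sum(l for _, l in cat_pool) / len(cat_pool))
            net += [(cat, True)] * n_lof + [(cat, False)] * (n_cat - n_lof)
        res = permutation_lof_distribution(net, pool, n_perm=500, seed=7)
        assert res.permutation_p > 0.05

    def test_too_small_pool_rejected(self):
        with pytest.raises(ValueError, match="subset_size"):
            permutation_lof_distribution([("SZ", True)], [("SZ", True)] * 10, subset_size=60, n_perm=10, seed=0)


def test_severity_summary_fixture(table1):
    summary = severity_summary(table1)
    assert summary["lof_pct_rounded"] == {"ASD-lowIQ": 43, "ASD-normIQ": 17, "SZ": 11}
    assert len(summary["severity_gradient_genes"]) == 6
    assert summary["opposite_pattern_genes"] == []
    assert 0 < summary["fisher_rxc_p"] < 1
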