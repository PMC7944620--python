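"""Statistical toolkit: exact examples, enumeration oracles, library
cross-checks (scipy/statsmodels are used as independent references,
never as the implementation)."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import triadtrack as tt


# ---------------------------------------------------------------------------
# exact binomial asymmetry test
# ---------------------------------------------------------------------------

class TestBinomAsymmetry:
    @pytest.mark.parametrize("gt,lt,expected", [
        (10, 0, 0.001953125),      # 2 * 0.5**10
        (5, 5, 1.0),
        (7, 3, 0.34375),           # brute-force sum over Binomial(10, .5)
    ])
    def test_closed_form_examples(self, gt, lt, expected):
        assert tt.binom_asymmetry(gt, lt).p_value == pytest.approx(expected)

    def test_symmetry(self, rng):
        for _ in range(50):
            a, b = rng.integers(0, 60, 2)
            if a + b == 0:
                continue
            assert tt.binom_asymmetry(a, b).p_value == pytest.approx(
                tt.binom_asymmetry(b, a).p_value)

    def test_matches_scipy_binomtest(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 300))
            k = int(rng.integers(0, n + 1))
            ours = tt.binom_asymmetry(k, n - k).p_value
            ref = sps.binomtest(k, n, 0.5).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_no_biased_triads_is_an_error(self):
        with pytest.raises(ValueError, match="no biased"):
            tt.binom_asymmetry(0, 0)


# ---------------------------------------------------------------------------
# two-sample proportion test
# ---------------------------------------------------------------------------

class TestTwoProportion:
    def test_identical_proportions(self):
        res = tt.two_proportion_test(50, 100, 50, 100)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_corrected_statistic(self):
        # (|0.3 - 0.1| - 0.01)^2 / (0.2 * 0.8 * 0.02)
        res = tt.two_proportion_test(30, 100, 10, 100)
        assert res.statistic == pytest.approx(11.28125)

    def test_degenerate_pooled_proportion(self):
        res = tt.two_proportion_test(0, 10, 0, 10)
        assert res.p_value == 1.0

    def test_uncorrected_equals_squared_pooled_z(self, rng):
        from statsmodels.stats.proportion import proportions_ztest
        for _ in range(30):
            n1, n2 = rng.integers(5, 200, 2)
            x1 = int(rng.integers(1, n1))
            x2 = int(rng.integers(1, n2))
            res = tt.two_proportion_test(x1, int(n1), x2, int(n2),
                                         correction=False)
            z, p = proportions_ztest([x1, x2], [int(n1), int(n2)])
            assert res.statistic == pytest.approx(z ** 2, rel=1e-9)
            assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_corrected_matches_yates_chi2_contingency(self, rng):
        """Equivalent to the Yates chi-square on the 2x2 table (as R's
        prop.test computes it) whenever the correction does not cap."""
        for _ in range(30):
            n1, n2 = (int(v) for v in rng.integers(20, 200, 2))
            x1 = int(rng.integers(1, n1))
            x2 = int(rng.integers(1, n2))
            table = [[x1, n1 - x1], [x2, n2 - x2]]
            chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
            res = tt.two_proportion_test(x1, n1, x2, n2, correction=True)
            assert res.statistic == pytest.approx(chi2, rel=1e-9)
            assert res.p_value == pytest.approx(p, rel=1e-9)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _exact_wilcoxon_oracle(x, y):
    """Two-sided exact p by explicit enumeration of rank assignments."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))
    r_obs = ranks[:n1].sum()
    sums = [sum(c) for c in itertools.combinations(range(1, n + 1), n1)]
    total = len(sums)
    lower = sum(s <= r_obs for s in sums) / total
    upper = sum(s >= r_obs for s in sums) / total
    return min(1.0, 2 * min(lower, upper))


class TestWilcoxonRankSum:
    def test_fully_separated_samples(self):
        res = tt.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)   # 2/20 rank assignments

    def test_three_observations(self):
        assert tt.wilcoxon_rank_sum([1, 2], [3]).p_value == pytest.approx(
            2 / 3)

    def test_identical_samples_no_shift(self):
        res = tt.wilcoxon_rank_sum(list(range(20)), list(range(20)))
        assert res.p_value >= 0.99

    def test_exact_matches_enumeration_oracle_all_small_sizes(self, rng):
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                res = tt.wilcoxon_rank_sum(x, y)
                assert res.method == "wilcoxon_rank_sum_exact"
                assert res.p_value == pytest.approx(
                    _exact_wilcoxon_oracle(x, y))

    def test_exact_matches_scipy_mannwhitneyu(self, rng):
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            ref = sps.mannwhitneyu(x, y, method="exact",
                                   alternative="two-sided").pvalue
            assert tt.wilcoxon_rank_sum(x, y).p_value == pytest.approx(ref)

    def test_normal_approximation_close_to_exact_at_n12(self, rng):
        """|p_approx - p_exact| <= 0.02 at n1 = n2 = 6 without ties."""
        for _ in range(25):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            exact = tt.wilcoxon_rank_sum(x, y, exact_threshold=16).p_value
            approx = tt.wilcoxon_rank_sum(x, y, exact_threshold=0).p_value
            assert abs(exact - approx) <= 0.02

    def test_ties_fall_back_to_corrected_approximation(self):
        res = tt.wilcoxon_rank_sum([1, 1, 2], [2, 3, 3])
        assert res.method == "wilcoxon_rank_sum"
        ref = sps.mannwhitneyu([1, 1, 2], [2, 3, 3], method="asymptotic",
                               alternative="two-sided").pvalue
        assert res.p_value == pytest.approx(ref, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            tt.wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# hypergeometric enrichment + Benjamini-Hochberg
# ---------------------------------------------------------------------------

def _annotation(mapping):
    import pandas as pd
    rows = [{"gene_id": g, "term_id": t, "term_name": t}
            for t, genes in mapping.items() for g in genes]
    return pd.DataFrame(rows)


class TestEnrichment:
    def test_selection_equal_universe_gives_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        ann = _annotation({"T1": genes[:4], "T2": genes[4:]})
        res = tt.hypergeom_enrichment(genes, ann, genes)
        assert (res["p_value"] == 1.0).all()

    def test_perfect_overlap_closed_form(self):
        """k = K = n = 5 in N = 20: p = 1 / C(20, 5)."""
        universe = [f"g{i}" for i in range(20)]
        ann = _annotation({"T1": universe[:5]})
        res = tt.hypergeom_enrichment(universe[:5], ann, universe)
        assert res["p_value"].iloc[0] == pytest.approx(1 / math.comb(20, 5))
        assert res["p_value"].iloc[0] == pytest.approx(6.4499e-5, rel=1e-4)

    def test_matches_one_sided_fisher(self, rng):
        universe = [f"g{i}" for i in range(60)]
        for _ in range(20):
            term = list(rng.choice(universe, size=15, replace=False))
            sel = list(rng.choice(universe, size=20, replace=False))
            ann = _annotation({"T": term})
            res = tt.hypergeom_enrichment(sel, ann, universe)
            k = len(set(term) & set(sel))
            table = [[k, len(sel) - k],
                     [15 - k, 60 - 15 - (len(sel) - k)]]
            _, ref = sps.fisher_exact(table, alternative="greater")
            assert res["p_value"].iloc[0] == pytest.approx(ref, rel=1e-9)

    def test_selection_outside_universe_rejected(self):
        ann = _annotation({"T": ["g1"]})
        with pytest.raises(ValueError, match="subset"):
            tt.hypergeom_enrichment(["gX"], ann, ["g1"])


class TestBhAdjust:
    def test_hand_applied_step_up(self):
        q = tt.bh_adjust([0.01, 0.02, 0.03])
        assert list(q) == pytest.approx([0.03, 0.03, 0.03])

    def test_monotone_in_p_order_and_capped(self, rng):
        for _ in range(20):
            p = rng.uniform(size=40)
            q = tt.bh_adjust(p)
            assert (q <= 1.0).all()
            assert (q >= p - 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=25)
        ref = multipletests(p, method="fdr_bh")[1]
        assert tt.bh_adjust(p) == pytest.approx(ref)


class TestPearson:
    def test_perfect_relations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert tt.pearson_r(x, [2 * v for v in x]).statistic == \
            pytest.approx(1.0)
        assert tt.pearson_r(x, [-v for v in x]).statistic == \
            pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert tt.pearson_r([1, 2, 3, 4], [2, 1, 4, 3]).statistic == \
            pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            tt.pearson_r([1, 1, 1], [1, 2, 3])
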