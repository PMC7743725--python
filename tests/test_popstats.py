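"""KS shift test, BH/FDR rule, SRH rank model, Wilcoxon, Fst, enrichment, OLS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mirselect import (
    ConfigurationError,
    DegenerateDesignError,
    InsufficientDataError,
    NoInformationError,
    bh_qvalues,
    expected_fp_mask,
    fst_enrichment,
    ks_one_tailed,
    latitude_regression,
    nei_fst,
    srh_test,
    wilcoxon_paired,
)


def brute_force_d(x, y):
    """Independent oracle: max ECDF differences evaluated at every pooled point."""
    pts = sorted(set(x) | set(y))
    d_plus = d_minus = 0.0
    for v in pts:
        fx = sum(xi <= v for xi in x) / len(x)
        fy = sum(yi <= v for yi in y) / len(y)
        d_plus = max(d_plus, fx - fy)
        d_minus = max(d_minus, fy - fx)
    return d_plus, d_minus


class TestKsOneTailed:
    def test_identical_samples(self):
        d, p = ks_one_tailed([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert d == 0.0
        assert p == 1.0

    def test_full_separation_d(self):
        d, _ = ks_one_tailed([0.1, 0.1, 0.2], [0.5, 0.6, 0.7])
        assert d == pytest.approx(1.0)

    def test_plain_asymptotic_formula(self):
        _, p = ks_one_tailed([0.1, 0.1, 0.2], [0.5, 0.6, 0.7], corrected=False)
        assert p == pytest.approx(math.exp(-2.0 * 1.0 * 9 / 6), abs=1e-12)

    def test_signed_convention(self):
        low = [0.05, 0.1, 0.15]
        high = [0.6, 0.7, 0.8]
        d_anc, _ = ks_one_tailed(low, high, "toward-ancestral")
        d_der, _ = ks_one_tailed(low, high, "toward-derived")
        assert d_anc > 0
        assert d_der <= 0

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            ks_one_tailed([], [0.1])

    def test_matches_brute_force_and_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            m, n = rng.integers(3, 40, size=2)
            x = np.round(rng.uniform(size=m), 2)  # rounding induces ties
            y = np.round(rng.uniform(size=n), 2)
            d_plus, d_minus = brute_force_d(list(x), list(y))
            da, _ = ks_one_tailed(x, y, "toward-ancestral")
            dd, _ = ks_one_tailed(x, y, "toward-derived")
            assert da == pytest.approx(d_plus, abs=1e-12)
            assert -dd == pytest.approx(d_minus, abs=1e-12)
            sp = sps.ks_2samp(x, y, alternative="greater").statistic
            assert da == pytest.approx(sp, abs=1e-12)


class TestBhQvalues:
    def test_single_p(self):
        assert bh_qvalues([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed(self):
        assert bh_qvalues([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert bh_qvalues([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            bh_qvalues([])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_monotone_and_order_invariant(self, ps):
        q = bh_qvalues(ps)
        assert np.all(q >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)
        shuffled = list(reversed(ps))
        assert bh_qvalues(shuffled)[::-1] == pytest.approx(q)


class TestExpectedFpMask:
    @pytest.mark.parametrize("q,ceiling,expected", [
        ([0.01], 0.10, [True]),
        ([0.15], 0.10, [False]),
        ([0.09] * 10, 0.10, [True] * 10),       # 0.9 expected false positives < 1
        ([0.2] * 10, 0.25, [False] * 10),       # 2 expected false positives
    ])
    def test_rule(self, q, ceiling, expected):
        assert list(expected_fp_mask(q, ceiling)) == expected


class TestSrh:
    def test_constant_response(self):
        res = srh_test([3.0] * 8, ["a", "a", "b", "b"] * 2, ["x", "y"] * 4)
        assert all(v == 0.0 for v in res.H.values())
        assert all(v == 1.0 for v in res.p.values())

    def test_two_by_two_fixture(self):
        # y = 1..4 placed so factor A separates {1,2} from {3,4}:
        # ranks 1..4, SS_total = 5, SS_A = 4, H_A = 4 / (5/3) = 2.4
        res = srh_test([1, 2, 3, 4], ["a1", "a1", "a2", "a2"], ["b1", "b2", "b1", "b2"])
        assert res.H["A"] == pytest.approx(2.4)
        assert res.df["A"] == 1
        assert res.p["A"] == pytest.approx(float(sps.chi2.sf(2.4, 1)))

    def test_reference_cell_is_zero(self):
        rng = np.random.default_rng(0)
        a = ["high", "low"] * 10
        b = ["animal", "primate"] * 10
        res = srh_test(rng.normal(size=20), a, b, reference=("high", "animal"))
        assert res.rank_coefficients[("high", "animal")] == 0.0

    def test_one_level_factor_rejected(self):
        with pytest.raises(DegenerateDesignError):
            srh_test([1, 2, 3, 4], ["a"] * 4, ["x", "y"] * 2)

    def test_matches_statsmodels_type2_anova(self):
        """Cross-check SS on an unbalanced design against statsmodels."""
        import pandas as pd
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        n = 40
        frame = pd.DataFrame({
            "a": rng.choice(["p", "q", "r"], size=n),
            "b": rng.choice(["u", "v"], size=n),
            "y": rng.normal(size=n),
        })
        frame["r"] = sps.rankdata(frame["y"])
        fit = smf.ols("r ~ C(a) * C(b)", data=frame).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        res = srh_test(frame["y"], frame["a"], frame["b"])
        ms_total = ((frame["r"] - frame["r"].mean()) ** 2).sum() / (n - 1)
        assert res.H["A"] == pytest.approx(anova.loc["C(a)", "sum_sq"] / ms_total, rel=1e-8)
        assert res.H["B"] == pytest.approx(anova.loc["C(b)", "sum_sq"] / ms_total, rel=1e-8)
        assert res.H["A:B"] == pytest.approx(
            anova.loc["C(a):C(b)", "sum_sq"] / ms_total, rel=1e-8
        )


class TestWilcoxon:
    def test_no_information(self):
        with pytest.raises(NoInformationError):
            wilcoxon_paired([1, 2, 3], [1, 2, 3])

    def test_exact_minimal_w(self):
        # all six differences negative: W = 0, exact two-sided p = 2/2^6
        x = [1, 2, 3, 4, 5, 6]
        y = [v + 1 for v in x]
        assert wilcoxon_paired(x, y) == pytest.approx(0.03125)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert wilcoxon_paired(x, y) == pytest.approx(wilcoxon_paired(y, x))


class TestNeiFst:
    @pytest.mark.parametrize("freqs,expected", [
        ((0.0, 1.0), 1.0),
        ((0.3, 0.3, 0.3), 0.0),
        ((0.2, 0.8), 0.36),  # Hs = 0.32, Ht = 0.5
    ])
    def test_closed_forms(self, freqs, expected):
        assert nei_fst(freqs) == pytest.approx(expected)

    def test_monomorphic_returns_zero(self):
        assert nei_fst((0.0, 0.0, 0.0)) == 0.0

    def test_single_population_rejected(self):
        with pytest.raises(InsufficientDataError):
            nei_fst((0.5,))


class TestFstEnrichment:
    def test_identical_samples_flat_zero(self):
        vals = np.linspace(0.01, 0.99, 50)
        bins = fst_enrichment(vals, vals)
        for b in bins:
            if b.defined:
                assert b.log_ratio == pytest.approx(0.0)

    def test_log10_two(self):
        # one bin holding 20% of targets vs 10% of background
        target = [0.01] * 2 + [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        background = [0.01] * 1 + [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99]
        bins = fst_enrichment(target, background)
        assert bins[0].log_ratio == pytest.approx(math.log10(2.0))

    def test_empty_background_bin_flagged(self):
        bins = fst_enrichment([0.01, 0.99], [0.01, 0.01])
        last = bins[-1]
        assert last.defined is False and math.isnan(last.log_ratio)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(8)
        bins = fst_enrichment(rng.uniform(size=200), rng.uniform(size=300))
        assert sum(b.P_t for b in bins) == pytest.approx(1.0)
        assert sum(b.P_b for b in bins) == pytest.approx(1.0)

    def test_last_bin_closed(self):
        bins = fst_enrichment([1.0], [1.0])
        assert bins[-1].P_t == pytest.approx(1.0)

    def test_bad_bin_width(self):
        with pytest.raises(ConfigurationError):
            fst_enrichment([0.1], [0.2], bin_width=0.07)


class TestLatitudeRegression:
    def test_perfect_linear(self):
        lats = [0.0, 10.0, 20.0, 30.0]
        y = [0.5 - 0.01 * v for v in lats]
        slope, p, adj = latitude_regression(y, lats)
        assert slope == pytest.approx(-0.01)
        assert adj == pytest.approx(1.0)

    def test_constant_response(self):
        slope, _, _ = latitude_regression([0.4] * 4, [0.0, 10.0, 20.0, 30.0])
        assert slope == pytest.approx(0.0)

    def test_closed_form_four_points(self):
        x = np.array([5.0, 12.0, 30.0, 44.0])
        y = np.array([0.61, 0.50, 0.38, 0.22])
        slope, p, adj = latitude_regression(y, x)
        # normal equations by hand
        b = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        a = y.mean() - b * x.mean()
        resid = y - (a + b * x)
        s2 = resid @ resid / 2
        se = math.sqrt(s2 / ((x - x.mean()) @ (x - x.mean())))
        t = b / se
        p_hand = 2 * sps.t.sf(abs(t), 2)
        r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
        adj_hand = 1 - (1 - r2) * 3 / 2
        assert slope == pytest.approx(b, abs=1e-10)
        assert p == pytest.approx(p_hand, abs=1e-10)
        assert adj == pytest.approx(adj_hand, abs=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateDesignError):
            latitude_regression([0.1, 0.2, 0.3], [10.0, 10.0, 10.0])


def test_fst_record_range_checked():
    from mirselect import FstRecord

    assert FstRecord("rs1", 0.3314).fst == pytest.approx(0.3314)
    with pytest.raises(ValueError):
        FstRecord("rs1", 1.2)
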