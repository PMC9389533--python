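"""Diagnostic metrics, agreement statistics and hypothesis tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from ttroi import (
    ConfusionCounts,
    cohens_kappa,
    confusion_counts,
    diagnostic_metrics,
    fisher_exact_2x2,
    mann_whitney,
    mcnemar_test,
    pearson_chi2_2x2,
    stratified_accuracy,
    wilson_ci,
)
from ttroi.stats import round_half_up


class TestConfusionCounts:
    def test_enumeration(self):
        c = confusion_counts(["cancer", "cancer", "non_cancer"],
                             ["cancer", "non_cancer", "non_cancer"])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 0)

    def test_identical_vectors(self):
        v = ["cancer", "non_cancer", "cancer"]
        c = confusion_counts(v, v)
        assert c.fn == c.fp == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts(["cancer"], ["cancer", "cancer"])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=1)


class TestDiagnosticMetrics:
    def test_likelihood_ratio_identities(self):
        rep = diagnostic_metrics(ConfusionCounts(tp=48, fp=14, fn=5, tn=50))
        sens, spec = rep.sensitivity.value, rep.specificity.value
        assert sens * 53 == pytest.approx(48, abs=1e-12)
        assert spec * 64 == pytest.approx(50, abs=1e-12)
        assert rep.plr.value == pytest.approx(sens / (1 - spec), abs=1e-12)
        assert rep.nlr.value == pytest.approx((1 - sens) / spec, abs=1e-12)
        for est in (rep.sensitivity, rep.specificity, rep.accuracy, rep.plr, rep.nlr):
            assert est.ci_low <= est.value <= est.ci_high

    def test_perfect_counts_degenerate(self):
        rep = diagnostic_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=10))
        assert rep.sensitivity.value == rep.specificity.value == 1.0
        assert rep.accuracy.value == 1.0
        assert np.isinf(rep.plr.value) and not rep.plr_defined
        assert rep.nlr.value == 0.0 and rep.nlr_defined

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            diagnostic_metrics(ConfusionCounts(tp=5, fp=0, fn=2, tn=0))


class TestWilson:
    def test_small_sample_interval(self):
        est = wilson_ci(1, 1)
        assert est.value == 1.0
        assert est.ci_low == pytest.approx(0.2065, abs=5e-4)
        assert est.ci_high == 1.0

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 7), (21, 24), (50, 50)])
    def test_interval_contains_point_within_unit(self, k, n):
        est = wilson_ci(k, n)
        assert 0.0 <= est.ci_low <= est.value <= est.ci_high <= 1.0

    def test_approaches_wald_for_large_n(self):
        n, k = 10**6, 300_000
        est = wilson_ci(k, n)
        p = k / n
        z = sps.norm.ppf(0.975)
        wald = z * np.sqrt(p * (1 - p) / n)
        assert est.ci_low == pytest.approx(p - wald, abs=1e-3)
        assert est.ci_high == pytest.approx(p + wald, abs=1e-3)


class TestStratifiedAccuracy:
    def test_per_stratum_proportions(self):
        pathology = ["atrophy_IM"] * 16 + ["IM"] * 7 + ["LGIN"] * 1
        correct = [True] * 10 + [False] * 6 + [True] * 7 + [True]
        tbl = stratified_accuracy(pathology, correct)
        by = tbl.set_index("pathology")
        assert by.loc["atrophy_IM", "proportion"] == pytest.approx(10 / 16)
        assert by.loc["IM", "proportion"] == 1.0
        assert by.loc["LGIN", "n"] == 1
        assert by.loc["LGIN", "ci_low"] == pytest.approx(0.2065, abs=5e-4)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            tbl = stratified_accuracy([], [])
        assert tbl.empty


class TestKappa:
    def test_perfect_agreement(self):
        est = cohens_kappa(["x", "y", "x"], ["x", "y", "x"])
        assert est.value == 1.0

    def test_hand_worked_example(self):
        est = cohens_kappa(list("++--"), list("+---"))
        assert est.value == pytest.approx(0.5)

    def test_independent_raters_near_zero(self, rng):
        a = rng.choice(["cancer", "non_cancer"], 10_000)
        b = rng.choice(["cancer", "non_cancer"], 10_000)
        assert abs(cohens_kappa(a, b).value) < 0.03

    def test_symmetry_and_relabeling_invariance(self, rng):
        a = rng.choice(list("abc"), 200)
        b = rng.choice(list("abc"), 200)
        assert cohens_kappa(a, b).value == pytest.approx(cohens_kappa(b, a).value)
        relabel = {"a": "z", "b": "y", "c": "x"}
        a2 = np.array([relabel[v] for v in a])
        b2 = np.array([relabel[v] for v in b])
        assert cohens_kappa(a2, b2).value == pytest.approx(cohens_kappa(a, b).value)

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_reference_implementation(self, seed):
        r = np.random.default_rng(seed)
        a = r.choice(["p", "q"], 30)
        b = np.where(r.random(30) < 0.7, a, r.choice(["p", "q"], 30))
        if (a == a[0]).all() and (b == a[0]).all():
            return
        assert cohens_kappa(a, b).value == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_constant_raters_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            cohens_kappa(["x", "x"], ["x", "x"])


class TestMcNemar:
    def test_no_discordance(self):
        assert mcnemar_test(0, 0).pvalue == 1.0

    def test_exact_binomial(self):
        res = mcnemar_test(10, 2)
        assert res.pvalue == pytest.approx(0.0386, abs=5e-5)

    def test_symmetric_discordance(self):
        assert mcnemar_test(5, 5).pvalue == 1.0

    def test_from_correctness_vectors(self):
        a = np.array([True] * 10 + [False] * 2 + [True] * 5)
        b = np.array([False] * 10 + [True] * 2 + [True] * 5)
        res = mcnemar_test(a, b)
        assert (res.b, res.c) == (10, 2)

    def test_chi_square_variant(self):
        res = mcnemar_test(10, 2, exact=False)
        stat = (10 - 2) ** 2 / 12
        assert res.pvalue == pytest.approx(float(sps.chi2.sf(stat, 1)))


class TestChi2AndFisher:
    def test_independence_gives_unit_p(self):
        stat, p = pearson_chi2_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_hand_formula(self, seed):
        r = np.random.default_rng(seed)
        a, b, c, d = (int(v) for v in r.integers(0, 30, 4))
        table = [[a, b], [c, d]]
        margins_ok = (a + b) and (c + d) and (a + c) and (b + d)
        if not margins_ok:
            with pytest.raises(ValueError, match="degenerate"):
                pearson_chi2_2x2(table)
            return
        stat, _ = pearson_chi2_2x2(table)
        n = a + b + c + d
        hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(hand, rel=1e-12)

    def test_fisher_examples(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == 1.0
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(0.0079, abs=5e-5)
        assert fisher_exact_2x2([[3, 4], [0, 0]]) == 1.0  # zero margin


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_fully_tied(self):
        u, p = mann_whitney([5.0], [5.0])
        assert u == 0.5 and p == 1.0

    def test_separated_large_groups(self, rng):
        a = rng.normal(10, 1, 50)
        b = rng.normal(0, 1, 50)
        _, p = mann_whitney(a, b)
        assert p < 1e-4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_asymptotic_close_to_exact_untied(self):
        # the continuity-corrected normal approximation tracks exact
        # enumeration closely at small untied samples: mean |Δp| < 0.01 and
        # worst case < 0.02 over random group sizes 5–8
        r = np.random.default_rng(1815)
        diffs = []
        for _ in range(500):
            n1, n2 = r.integers(5, 9, 2)
            vals = r.permutation(np.arange(n1 + n2, dtype=float))  # untied
            a, b = vals[:n1], vals[n1:]
            _, p_exact = mann_whitney(a, b, method="exact")
            _, p_asym = mann_whitney(a, b, method="asymptotic")
            diffs.append(abs(p_exact - p_asym))
        assert np.mean(diffs) < 0.01
        assert max(diffs) < 0.02


class TestRounding:
    @pytest.mark.parametrize(
        "x,nd,expected",
        [(0.625, 2, 0.63), (10 / 16, 2, 0.63), (0.905660, 2, 0.91),
         (0.0385742, 4, 0.0386), (0.781, 1, 0.8)],
    )
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected
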