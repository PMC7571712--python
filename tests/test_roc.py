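"""ROC estimation, bootstrap CIs, DeLong comparisons, operating points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import npxpanel as npx
from npxpanel import roc


def auc_by_pair_enumeration(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


def auc_by_midranks(scores, labels):
    from scipy.stats import rankdata

    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    r = rankdata(scores)
    n1, n0 = labels.sum(), (1 - labels).sum()
    return (r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def delong_brute_force(a, b, labels):
    """Placement components computed with explicit loops and the textbook
    variance-of-difference formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    labels = np.asarray(labels, int)

    def placements(s):
        pos, neg = s[labels == 1], s[labels == 0]
        v10 = np.array(
            [np.mean([(1.0 if x > y else 0.5 if x == y else 0.0) for y in neg]) for x in pos]
        )
        v01 = np.array(
            [np.mean([(1.0 if x > y else 0.5 if x == y else 0.0) for x in pos]) for y in neg]
        )
        return v10, v01

    v10a, v01a = placements(a)
    v10b, v01b = placements(b)
    var = np.var(v10a - v10b, ddof=1) / len(v10a) + np.var(v01a - v01b, ddof=1) / len(v01a)
    return v10a.mean(), v10b.mean(), var


scores_labels = st.integers(0, 10_000).map(
    lambda seed: (
        np.random.default_rng(seed).choice([0.0, 0.5, 1.0, 2.0, 3.5], size=12),
        np.random.default_rng(seed + 1).permutation([0] * 5 + [1] * 7),
    )
)


class TestEmpiricalAuc:
    @pytest.mark.parametrize(
        "scores,labels,want",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
            ([2, 2, 2, 2], [0, 0, 1, 1], 0.5),
            ([3, 1, 2, 4], [0, 0, 1, 1], 0.75),
        ],
    )
    def test_examples(self, scores, labels, want):
        assert npx.empirical_auc(scores, labels) == pytest.approx(want)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(scores_labels)
    def test_matches_both_oracles_with_ties(self, sl):
        scores, labels = sl
        got = npx.empirical_auc(scores, labels)
        assert got == pytest.approx(auc_by_pair_enumeration(scores, labels), abs=1e-12)
        assert got == pytest.approx(auc_by_midranks(scores, labels), abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(scores_labels)
    def test_complement_identity(self, sl):
        scores, labels = sl
        total = npx.empirical_auc(scores, labels) + npx.empirical_auc(-scores, labels)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            npx.empirical_auc([1.0, 2.0], [1, 1])


class TestBootstrapCi:
    def test_deterministic_under_seed(self, rng):
        s = rng.normal(size=40)
        y = np.repeat([0, 1], 20)
        a = npx.bootstrap_auc_ci(s, y, n_boot=200, seed=7)
        b = npx.bootstrap_auc_ci(s, y, n_boot=200, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_perfect_separation_upper_limit(self):
        est = npx.bootstrap_auc_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=100, seed=0)
        assert est.auc == 1.0 and est.ci_high == 1.0

    def test_interval_brackets_estimate(self, rng):
        s = rng.normal(size=80) + np.repeat([0.0, 1.0], 40)
        y = np.repeat([0, 1], 40)
        est = npx.bootstrap_auc_ci(s, y, n_boot=500, seed=3)
        assert est.ci_low <= est.auc <= est.ci_high

    def test_coverage_of_binormal_truth(self):
        """95% CI covers the closed-form AUC in >= 90% of 200 replicates
        at the discovery-cohort sample sizes (30 controls / 116 cases)."""
        truth = npx.binormal_auc(7.37, 0.72, 8.33, 0.64)
        rng = np.random.default_rng(42)
        hits = 0
        for rep in range(200):
            s, y = npx.simulate_two_group(7.37, 0.72, 8.33, 0.64, 30, 116, rng)
            est = npx.bootstrap_auc_ci(s, y, n_boot=500, seed=rep)
            hits += est.ci_low <= truth <= est.ci_high
        assert hits >= 0.90 * 200


class TestDelong:
    def test_self_comparison_p_one(self, rng):
        s = rng.normal(size=30)
        y = rng.permutation([0] * 10 + [1] * 20)
        d = npx.delong_paired_test(s, s, y)
        assert d.p == 1.0 and d.var_diff == 0.0 and d.z == 0.0

    def test_negating_both_scores_flips_z(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(scale=0.5, size=40)
        y = np.repeat([0, 1], 20)
        d1 = npx.delong_paired_test(a, b, y)
        d2 = npx.delong_paired_test(-a, -b, y)
        assert d1.z == pytest.approx(-d2.z, abs=1e-12)
        assert d1.p == pytest.approx(d2.p, abs=1e-12)

    def test_ten_sample_brute_force_oracle(self):
        a = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2, 0.9, 0.5, 0.6, 0.3])
        b = np.array([0.2, 0.3, 0.35, 0.7, 0.6, 0.1, 0.8, 0.4, 0.9, 0.5])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        auc_a, auc_b, var = delong_brute_force(a, b, y)
        d = npx.delong_paired_test(a, b, y)
        assert d.auc_a == pytest.approx(auc_a, abs=1e-12)
        assert d.auc_b == pytest.approx(auc_b, abs=1e-12)
        assert d.var_diff == pytest.approx(var, abs=1e-12)

    def test_single_auc_variance_components(self, rng):
        s = rng.normal(size=25)
        y = rng.permutation([0] * 12 + [1] * 13)
        pos, neg = s[y == 1], s[y == 0]
        v10 = np.array([np.mean((x > neg) + 0.5 * (x == neg)) for x in pos])
        v01 = np.array([np.mean((pos > x) + 0.5 * (pos == x)) for x in neg])
        want = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
        assert roc.delong_auc_variance(s, y) == pytest.approx(want, abs=1e-14)


class TestOperatingPoints:
    def test_perfect_classifier(self):
        s, y = np.array([1, 2, 3, 10, 11, 12.0]), np.array([0, 0, 0, 1, 1, 1])
        pt = npx.sensitivity_at_specificity(s, y, 0.95, n_boot=0)
        assert pt.sensitivity == 1.0 and pt.specificity == 1.0
        yj = npx.youden_point(s, y)
        assert yj.sensitivity == 1.0 and yj.specificity == 1.0

    def test_all_ties_degenerate(self):
        s, y = np.ones(10), np.repeat([0, 1], 5)
        pt = npx.sensitivity_at_specificity(s, y, 0.95, n_boot=0)
        assert pt.sensitivity == 0.0 and pt.specificity == 1.0

    def test_threshold_enumeration_example(self):
        s, y = np.arange(1.0, 7.0), np.array([0, 0, 0, 1, 1, 1])
        pt = npx.sensitivity_at_specificity(s, y, 0.95, n_boot=0)
        assert pt.sensitivity == 1.0 and pt.specificity == 1.0
        assert 3.0 < pt.threshold <= 4.0

    def test_youden_tie_broken_toward_specificity(self):
        pt = npx.youden_point([1, 2, 3, 4], [0, 1, 0, 1])
        assert (pt.sensitivity, pt.specificity) == (0.5, 1.0)

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(size=30)
        y = rng.permutation([0] * 15 + [1] * 15)
        a = npx.youden_point(s, y)
        b = npx.youden_point(np.exp(s), y)
        assert (a.sensitivity, a.specificity) == (b.sensitivity, b.specificity)

    def test_spec_at_sens_constraint_holds(self, rng):
        s = rng.normal(size=60) + np.repeat([0, 1.0], 30)
        y = np.repeat([0, 1], 30)
        pt = npx.specificity_at_sensitivity(s, y, 0.95, n_boot=50, seed=1)
        assert pt.sensitivity >= 0.95
        assert pt.ci_low is not None and pt.ci_low <= pt.specificity <= pt.ci_high + 1e-12


class TestUnivariateRanking:
    def test_flat_marker_excluded_and_flips_recorded(self, clean_cohort):
        df = npx.rank_univariate_auc(
            clean_cohort, npx.BENIGN_VS_CANCER, auc_threshold=0.0, n_boot=50, seed=0
        )
        assert (df["auc"] >= 0.5).all()
        by_prot = df.set_index("protein")
        # down-regulated markers rank by discrimination, orientation recorded
        for prot in ("ITGAV", "DNER", "CTSV"):
            assert bool(by_prot.loc[prot, "flipped"])
            assert by_prot.loc[prot, "auc"] > 0.6
        assert not bool(by_prot.loc["WFDC2", "flipped"])
        strong = df.loc[df["auc"] > 0.7, "protein"]
        assert not any(p.startswith("NOISE") for p in strong)
        assert "WFDC2" in set(df.head(5)["protein"])
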