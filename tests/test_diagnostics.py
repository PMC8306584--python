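import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from ramancd import (
    MarkerRecord,
    accuracy_at_cutoff,
    auc_ci,
    clopper_pearson,
    kde_fit,
    roc_curve,
    youden_optimal,
)
from ramancd.exceptions import ConfigError, DataError


def auc_by_pair_counting(pos, neg):
    """Independent oracle: concordant pairs (+ half ties) / all pairs."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def youden_by_exhaustive_scan(pos, neg):
    """Independent oracle: best (J, spec, -cutoff) over observed thresholds."""
    best = None
    for t in sorted(set(pos) | set(neg)):
        sens = sum(p > t for p in pos) / len(pos)
        spec = sum(n <= t for n in neg) / len(neg)
        j = sens + spec - 1
        key = (j, spec, -t)
        if best is None or key > best[0]:
            best = (key, t, j)
    return best[1], best[2]


# integer scores force ties between and within groups
score_sets = st.tuples(
    st.lists(st.integers(0, 12), min_size=1, max_size=30),
    st.lists(st.integers(0, 12), min_size=1, max_size=30),
)


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([3, 4, 1, 2], ["CD", "CD", "nonCD", "nonCD"])
        assert roc.auc == 1.0

    def test_reversed_separation(self):
        roc = roc_curve([1, 2, 3, 4], ["CD", "CD", "nonCD", "nonCD"])
        assert roc.auc == 0.0

    def test_tied_overlap_example(self):
        # pos {1,2,3} vs neg {2,3,4}: 1 win + 2 half-ties over 9 pairs
        roc = roc_curve([1, 2, 3, 2, 3, 4], [1, 1, 1, 0, 0, 0])
        assert roc.auc == pytest.approx(2 / 9)

    def test_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        roc = roc_curve(scores, labels)
        assert (roc.fpr[0], roc.sens[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.sens[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.sens) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_curve([1, 2], ["CD", "CD"])

    @given(score_sets)
    def test_trapezoid_auc_equals_pair_counting(self, sets):
        """AUC by trapezoid rule == tie-corrected Mann-Whitney, exactly."""
        pos, neg = sets
        roc = roc_curve(pos + neg, [1] * len(pos) + [0] * len(neg))
        assert roc.auc == pytest.approx(auc_by_pair_counting(pos, neg), abs=1e-12)

    @given(score_sets)
    def test_label_inversion_flips_auc(self, sets):
        pos, neg = sets
        scores = pos + neg
        a = roc_curve(scores, [1] * len(pos) + [0] * len(neg)).auc
        b = roc_curve(scores, [0] * len(pos) + [1] * len(neg)).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_agreement_with_reference_implementation(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=60).round(1)  # rounding makes ties
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_binormal_closed_form(self, rng):
        """Empirical AUC of N(0,1) vs N(delta,1) ~= Phi(delta/sqrt(2))."""
        delta = 1.2
        neg = rng.normal(0, 1, 500)
        pos = rng.normal(delta, 1, 500)
        roc = roc_curve(
            np.concatenate([pos, neg]), np.r_[np.ones(500), np.zeros(500)]
        )
        lo, hi = auc_ci(roc, method="delong")
        se = (hi - lo) / (2 * 1.959964)
        assert abs(roc.auc - norm.cdf(delta / np.sqrt(2))) < 3 * se


class TestAucCi:
    def _roc(self, pos, neg):
        return roc_curve(
            np.concatenate([pos, neg]),
            np.r_[np.ones(len(pos)), np.zeros(len(neg))],
        )

    def test_perfect_separation_interval(self, rng):
        roc = self._roc(rng.normal(10, 1, 20), rng.normal(0, 1, 20))
        lo, hi = auc_ci(roc, seed=0)
        assert hi == 1.0
        assert lo > 0.8

    def test_bootstrap_deterministic_under_seed(self, rng):
        roc = self._roc(rng.normal(1, 1, 15), rng.normal(0, 1, 15))
        assert auc_ci(roc, seed=5) == auc_ci(roc, seed=5)

    def test_null_interval_contains_half(self, rng):
        """Same score distribution in both groups: CI should cover 0.5."""
        covered = 0
        for _ in range(20):
            roc = self._roc(rng.normal(0, 1, 50), rng.normal(0, 1, 50))
            lo, hi = auc_ci(roc, n_boot=300, seed=1)
            covered += lo <= 0.5 <= hi
        assert covered >= 18

    def test_small_n_boot_rejected(self, rng):
        roc = self._roc(rng.normal(1, 1, 10), rng.normal(0, 1, 10))
        with pytest.raises(ConfigError):
            auc_ci(roc, n_boot=10)

    def test_delong_contains_point_estimate(self, rng):
        roc = self._roc(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        lo, hi = auc_ci(roc, method="delong")
        assert lo <= roc.auc <= hi


class TestYouden:
    def test_perfect_separation_selects_highest_negative(self):
        roc = roc_curve([10, 11, 12, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        rep = youden_optimal(roc)
        assert rep.youden_j == 1.0
        assert rep.cutoff == 3.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.cutoff_midpoint == pytest.approx(2.5)

    def test_no_discrimination(self):
        roc = roc_curve([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert youden_optimal(roc).youden_j == pytest.approx(0.0)

    def test_overlapping_example_matches_scan(self):
        pos, neg = [2, 3, 4, 5], [1, 2, 3]
        roc = roc_curve(pos + neg, [1] * 4 + [0] * 3)
        rep = youden_optimal(roc)
        cut, j = youden_by_exhaustive_scan(pos, neg)
        assert rep.cutoff == cut
        assert rep.youden_j == pytest.approx(j)

    @given(score_sets)
    def test_matches_exhaustive_scan(self, sets):
        """Reported cutoff and J equal the brute-force threshold scan."""
        pos, neg = sets
        roc = roc_curve(pos + neg, [1] * len(pos) + [0] * len(neg))
        rep = youden_optimal(roc)
        cut, j = youden_by_exhaustive_scan(pos, neg)
        assert rep.youden_j == pytest.approx(j, abs=1e-12)
        assert rep.cutoff == cut

    def test_cis_contain_point_estimates(self, rng):
        roc = roc_curve(rng.normal(1, 1, 40), rng.integers(0, 2, 40) * 0 + np.r_[np.ones(20), np.zeros(20)])
        rep = youden_optimal(roc)
        assert rep.sens_ci[0] <= rep.sensitivity <= rep.sens_ci[1]
        assert rep.spec_ci[0] <= rep.specificity <= rep.spec_ci[1]


class TestClopperPearson:
    @pytest.mark.parametrize(
        "s,n,expected",
        [
            (22, 23, (0.781, 0.999)),
            (23, 25, (0.740, 0.990)),
            (24, 25, (0.796, 0.999)),
        ],
    )
    def test_published_interval_arithmetic(self, s, n, expected):
        """The printed sensitivity/specificity limits to 3 decimals."""
        lo, hi = clopper_pearson(s, n, 0.95)
        assert round(lo, 3) == expected[0]
        assert round(hi, 3) == expected[1]

    def test_zero_successes_lower_limit_is_zero(self):
        lo, hi = clopper_pearson(0, 10, 0.95)
        assert lo == 0.0
        assert 0 < hi < 1

    def test_all_successes_upper_limit_is_one(self):
        lo, hi = clopper_pearson(10, 10, 0.95)
        assert hi == 1.0

    def test_agreement_with_reference_implementation(self):
        from statsmodels.stats.proportion import proportion_confint

        for s, n in [(3, 17), (22, 23), (12, 40)]:
            lo, hi = clopper_pearson(s, n, 0.95)
            ref = proportion_confint(s, n, 0.05, method="beta")
            assert (lo, hi) == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("s,n,conf", [(-1, 10, 0.95), (11, 10, 0.95), (5, 0, 0.95), (5, 10, 1.5)])
    def test_domain_errors(self, s, n, conf):
        with pytest.raises(DataError):
            clopper_pearson(s, n, conf)


class TestKde:
    def test_standard_normal_density_at_zero(self, rng):
        grid, dens = kde_fit(rng.normal(size=1000))
        at0 = np.interp(0.0, grid, dens)
        assert at0 == pytest.approx(1 / np.sqrt(2 * np.pi), rel=0.15)

    def test_integrates_to_one(self, rng):
        grid, dens = kde_fit(rng.normal(size=200))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DataError):
            kde_fit([2.0, 2.0, 2.0])


class TestAccuracy:
    def _records(self, vals, labels):
        return [
            MarkerRecord(f"s{i}", v, v, lab) for i, (v, lab) in enumerate(zip(vals, labels))
        ]

    def test_perfect_split(self):
        recs = self._records([5, 6, 1, 2], ["CD", "CD", "nonCD", "nonCD"])
        assert accuracy_at_cutoff(recs, 3.0, "r1450") == 1.0

    def test_at_cutoff_counts_as_negative(self):
        recs = self._records([3.0, 1.0], ["CD", "nonCD"])
        assert accuracy_at_cutoff(recs, 3.0, "r1450") == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            accuracy_at_cutoff([], 1.0, "r1450")
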