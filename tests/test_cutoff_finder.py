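"""Cut-off discovery against independent brute-force oracles."""
import itertools
import logging
import math

import numpy as np
import pytest
from scipy import stats

from methrisk.cutoff_finder import (
    CutoffPurpose,
    minp_logrank_cutoff,
    minp_ttest_cutoff,
    proportion_above,
    roc_auc,
    youden_cutoff,
)

logging.getLogger("methrisk").setLevel(logging.ERROR)


def brute_force_auc(pos, neg):
    """All-pairs concordance count, ties worth 1/2 — the Mann-Whitney
    identity spelled out pair by pair."""
    score = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                score += 1.0
            elif p == q:
                score += 0.5
    return score / (len(pos) * len(neg))


class TestRocAuc:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([10, 11], [1, 2], 1.0),
            ([3, 1, 2], [3, 1, 2], 0.5),
            ([3, 5], [1, 4], 0.75),
        ],
    )
    def test_known_values(self, pos, neg, expected):
        assert roc_auc(pos, neg) == pytest.approx(expected)

    def test_matches_all_pairs_oracle_on_random_instances(self, rng):
        for _ in range(1000):
            pos = rng.integers(0, 8, size=rng.integers(1, 9)).astype(float)
            neg = rng.integers(0, 8, size=rng.integers(1, 9)).astype(float)
            assert roc_auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))

    def test_complement_symmetry(self, rng):
        for _ in range(200):
            pos = rng.integers(0, 5, size=6).astype(float)
            neg = rng.integers(0, 5, size=4).astype(float)
            assert roc_auc(pos, neg) + roc_auc(neg, pos) == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])


def brute_force_youden(pos, neg):
    best = (-math.inf, None)
    for theta in sorted(set(pos) | set(neg)):
        sens = sum(v >= theta for v in pos) / len(pos)
        spec = sum(v < theta for v in neg) / len(neg)
        j = sens + spec - 1
        if j >= best[0]:
            best = (j, theta)
    return best[1]


class TestYoudenCutoff:
    def test_separable_classes(self):
        result = youden_cutoff([10, 12, 14], [1, 2, 3])
        assert result.threshold == 10
        assert result.sensitivity + result.specificity - 1 == pytest.approx(1.0)

    def test_exhaustive_scan_example(self):
        result = youden_cutoff([2, 5, 6], [1, 2, 3])
        assert result.threshold == 5
        assert result.sensitivity == pytest.approx(2 / 3)
        assert result.specificity == pytest.approx(1.0)

    def test_identical_classes_tie_break_to_max(self):
        result = youden_cutoff([1, 2, 3], [1, 2, 3])
        assert result.threshold == 3  # J = 0 everywhere; larger theta wins
        assert result.auc == pytest.approx(0.5)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(300):
            pos = rng.integers(0, 10, size=rng.integers(2, 12)).astype(float)
            neg = rng.integers(0, 10, size=rng.integers(2, 12)).astype(float)
            assert youden_cutoff(pos, neg).threshold == brute_force_youden(
                list(pos), list(neg)
            )

    def test_invariant_under_monotone_transform(self, rng):
        """The selected threshold maps through any strictly increasing
        transform; sensitivity and specificity are unchanged."""
        for transform in (np.exp, lambda x: x**3, lambda x: 5 * x - 2):
            pos = rng.normal(2, 1, size=15)
            neg = rng.normal(0, 1, size=15)
            plain = youden_cutoff(pos, neg)
            warped = youden_cutoff(transform(pos), transform(neg))
            assert warped.threshold == pytest.approx(
                float(transform(np.array([plain.threshold]))[0])
            )
            assert warped.sensitivity == pytest.approx(plain.sensitivity)
            assert warped.specificity == pytest.approx(plain.specificity)


class TestProportionAbove:
    def test_printed_style_percent(self, rng):
        values = np.concatenate([np.full(48, 7.0), np.full(10, 1.0)])
        assert proportion_above(values, 6.49) == 82.8  # 48 of 58

    def test_edge_conventions(self):
        assert proportion_above([1, 2, 3], 10.0) == 0.0
        assert proportion_above([5, 5, 5], 5.0) == 100.0  # >= is positive


def brute_force_logrank_scan(values, times, events, min_frac, lifelines_test):
    """Independent scan: every unique value, eligibility by group size,
    log-rank p via lifelines."""
    n = len(values)
    best = None
    for theta in sorted(set(values)):
        high = values >= theta
        k = math.ceil(min_frac * n)
        if high.sum() < k or (~high).sum() < k:
            continue
        p = lifelines_test(
            times[high], times[~high], events[high], events[~high]
        ).p_value
        if best is None or p <= best[1]:
            best = (theta, p)
    return best


class TestMinpLogrank:
    def test_no_information_returns_not_found(self):
        result = minp_logrank_cutoff(
            [1, 2, 3, 4], [5, 5, 5, 5], [True] * 4, min_group_frac=0.2
        )
        assert not result.found
        assert result.threshold is None

    def test_clear_split_matches_oracle(self):
        from lifelines.statistics import logrank_test

        values = np.array([10.0, 10, 10, 1, 1, 1])
        times = np.array([1.0, 2, 3, 60, 60, 60])
        events = np.array([True, True, True, False, False, False])
        result = minp_logrank_cutoff(values, times, events, min_group_frac=0.1)
        theta, p = brute_force_logrank_scan(values, times, events, 0.1, logrank_test)
        assert result.found
        assert result.threshold == theta == 10.0
        assert result.scan_p == pytest.approx(p, rel=1e-6)
        assert result.relative_risk is not None and result.relative_risk > 1

    def test_eligibility_rule_skips_small_groups(self):
        # n = 10, min fraction 0.2 -> both groups need >= 2 members
        values = np.array([9.0] + [1.0] * 9)
        times = np.arange(1.0, 11.0)
        events = np.ones(10, bool)
        result = minp_logrank_cutoff(values, times, events, min_group_frac=0.2)
        # theta = 9 would leave a singleton high group: never selected
        assert result.threshold != 9.0

    def test_matches_brute_force_on_random_instances(self, rng):
        from lifelines.statistics import logrank_test

        for _ in range(25):
            n = int(rng.integers(10, 31))
            values = rng.integers(0, 6, size=n).astype(float)
            times = rng.exponential(20, size=n)
            events = rng.uniform(size=n) < 0.7
            if events.sum() == 0:
                continue
            oracle = brute_force_logrank_scan(values, times, events, 0.1, logrank_test)
            if oracle is None:
                continue
            result = minp_logrank_cutoff(values, times, events, min_group_frac=0.1,
                                         alpha=1.0 - 1e-12)
            assert result.threshold == pytest.approx(oracle[0])
            assert result.scan_p == pytest.approx(oracle[1], rel=1e-6)

    def test_recovers_hazard_switch_threshold(self, rng):
        """A hazard that switches at value 20 is located by the scan in at
        least 90% of replicates (40 cohorts of n = 120)."""
        hits = 0
        for _ in range(40):
            values = rng.uniform(0, 40, size=120)
            rate = np.where(values >= 20, 0.08, 0.01)
            times = np.minimum(rng.exponential(1 / rate), 60.0)
            events = times < 60.0
            result = minp_logrank_cutoff(values, times, events, min_group_frac=0.1)
            if result.found and 15 <= result.threshold <= 25:
                hits += 1
        assert hits >= 36


def brute_force_ttest_scan(values, terms, min_frac):
    n = len(values)
    best = None
    for theta in sorted(set(values)):
        high = values >= theta
        k = math.ceil(min_frac * n)
        if high.sum() < k or (~high).sum() < k:
            continue
        if high.sum() < 2 or (~high).sum() < 2:
            p = 1.0
        else:
            p = float(stats.ttest_ind(terms[high], terms[~high], equal_var=True)[1])
        if best is None or p <= best[1]:
            best = (theta, p)
    return best


class TestMinpTtest:
    def test_example_split(self):
        values = np.array([0.1, 0.1, 0.2, 1.0, 1.1, 1.2])
        terms = np.array([120.0, 130, 110, 40, 50, 45])
        result = minp_ttest_cutoff(values, terms)
        oracle = brute_force_ttest_scan(values, terms, 0.1)
        assert result.found
        assert result.threshold == oracle[0] == 1.0
        assert result.scan_p == pytest.approx(oracle[1])
        assert result.group_high["mean"] == pytest.approx(45.0)
        assert result.group_low["mean"] == pytest.approx(120.0)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 31))
            values = rng.integers(0, 5, size=n).astype(float)
            terms = rng.normal(100, 40, size=n)
            oracle = brute_force_ttest_scan(values, terms, 0.1)
            if oracle is None:
                continue
            result = minp_ttest_cutoff(values, terms)
            assert result.threshold == pytest.approx(oracle[0])
            assert result.scan_p == pytest.approx(oracle[1])

    def test_constant_values_not_found(self):
        result = minp_ttest_cutoff([2.0] * 6, [10.0, 20, 30, 40, 50, 60])
        assert not result.found

    def test_minimum_p_selection_is_anticonservative(self, rng):
        """Under the null (terms independent of values) the selected minimum
        p is stochastically below uniform — the scan's known inflation."""
        min_ps = []
        for _ in range(300):
            values = rng.uniform(0, 1, size=24)
            terms = rng.normal(100, 40, size=24)
            result = minp_ttest_cutoff(values, terms)
            min_ps.append(result.scan_p)
        min_ps = np.array(min_ps)
        # stochastically dominated by U(0,1): heavy excess below 0.05
        assert (min_ps < 0.05).mean() > 2 * 0.05
        assert stats.kstest(min_ps, "uniform", alternative="greater").pvalue < 0.01

    def test_permutation_adjustment_deflates_selection(self, rng):
        values = rng.uniform(0, 1, size=20)
        terms = rng.normal(100, 40, size=20)
        result = minp_ttest_cutoff(values, terms, n_permutations=200, rng=rng)
        assert result.scan_p_adjusted is not None
        assert result.scan_p_adjusted >= result.scan_p
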