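import numpy as np
import pandas as pd
import pytest

from seasonomics.cohort import CohortDesign, FeatureSpec, generate_features, generate_visits
from seasonomics.intervals import (GroupFit, IntervalError, NullPool,
                                   call_significant, fit_group_curves,
                                   grid_days, interval_pvalues,
                                   interval_statistics, permutation_null,
                                   permuted_labels, run_interval_test)


def _const_fit(label, value, se, T=52):
    g = grid_days(T)
    return GroupFit(label, g, np.full(T, float(value)), np.full(T, float(se)))


class TestStatistic:
    def test_identical_curves_all_zero(self):
        st = interval_statistics(_const_fit("IR", 1.0, 0.5),
                                 _const_fit("IS", 1.0, 0.5)).statistics
        np.testing.assert_allclose(st, 0.0, atol=1e-15)

    def test_unit_offset_unit_se_closed_form(self):
        # trapezoid area difference 1, denominator sqrt(1 + 1)
        st = interval_statistics(_const_fit("IR", 1.0, 1.0),
                                 _const_fit("IS", 0.0, 1.0)).statistics
        np.testing.assert_allclose(st, 1.0 / np.sqrt(2.0), atol=1e-12)

    def test_group_swap_negates(self):
        rng = np.random.default_rng(0)
        g = grid_days(30)
        f1 = GroupFit("IR", g, rng.normal(0, 1, 30), rng.uniform(0.1, 1, 30))
        f2 = GroupFit("IS", g, rng.normal(0, 1, 30), rng.uniform(0.1, 1, 30))
        a = interval_statistics(f1, f2).statistics
        b = interval_statistics(f2, f1).statistics
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_zero_se_zero_difference_is_zero(self):
        st = interval_statistics(_const_fit("IR", 1.0, 0.0),
                                 _const_fit("IS", 1.0, 0.0)).statistics
        np.testing.assert_allclose(st, 0.0)

    def test_zero_se_nonzero_difference_rejected(self):
        with pytest.raises(IntervalError):
            interval_statistics(_const_fit("IR", 1.0, 0.0),
                                _const_fit("IS", 0.0, 0.0))


class TestPvalues:
    def test_toy_pool_hand_count(self):
        # pool {0.5, 1.5} (B=1, T-1=2); observed (1.0, 2.0), positive side
        null = NullPool(statistics=np.array([[0.5, 1.5]]), unit="subject", seed=0)
        obs = interval_statistics(_const_fit("IR", 1.0, 1.0, T=3),
                                  _const_fit("IS", 0.0, 1.0, T=3))
        obs.statistics = np.array([1.0, 2.0])
        np.testing.assert_allclose(interval_pvalues(obs, null), [0.5, 0.0])

    def test_observed_above_all_null_gives_zero(self):
        null = NullPool(np.full((5, 4), 0.1), "subject", 0)
        obs = interval_statistics(_const_fit("IR", 1.0, 1.0, T=5),
                                  _const_fit("IS", 0.0, 1.0, T=5))
        np.testing.assert_allclose(interval_pvalues(obs, null), 0.0)

    def test_observed_below_all_null_gives_one(self):
        null = NullPool(np.full((5, 4), 9.9), "subject", 0)
        obs = interval_statistics(_const_fit("IR", 1.0, 1.0, T=5),
                                  _const_fit("IS", 0.0, 1.0, T=5))
        np.testing.assert_allclose(interval_pvalues(obs, null), 1.0)

    def test_larger_magnitude_never_larger_p(self):
        rng = np.random.default_rng(1)
        null = NullPool(rng.normal(0, 1, (40, 9)), "subject", 0)
        g = grid_days(10)
        lo = GroupFit("IR", g, np.full(10, 0.5), np.ones(10))
        hi = GroupFit("IR", g, np.full(10, 2.0), np.ones(10))
        ref = GroupFit("IS", g, np.zeros(10), np.ones(10))
        p_lo = interval_pvalues(interval_statistics(lo, ref), null)
        p_hi = interval_pvalues(interval_statistics(hi, ref), null)
        assert (p_hi <= p_lo + 1e-12).all()

    def test_empty_pool_rejected(self):
        obs = interval_statistics(_const_fit("IR", 1.0, 1.0, T=3),
                                  _const_fit("IS", 0.0, 1.0, T=3))
        with pytest.raises(IntervalError):
            interval_pvalues(obs, NullPool(np.empty((0, 2)), "subject", 0))


def _bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestCalling:
    def test_bh_matches_hand_example(self):
        res = call_significant(np.array([0.01, 0.02, 0.04, 0.5]), grid_days(5))
        np.testing.assert_allclose(res.adjusted, [0.04, 0.04, 0.04 * 4 / 3, 0.5],
                                   atol=1e-12)

    def test_bh_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            res = call_significant(p, grid_days(len(p) + 1))
            np.testing.assert_allclose(res.adjusted, _bh_oracle(p), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(3)
        p = rng.random(51)
        res = call_significant(p, grid_days(52))
        assert (res.adjusted >= p - 1e-15).all()

    def test_classification_rules(self):
        g = grid_days(5)
        assert call_significant(np.ones(4), g).classification == "none"
        assert call_significant(np.zeros(4), g).classification == "global"
        half = call_significant(np.array([0.0, 0.0, 0.9, 0.9]), g)
        assert half.classification == "partial"
        assert half.significant_ranges == [(1.0, 183.0)]

    def test_wraparound_ranges_merged(self):
        p = np.array([0.0, 0.9, 0.9, 0.0])  # first and last interval
        res = call_significant(p, grid_days(5))
        assert len(res.significant_ranges) == 1
        (a, b), = res.significant_ranges
        assert a > b  # wraps across day 365 -> 1

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(IntervalError):
            call_significant(np.array([0.1, 1.2]), grid_days(3))


@pytest.fixture(scope="module")
def small_visits():
    return generate_visits(CohortDesign(n_subjects=20, n_years=2,
                                        visits_per_year=6, seed=6))


class TestGroupFits:

    def test_identical_relabeled_groups_agree(self, small_visits):
        rng = np.random.default_rng(4)
        v = small_visits.copy()
        y = np.sin(2 * np.pi * v["day_of_year"] / 365).to_numpy() \
            + rng.normal(0, 0.2, len(v))
        # duplicate every subject into one IR and one IS twin with equal data
        v_ir = v.assign(group="IR", subject_id=v.subject_id + "_a")
        v_is = v.assign(group="IS", subject_id=v.subject_id + "_b")
        vv = pd.concat([v_ir, v_is], ignore_index=True)
        yy = np.concatenate([y, y])
        f1, f2 = fit_group_curves(yy, vv, T=26)
        assert np.abs(f1.fitted - f2.fitted).max() < 1e-6

    def test_constant_offset_recovered(self):
        d = CohortDesign(n_subjects=80, n_years=3, visits_per_year=6, seed=7)
        v = generate_visits(d)
        rng = np.random.default_rng(5)
        y = rng.normal(0, 0.3, len(v)) + 1.5 * (v["group"] == "IR").to_numpy()
        f1, f2 = fit_group_curves(y, v, T=26)
        np.testing.assert_allclose(f1.fitted - f2.fitted, 1.5, atol=0.15)

    def test_se_shrinks_with_sample_size(self):
        rng = np.random.default_rng(8)
        ses = []
        for n_subj in (12, 48):
            d = CohortDesign(n_subjects=n_subj, n_years=3, visits_per_year=4,
                             seed=9)
            v = generate_visits(d)
            y = rng.normal(0, 1, len(v))
            f1, _ = fit_group_curves(y, v, T=26)
            ses.append(np.median(f1.se))
        assert ses[1] < ses[0]

    def test_empty_group_named_in_error(self, small_visits):
        v = small_visits.assign(group="IR")
        with pytest.raises(IntervalError, match="IS"):
            fit_group_curves(np.zeros(len(v)), v, T=13)


class TestPermutation:
    def test_subject_unit_moves_visits_together(self, ):
        v = generate_visits(CohortDesign(n_subjects=15, n_years=2,
                                         visits_per_year=5, seed=10))
        rng = np.random.default_rng(0)
        for _ in range(10):
            lab = permuted_labels(v, "subject", rng)
            per_subj = pd.DataFrame({"s": v.subject_id, "l": lab}).groupby("s")["l"].nunique()
            assert (per_subj == 1).all()
        # label multiset is preserved (drawn without replacement)
        assert sorted(lab) == sorted(v["group"])

    def test_sample_unit_preserves_label_counts(self):
        v = generate_visits(CohortDesign(n_subjects=10, n_years=1,
                                         visits_per_year=6, seed=12))
        rng = np.random.default_rng(1)
        lab = permuted_labels(v, "sample", rng)
        assert sorted(lab) == sorted(v["group"])

    def test_same_seed_identical_pool(self):
        d = CohortDesign(n_subjects=16, n_years=2, visits_per_year=4, seed=13)
        v = generate_visits(d)
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, len(v))
        a = permutation_null(y, v, B=3, seed=42, T=13)
        b = permutation_null(y, v, B=3, seed=42, T=13)
        np.testing.assert_array_equal(a.statistics, b.statistics)

    def test_invalid_B_and_unit_rejected(self, ):
        v = generate_visits(CohortDesign(n_subjects=6, seed=14))
        with pytest.raises(IntervalError):
            permutation_null(np.zeros(len(v)), v, B=0)
        with pytest.raises(IntervalError):
            permutation_null(np.zeros(len(v)), v, B=1, unit="visit")


def test_end_to_end_reproducible():
    d = CohortDesign(n_subjects=20, n_years=2, visits_per_year=5, seed=15)
    v = generate_visits(d)
    spec = FeatureSpec("d", kind="differential", amplitude=0.0,
                       diff_window=(100, 230), diff_effect=2.0)
    long, _ = generate_features(d, [spec], v)
    y = long["value"].to_numpy()
    a = run_interval_test(y, long, B=30, T=13, seed=3)
    b = run_interval_test(y, long, B=30, T=13, seed=3)
    np.testing.assert_array_equal(a.pvalues, b.pvalues)
    assert a.classification == b.classification
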