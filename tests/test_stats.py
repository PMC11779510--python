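"""Pointwise statistics: paired t, BH-FDR vs brute force, interval rule vs
exhaustive scan, power function and effect size."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aristop import (AnalysisConfig, bh_fdr, cohens_d_paired,
                     longest_qualified_interval, paired_t_power,
                     pointwise_paired_t)
from aristop.errors import DegenerateInputError, UsageError
from aristop.types import EpochMatrix


def make_matrix(values, condition="a"):
    values = np.asarray(values, dtype=float)
    return EpochMatrix(values=values, times=np.arange(values.shape[1], dtype=float),
                       lock="stop_signal", condition=condition,
                       channel="left_ADM")


class TestPointwisePairedT:
    def test_identical_conditions_give_null(self, rng):
        v = rng.normal(size=(6, 50))
        res = pointwise_paired_t(make_matrix(v), make_matrix(v.copy()))
        assert np.all(res.t_values == 0.0)
        assert np.all(res.p_values == 1.0)
        assert not res.fdr_mask.any()
        assert res.df == 5

    def test_closed_form_three_participants(self):
        # differences {1,2,3}: t = 2 / (1/sqrt(3)) = 3.464, p ~ 0.074 (df 2)
        a = make_matrix([[1.0], [2.0], [3.0]])
        b = make_matrix([[0.0], [0.0], [0.0]])
        res = pointwise_paired_t(a, b)
        assert res.t_values[0] == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert res.p_values[0] == pytest.approx(0.07418, abs=2e-4)

    def test_matches_scipy_ttest_rel(self, rng):
        from scipy import stats as sp
        a, b = rng.normal(size=(2, 10, 30))
        res = pointwise_paired_t(make_matrix(a), make_matrix(b))
        t_ref, p_ref = sp.ttest_rel(a, b, axis=0)
        np.testing.assert_allclose(res.t_values, t_ref, rtol=1e-10)
        np.testing.assert_allclose(res.p_values, p_ref, rtol=1e-10)

    def test_constant_nonzero_difference_is_degenerate(self):
        a = make_matrix(np.ones((4, 3)))
        b = make_matrix(np.zeros((4, 3)))
        res = pointwise_paired_t(a, b)
        assert np.isnan(res.p_values).all()
        assert not res.fdr_mask.any()

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(UsageError):
            pointwise_paired_t(make_matrix(rng.normal(size=(4, 5))),
                               make_matrix(rng.normal(size=(4, 6))))


def bh_oracle(p, q):
    """Literal step-up definition, quadratic and index-based."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    if k_star:
        mask[order[:k_star]] = True
    return mask


class TestBHFDR:
    def test_all_ones_no_rejection(self):
        assert not bh_fdr(np.ones(10)).any()

    def test_step_up_rescues_small_pvalues(self):
        # p(4) = 0.04 <= 0.05 -> all four rejected
        mask = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert mask.all()

    def test_step_up_partial_rejection(self):
        mask = bh_fdr([0.001, 0.2, 0.3], q=0.05)
        np.testing.assert_array_equal(mask, [True, False, False])

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_nan_pvalues_never_rejected(self):
        mask = bh_fdr([0.001, np.nan, 0.002], q=0.05)
        np.testing.assert_array_equal(mask, [True, False, True])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    def test_matches_brute_force_oracle(self, pvals, q):
        p = np.array(pvals)
        np.testing.assert_array_equal(bh_fdr(p, q), bh_oracle(p, q))


def interval_oracle(mask, min_prop=0.9):
    """Exhaustive O(n^2) scan over all contiguous intervals."""
    mask = np.asarray(mask, dtype=bool)
    best = None  # (length, start)
    n = mask.size
    for i in range(n):
        for j in range(i, n):
            length = j - i + 1
            if mask[i:j + 1].sum() > min_prop * length + 1e-12:
                if best is None or length > best[0]:
                    best = (length, i)
    if best is None:
        return None
    return best[1], best[1] + best[0] - 1


class TestLongestQualifiedInterval:
    def test_all_true_covers_everything(self):
        iv = longest_qualified_interval(np.ones(25, dtype=bool))
        assert (iv.onset, iv.offset, iv.n_points) == (0.0, 24.0, 25)
        assert iv.prop_significant == 1.0

    def test_all_false_is_absent(self):
        assert longest_qualified_interval(np.zeros(25, dtype=bool)) is None

    def test_hand_worked_mask(self):
        # full span is 9/10 = 0.9, not > 0.9; the qualifying run is 4..9
        mask = np.array([1, 1, 1, 0, 1, 1, 1, 1, 1, 1], dtype=bool)
        iv = longest_qualified_interval(mask)
        assert (iv.onset, iv.offset, iv.n_points) == (4.0, 9.0, 6)

    def test_times_axis_respected(self):
        times = np.linspace(-100.0, 98.0, 100)
        mask = np.zeros(100, dtype=bool)
        mask[50:60] = True
        iv = longest_qualified_interval(mask, times=times)
        # one flanking gap point still keeps the fraction above 0.9 (10/11);
        # earliest-onset tie-break extends the interval one sample left
        assert iv.onset == pytest.approx(times[49])
        assert iv.offset == pytest.approx(times[59])
        assert iv.n_points == 11

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=120),
           st.sampled_from([0.5, 0.75, 0.9]))
    def test_matches_exhaustive_oracle(self, bits, min_prop):
        mask = np.array(bits, dtype=bool)
        got = longest_qualified_interval(mask, min_prop=min_prop)
        want = interval_oracle(mask, min_prop)
        if want is None:
            assert got is None
        else:
            assert (got.onset, got.offset) == want


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        assert paired_t_power(18, 0.0, alpha=0.05) == pytest.approx(0.05,
                                                                    abs=1e-10)

    def test_monte_carlo_agreement(self):
        # 1e5 simulated paired-t experiments at n=10, d=1
        rng = np.random.default_rng(7)
        n, d, reps = 10, 1.0, 100_000
        x = rng.normal(d, 1.0, size=(reps, n))
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        from scipy import stats as sp
        tc = sp.t.ppf(0.975, n - 1)
        mc = (np.abs(t) > tc).mean()
        assert paired_t_power(n, d) == pytest.approx(mc, abs=0.01)

    def test_monotone_in_n_and_d(self):
        powers_n = [paired_t_power(n, 0.6) for n in (5, 10, 20, 40)]
        assert powers_n == sorted(powers_n)
        powers_d = [paired_t_power(12, d) for d in (0.1, 0.4, 0.8, 1.2)]
        assert powers_d == sorted(powers_d)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(UsageError):
            paired_t_power(1, 0.5)
        with pytest.raises(UsageError):
            paired_t_power(10, -0.1)


class TestCohensD:
    def test_zero_mean_differences(self):
        assert cohens_d_paired([1, 1, 1, -1, -1, -1]) == 0.0

    def test_hand_computation(self):
        assert cohens_d_paired([0.0, 2.0]) == pytest.approx(1 / np.sqrt(2))

    def test_scale_invariance(self, rng):
        x = rng.normal(0.4, 1.0, size=30)
        assert cohens_d_paired(7.3 * x) == pytest.approx(cohens_d_paired(x))

    def test_zero_sd_rejected(self):
        with pytest.raises(DegenerateInputError):
            cohens_d_paired([2.0, 2.0, 2.0])
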