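import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ribofret.bootstrap import (
    bootstrap_estimator,
    bootstrap_welch_test,
    compare_conditions,
    shifted_null_pvalue,
    welch_t,
)
from ribofret.errors import DegenerateDataError, ValidationError


class TestBootstrapEstimator:
    def test_matches_textbook_bootstrap_on_same_resamples(self):
        data = list(np.random.default_rng(0).normal(5, 2, 30))
        reps = bootstrap_estimator(data, lambda xs: float(np.mean(xs)), 200, seed=42)
        rng = np.random.default_rng(42)
        manual = np.array(
            [np.mean([data[i] for i in rng.integers(0, 30, 30)]) for _ in range(200)]
        )
        np.testing.assert_allclose(reps, manual)

    def test_sem_of_mean_approximates_sd_over_sqrt_n(self):
        rng = np.random.default_rng(1)
        data = list(rng.normal(0, 3, 400))
        reps = bootstrap_estimator(data, lambda xs: float(np.mean(xs)), 1000, seed=2)
        assert reps.std(ddof=1) == pytest.approx(np.std(data, ddof=1) / 20, rel=0.15)

    def test_deterministic_under_seed(self):
        data = list(range(50))
        a = bootstrap_estimator(data, lambda xs: float(np.median(xs)), 150, seed=7)
        b = bootstrap_estimator(data, lambda xs: float(np.median(xs)), 150, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_failing_replicates_dropped_with_warning(self):
        data = [1.0, 2.0, 3.0, -1.0]

        def sqrt_mean(xs):
            m = np.mean(xs)
            if m < 1.2:
                raise ValueError("unstable replicate")
            return float(np.sqrt(m))

        with pytest.warns(UserWarning, match="replicates failed"):
            reps = bootstrap_estimator(data, sqrt_mean, 200, seed=3)
        assert 0 < reps.size < 200


class TestWelchT:
    def test_hand_arithmetic(self):
        # var = 1, n = 3 each: t = (2 - 5)/sqrt(1/3 + 1/3)
        assert welch_t([1, 2, 3], [4, 5, 6]) == pytest.approx(-3 / np.sqrt(2 / 3))

    def test_identical_samples_give_zero(self):
        assert welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    @given(
        a=st.lists(st.floats(-50, 50), min_size=3, max_size=20),
        b=st.lists(st.floats(-50, 50), min_size=3, max_size=20),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b):
        va = np.var(a, ddof=1) / len(a) + np.var(b, ddof=1) / len(b)
        if va == 0:
            return
        assert welch_t(a, b) == pytest.approx(-welch_t(b, a), rel=1e-9, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            welch_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestShiftedNull:
    def test_p_near_one_when_t_obs_near_zero(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 60)
        b = np.concatenate([a[:30] + 1e-12, a[30:]])  # same mean by construction
        p, bound = shifted_null_pvalue(a, b, n_null=10**3, seed=5)
        assert p > 0.5
        assert not bound

    def test_widely_separated_samples_hit_the_bound(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 50)
        b = rng.normal(20, 1, 50)  # >= 10 pooled sds apart
        p, bound = shifted_null_pvalue(a, b, n_null=10**4, seed=7)
        assert bound
        assert p == pytest.approx(1 / (10**4 + 1))

    def test_null_pvalues_are_uniform(self):
        """Calibration: same-distribution samples give U(0,1) p-values."""
        rng = np.random.default_rng(8)
        ps = []
        for i in range(150):
            a = rng.normal(0, 1, 40)
            b = rng.normal(0, 1, 40)
            p, _ = shifted_null_pvalue(a, b, n_null=1500, seed=int(rng.integers(2**31)))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_p_monotone_in_separation(self):
        rng = np.random.default_rng(9)
        base_a = rng.normal(0, 1, 50)
        base_b = rng.normal(0, 1, 50)
        ps = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            p, _ = shifted_null_pvalue(base_a, base_b + shift, n_null=2000, seed=10)
            ps.append(p)
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_addone_p_never_zero(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 30)
        b = rng.normal(50, 1, 30)
        p, bound = shifted_null_pvalue(a, b, n_null=10**3, seed=12)
        assert p > 0


class TestCompareConditions:
    def test_dataset_compared_with_itself_is_not_significant(self):
        rng = np.random.default_rng(13)
        data = list(rng.normal(10, 2, 80))
        res = compare_conditions(data, list(data), lambda xs: float(np.mean(xs)),
                                 n_boot=150, n_null=2000, seed=14)
        assert res.p_value > 0.2

    def test_report_schema(self):
        rng = np.random.default_rng(15)
        res = compare_conditions(
            list(rng.normal(0, 1, 50)), list(rng.normal(3, 1, 50)),
            lambda xs: float(np.mean(xs)), n_boot=120, n_null=1500, seed=16,
            estimator_name="mean",
        )
        d = res.to_dict()
        for key in ("estimator", "estimate_a", "estimate_b", "sem_a", "sem_b",
                    "t_observed", "p_value", "p_is_upper_bound", "p_string", "seed"):
            assert key in d
        assert d["p_value"] <= 0.01

    def test_bootstrap_welch_test_detects_separation(self):
        rng = np.random.default_rng(17)
        reps_a = rng.normal(50, 3, 200)
        reps_b = rng.normal(71, 3, 200)
        t, p, bound = bootstrap_welch_test(reps_a, reps_b, n_null=10**4, seed=18)
        assert abs(t) > 4
        assert bound or p < 1e-3

    def test_n_boot_floor(self):
        with pytest.raises(ValidationError):
            bootstrap_estimator([1.0, 2.0], lambda xs: 0.0, 10, seed=0)
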