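import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trivus.estimators import corrected_disease
from trivus.inference import test_vus as vus_null_test
from trivus.inference import (
    ModelSpec,
    asymptotic_variance,
    bootstrap_variance,
    confidence_interval,
    vus_analyze,
    vus_point,
)
from trivus.data_prep import prepare
from trivus.simulation import SimulationConfig, simulate

from conftest import brute_force_vus, make_prepared


SPEC = ModelSpec(disease_predictors=("T", "A"), verification_predictors=("T", "A"))


class TestVusPoint:
    def test_perfect_separation_is_one(self):
        data = make_prepared([1, 2, 3, 4, 5, 6], [1, 1, 2, 2, 3, 3])
        dh = corrected_disease("full", data)
        assert vus_point(dh, data.test) == 1.0

    def test_all_tied_is_one_sixth(self):
        data = make_prepared([2.0] * 9, [1, 2, 3] * 3)
        dh = corrected_disease("full", data)
        assert vus_point(dh, data.test) == pytest.approx(1 / 6, abs=1e-15)

    @pytest.mark.parametrize("tie", [False, True])
    def test_matches_brute_force_oracle(self, tie):
        rng = np.random.default_rng(11 + tie)
        for _ in range(40):
            n = int(rng.integers(5, 45))
            t = (rng.integers(0, 6, n).astype(float) if tie
                 else rng.normal(size=n))
            d = rng.random((n, 3))
            assert vus_point(d, t) == pytest.approx(brute_force_vus(d, t), abs=1e-12)

    def test_concordant_triple_fraction_on_distinct_data(self):
        rng = np.random.default_rng(4)
        n = 30
        t = rng.normal(size=n)
        codes = np.r_[np.ones(10), 2 * np.ones(10), 3 * np.ones(10)]
        data = make_prepared(t, codes)
        dh = corrected_disease("full", data)
        i1, i2, i3 = (np.flatnonzero(codes == k) for k in (1, 2, 3))
        conc = np.mean(
            [(t[i] < t[j]) & (t[j] < t[l]) for i in i1 for j in i2 for l in i3]
        )
        assert vus_point(dh, t) == pytest.approx(conc, abs=1e-12)

    def test_zero_column_sum_raises(self):
        with pytest.raises(ValueError, match="positive sum"):
            vus_point(np.array([[1.0, 0, 1], [1, 0, 1]]), np.array([1.0, 2.0]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_monotone_transform_invariance(self, data):
        n = data.draw(st.integers(4, 25))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 8, size=n).astype(float)
        d = rng.random((n, 3))
        base = vus_point(d, t)
        for f in (lambda x: 3.0 * x - 7.0, np.exp, lambda x: x**3):
            assert vus_point(d, f(t)) == pytest.approx(base, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        t = rng.normal(size=n)
        d = rng.random((n, 3))
        perm = rng.permutation(n)
        assert vus_point(d[perm], t[perm]) == pytest.approx(vus_point(d, t), abs=1e-12)

    def test_useless_test_averages_one_sixth(self):
        # identically distributed test values across classes
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(500):
            t = rng.normal(size=30)
            codes = rng.permutation(np.r_[np.ones(10), 2 * np.ones(10), 3 * np.ones(10)])
            data = make_prepared(t, codes)
            vals.append(vus_point(corrected_disease("full", data), t))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(1 / 6, abs=3 * se)


class TestJackknife:
    def test_nonnegative(self, full_data):
        dh = corrected_disease("full", full_data)
        assert asymptotic_variance(dh, full_data.test) >= 0

    def test_small_n_raises(self):
        data = make_prepared([1, 2, 3], [1, 2, 3])
        dh = corrected_disease("full", data)
        with pytest.raises(ValueError, match="n >= 10"):
            asymptotic_variance(dh, data.test)

    def test_matches_direct_loo_recomputation(self, sim_data):
        # independent oracle: rebuild the estimate with row i dropped
        from trivus.models import fit_disease_mlogit

        rho = fit_disease_mlogit(sim_data, ("T", "A"))
        dh = corrected_disease("msi", sim_data, rho=rho)
        sub = dh.dhat[:50]
        t = sim_data.test[:50]
        n = 50
        loo = np.array([
            vus_point(np.delete(sub, i, axis=0), np.delete(t, i))
            for i in range(n)
        ])
        expected = (n - 1) / n * np.sum((loo - loo.mean()) ** 2)
        assert asymptotic_variance(sub, t) == pytest.approx(expected, rel=1e-10)

    def test_agrees_with_bootstrap_on_full_data(self, full_data):
        # with no nuisance models the two variance paths target the same
        # quantity and should broadly agree
        dh = corrected_disease("full", full_data)
        jk = asymptotic_variance(dh, full_data.test)
        bs = bootstrap_variance(full_data, "full", ModelSpec(), B=400, seed=9)
        assert abs(np.sqrt(bs) - np.sqrt(jk)) / np.sqrt(jk) < 0.25


class TestBootstrap:
    def test_seed_contract_worker_invariance(self, sim_data):
        a = bootstrap_variance(sim_data, "fi", SPEC, B=12, seed=5, workers=1)
        b = bootstrap_variance(sim_data, "fi", SPEC, B=12, seed=5, workers=2)
        assert a == b

    def test_different_seeds_differ(self, sim_data):
        a = bootstrap_variance(sim_data, "fi", SPEC, B=8, seed=1)
        b = bootstrap_variance(sim_data, "fi", SPEC, B=8, seed=2)
        assert a != b

    def test_b_too_small_raises(self, sim_data):
        with pytest.raises(ValueError, match="B"):
            bootstrap_variance(sim_data, "fi", SPEC, B=1)


class TestConfidenceInterval:
    def test_zero_se_degenerate(self):
        assert confidence_interval(0.3, 0.0, 0.95, "normal") == (0.3, 0.3)
        lo, hi = confidence_interval(0.3, 0.0, 0.95, "logit")
        assert lo == pytest.approx(0.3) and hi == pytest.approx(0.3)

    def test_logit_bounds_inside_unit_interval(self):
        lo, hi = confidence_interval(0.9, 3.0, 0.99, "logit")
        assert 0 < lo < hi < 1

    def test_logit_requires_open_interval(self):
        with pytest.raises(ValueError, match="logit"):
            confidence_interval(1.0, 0.1, 0.95, "logit")

    def test_invalid_level(self):
        with pytest.raises(ValueError, match="level"):
            confidence_interval(0.5, 0.1, 1.0, "normal")


class TestTestVus:
    def test_null_value(self):
        t, p = vus_null_test(1 / 6, 0.01)
        assert t == 0.0 and p == 0.5

    def test_formula_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            est, var = rng.uniform(0, 1), rng.uniform(1e-6, 0.1)
            t, p = vus_null_test(est, var)
            assert t == (est - 1 / 6) / np.sqrt(var)
            from scipy.stats import norm

            assert p == pytest.approx(norm.sf(t), abs=1e-15)

    def test_nonpositive_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            vus_null_test(0.5, 0.0)


class TestVusAnalyze:
    def test_full_composition(self, full_data):
        res = vus_analyze(full_data, "full", ModelSpec())
        dh = corrected_disease("full", full_data)
        assert res.estimate == vus_point(dh, full_data.test)
        assert res.variance == asymptotic_variance(dh, full_data.test)
        assert res.t_stat == (res.estimate - 1 / 6) / res.se

    def test_deterministic(self, sim_data):
        a = vus_analyze(sim_data, "spe", SPEC, variance_method="bootstrap", B=8, seed=3)
        b = vus_analyze(sim_data, "spe", SPEC, variance_method="bootstrap", B=8, seed=3)
        assert a.to_dict() == b.to_dict()

    def test_estimates_near_truth_with_bootstrap_se(self):
        # single paper-model dataset: corrected estimates should sit within
        # 3 bootstrap SEs of the oracle truth
        truth = 0.7173  # 2e6-draw oracle value, MC SE ~3e-4
        data = prepare(simulate(SimulationConfig(n=1000, seed=77)))
        for method in ("fi", "msi", "spe"):
            res = vus_analyze(data, method, SPEC, variance_method="bootstrap",
                              B=100, seed=1)
            assert abs(res.estimate - truth) < 3 * res.se, method

    def test_knn_requires_k(self, sim_data):
        with pytest.raises(ValueError, match="knn_k"):
            vus_analyze(sim_data, "knn", ModelSpec(knn_k=None))
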