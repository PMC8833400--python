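"""Cox fitting, concordance, bootstrap-t CIs, LRT and Kaplan-Meier."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radsurv import (EvaluationConfig, bootstrap_ci, concordance, cox_fit,
                     km_estimate, likelihood_ratio_test)
from radsurv.survival import cox_gradient

from conftest import random_survival


def _design(values, name="x"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame({name: values},
                        index=[f"P{i}" for i in range(len(values))])


def _surv(times, events):
    return pd.DataFrame({"time": times, "event": events},
                        index=[f"P{i}" for i in range(len(times))])


def brute_force_concordance(scores, time, event):
    """Independent pair-by-pair enumeration of Harrell's C."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = (time[i] < time[j] and event[i] == 1) or (
                time[i] == time[j] and event[i] == 1 and event[j] == 0)
            if not usable:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


class TestConcordance:
    def test_perfect_ordering(self):
        surv = _surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert concordance([4.0, 3.0, 2.0, 1.0], surv) == 1.0

    def test_hand_example(self):
        surv = _surv([2.0, 4.0, 6.0, 8.0], [1, 1, 1, 1])
        assert concordance([0.9, 0.1, 0.8, 0.2], surv) == pytest.approx(4 / 6)

    def test_antisymmetry(self, rng):
        surv = random_survival(rng, 40)
        scores = rng.normal(size=40)  # continuous, no ties
        c = concordance(scores, surv)
        assert concordance(-scores, surv) == pytest.approx(1.0 - c)

    def test_matches_enumeration_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 31))
            surv = random_survival(rng, n, tie_prob=0.3)
            scores = rng.integers(0, 5, size=n).astype(float)  # tied scores
            try:
                oracle = brute_force_concordance(scores,
                                                 surv["time"].to_numpy(),
                                                 surv["event"].to_numpy())
            except ValueError:
                with pytest.raises(ValueError):
                    concordance(scores, surv)
                continue
            assert concordance(scores, surv) == oracle

    def test_no_usable_pairs(self):
        surv = _surv([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError):
            concordance([0.1, 0.2], surv)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        surv = random_survival(rng, n, tie_prob=0.2)
        scores = rng.normal(size=n).round(1)
        try:
            c = concordance(scores, surv)
        except ValueError:
            return
        assert 0.0 <= c <= 1.0


class TestCoxFit:
    def test_recovers_hazard_ratio_two(self, rng):
        n = 1000
        group = rng.integers(0, 2, size=n)
        times = rng.exponential(1.0, size=n) / np.exp(np.log(2.0) * group)
        model = cox_fit(_design(group), _surv(times, np.ones(n, dtype=int)))
        assert abs(model.coefficients[0] - np.log(2)) < 0.1
        assert model.gradient_max_norm < 1e-6
        assert model.hazard_ratios[0] == pytest.approx(np.exp(model.coefficients[0]))

    def test_null_covariate_calibrated(self, rng):
        hits = 0
        for _ in range(50):
            n = 500
            times = rng.exponential(1.0, size=n)
            x = rng.permutation(np.repeat([0.0, 1.0], n // 2))
            model = cox_fit(_design(x), _surv(times, np.ones(n, dtype=int)))
            hits += abs(model.coefficients[0]) < 0.2 and model.p_values[0] > 0.05
        assert hits >= 45

    def test_all_censored_rejected(self, rng):
        with pytest.raises(ValueError, match="events"):
            cox_fit(_design(rng.normal(size=10)),
                    _surv(rng.exponential(1, 10), np.zeros(10, dtype=int)))

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            cox_fit(_design(np.ones(10)),
                    _surv(np.arange(1.0, 11.0), np.ones(10, dtype=int)))

    def test_score_equation_holds_with_ties(self, rng):
        surv = random_survival(rng, 80, tie_prob=0.4)
        x = rng.normal(size=(80, 2))
        design = pd.DataFrame(x, index=surv.index, columns=["a", "b"])
        surv.index = design.index
        model = cox_fit(design, surv)
        grad = cox_gradient(model.coefficients, x,
                            surv["time"].to_numpy(), surv["event"].to_numpy())
        assert np.abs(grad).max() < 1e-6


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        ci = bootstrap_ci(lambda idx: 3.14, 50,
                          EvaluationConfig(n_bootstrap=100), rng=0)
        assert ci.mean == pytest.approx(3.14)
        assert ci.ci_high - ci.ci_low == pytest.approx(0.0, abs=1e-10)

    def test_same_seed_reproducible(self, rng):
        x = rng.normal(size=100)
        cfg = EvaluationConfig(n_bootstrap=200)
        a = bootstrap_ci(lambda idx: x[idx].mean(), 100, cfg, rng=42)
        b = bootstrap_ci(lambda idx: x[idx].mean(), 100, cfg, rng=42)
        assert (a.mean, a.ci_low, a.ci_high) == (b.mean, b.ci_low, b.ci_high)

    def test_failure_fraction_guard(self):
        def flaky(idx):
            if idx[0] % 3 == 0:  # ~1/3 of replicates fail
                raise RuntimeError("refit failed")
            return 1.0
        with pytest.raises(RuntimeError, match="bootstrap replicates failed"):
            bootstrap_ci(flaky, 30, EvaluationConfig(n_bootstrap=300), rng=1)


class TestLRT:
    def test_identical_models_give_p_one(self, rng):
        surv = random_survival(rng, 60)
        design = _design(rng.normal(size=60))
        surv.index = design.index
        model = cox_fit(design, surv)
        res = likelihood_ratio_test(model, model)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_nonnegative_statistic(self, rng):
        for _ in range(10):
            surv = random_survival(rng, 80)
            X = pd.DataFrame(rng.normal(size=(80, 3)), index=surv.index,
                             columns=["a", "b", "c"])
            nested = cox_fit(X[["a"]], surv)
            full = cox_fit(X, surv)
            res = likelihood_ratio_test(nested, full)
            assert res.statistic >= 0.0 and res.df == 2

    def test_power_with_planted_effect(self, rng):
        """Added covariate with HR 2 at n=110 rejects in most seeds."""
        hits = 0
        n_seeds = 200
        for _ in range(n_seeds):
            n = 110
            z = rng.integers(0, 2, size=n)
            noise = rng.normal(size=n)
            t = rng.exponential(1.0, size=n) / np.exp(np.log(2.0) * z)
            cens = rng.exponential(1.0, size=n)
            surv = _surv(np.minimum(t, cens), (t <= cens).astype(int))
            X = pd.DataFrame({"noise": noise, "z": z.astype(float)},
                             index=surv.index)
            nested = cox_fit(X[["noise"]], surv)
            full = cox_fit(X, surv)
            hits += likelihood_ratio_test(nested, full).p_value < 0.05
        assert hits >= 0.70 * n_seeds

    def test_non_nested_rejected(self, rng):
        surv = random_survival(rng, 50)
        X = pd.DataFrame(rng.normal(size=(50, 2)), index=surv.index,
                         columns=["a", "b"])
        ma = cox_fit(X[["a"]], surv)
        mb = cox_fit(X[["b"]], surv)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(ma, mb)


class TestKaplanMeier:
    def test_no_censoring_steps(self):
        surv = _surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        curve = km_estimate(surv)["all"]
        steps = curve.set_index("time")["survival"]
        np.testing.assert_allclose(steps.loc[[1.0, 2.0, 3.0, 4.0]],
                                   [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat(self):
        surv = _surv([5.0, 6.0, 7.0], [0, 0, 0])
        curve = km_estimate(surv)["all"]
        assert (curve["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        surv = _surv([6.0, 7.0, 10.0, 15.0, 19.0, 25.0], [1, 0, 1, 1, 0, 1])
        curve = km_estimate(surv)["all"].set_index("time")
        assert curve.loc[10.0, "survival"] == pytest.approx(5 / 6 * 3 / 4)

    def test_groups_and_empty_warning(self, rng):
        surv = random_survival(rng, 20)
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=surv.index)
        curves = km_estimate(surv, groups)
        assert set(curves) == {"a", "b"}
        for c in curves.values():
            assert (np.diff(c["survival"]) <= 1e-12).all()
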