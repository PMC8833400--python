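"""ComBat harmonization, KS diagnostics and the nested multi-batch loop."""
import numpy as np
import pandas as pd
import pytest

from radsurv import (HarmonizationConfig, SimulationConfig, combat_harmonize,
                     generate_cohort, ks_flag_count, nested_combat,
                     zscore_features)


def _frame(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, index=[f"P{i}" for i in range(len(arr))],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestZScore:
    def test_simple_column(self):
        z, const = zscore_features(_frame([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z.iloc[:, 0], [-1.0, 0.0, 1.0])
        assert const == []

    def test_idempotent(self, rng):
        x = rng.normal(size=(50, 3))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        z, _ = zscore_features(_frame(x))
        np.testing.assert_allclose(z.to_numpy(), x, atol=1e-12)

    def test_constant_column_zeroed_with_warning(self):
        df = _frame(np.column_stack([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        with pytest.warns(UserWarning, match="constant"):
            z, const = zscore_features(df)
        assert const == ["f0"]
        assert (z["f0"] == 0).all()


class TestCombat:
    def test_single_batch_is_noop(self, rng):
        df = _frame(rng.normal(size=(30, 5)))
        batch = pd.Series(["a"] * 30, index=df.index, name="b")
        out, est = combat_harmonize(df, batch)
        np.testing.assert_allclose(out.to_numpy(), df.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(est.gamma_star, 0.0, atol=1e-6)
        np.testing.assert_allclose(est.delta_star_sq, 1.0, atol=1e-6)

    def test_pure_location_shift_removed(self, rng):
        base = rng.normal(size=(200, 4))
        shifted = base.copy()
        shifted[100:, 0] += 3.0
        df = _frame(shifted)
        batch = pd.Series(["a"] * 100 + ["b"] * 100, index=df.index, name="b")
        out, _ = combat_harmonize(df, batch)
        means = out.groupby(batch).mean()
        assert abs(means.loc["a", "f0"] - means.loc["b", "f0"]) < 0.1

    def test_small_batch_level_rejected(self, rng):
        df = _frame(rng.normal(size=(10, 3)))
        batch = pd.Series(["a"] * 9 + ["tiny"], index=df.index, name="b")
        with pytest.raises(ValueError, match="tiny"):
            combat_harmonize(df, batch)

    def test_estimates_positive_scales(self, default_cohort):
        z, _ = zscore_features(default_cohort.features)
        _, est = combat_harmonize(z, default_cohort.batches["vendor"])
        assert (est.delta_star_sq > 0).all()
        assert (est.var_pooled > 0).all()

    def test_gamma_recovery_improves_with_n(self):
        """MAE of recovered batch locations shrinks as the cohort grows."""
        def mae(n, seed=17):
            rng = np.random.default_rng(seed)
            p = 40
            gamma = rng.normal(0, 1.0, size=(2, p))
            codes = rng.integers(0, 2, size=n)
            X = rng.normal(size=(n, p)) + gamma[codes]
            df = _frame(X)
            batch = pd.Series(np.array(["a", "b"])[codes], index=df.index, name="b")
            _, est = combat_harmonize(df, batch)
            # ComBat locations are relative to the batch-size-weighted mean,
            # on the pooled-sd scale
            w = np.bincount(codes, minlength=2) / n
            centered = gamma - w @ gamma
            # est.levels follows first-occurrence order; realign to (a, b)
            row = {lvl: i for i, lvl in enumerate(est.levels)}
            recovered = est.gamma_star[[row["a"], row["b"]]] * np.sqrt(est.var_pooled)
            return np.abs(recovered - centered).mean()

        assert mae(1100) < mae(110)

    def test_shape_and_order_preserved(self, default_cohort):
        z, _ = zscore_features(default_cohort.features)
        out, _ = combat_harmonize(z, default_cohort.batches["contrast"])
        assert out.shape == z.shape
        assert list(out.index) == list(z.index)
        assert list(out.columns) == list(z.columns)

    def test_protected_covariate_effect_preserved(self, rng):
        """A protected biological effect survives harmonization intact."""
        n = 200
        covariate = np.repeat([0.0, 1.0], n // 2)
        batch_lvls = np.where(rng.random(n) < 0.5, "a", "b")
        X = rng.normal(size=(n, 6))
        X[:, 0] += 2.0 * covariate          # biological signal
        X[batch_lvls == "b"] += 1.0         # batch shift on every feature
        df = _frame(X)
        batch = pd.Series(batch_lvls, index=df.index, name="b")
        cov = pd.DataFrame({"group": covariate}, index=df.index)
        out, _ = combat_harmonize(df, batch, covariates=cov)
        diff = (out.to_numpy()[covariate == 1, 0].mean()
                - out.to_numpy()[covariate == 0, 0].mean())
        assert diff == pytest.approx(2.0, abs=0.35)
        # the batch shift itself is removed
        means = out.groupby(batch).mean()
        assert abs(means.loc["a", "f1"] - means.loc["b", "f1"]) < 0.15

    def test_rank_deficient_covariates_rejected(self, rng):
        df = _frame(rng.normal(size=(20, 3)))
        batch = pd.Series(["a"] * 10 + ["b"] * 10, index=df.index, name="b")
        cov = pd.DataFrame({"c1": np.ones(20), "c2": np.ones(20)}, index=df.index)
        with pytest.raises(ValueError, match="rank"):
            combat_harmonize(df, batch, covariates=cov)

    def test_nonparametric_prior_not_available(self, rng):
        df = _frame(rng.normal(size=(20, 3)))
        batch = pd.Series(["a"] * 10 + ["b"] * 10, index=df.index, name="b")
        with pytest.raises(NotImplementedError):
            combat_harmonize(df, batch, HarmonizationConfig(prior="nonparametric"))


class TestKSFlags:
    def test_single_level_counts_zero(self, rng):
        df = _frame(rng.normal(size=(20, 4)))
        batch = pd.Series(["a"] * 20, index=df.index, name="b")
        _, count = ks_flag_count(df, batch)
        assert count == 0

    def test_large_shift_flagged(self, rng):
        X = rng.normal(size=(110, 3))
        X[55:, 1] += 3.0
        df = _frame(X)
        batch = pd.Series(["a"] * 55 + ["b"] * 55, index=df.index, name="b")
        flags, count = ks_flag_count(df, batch)
        assert flags["f1"]
        assert count >= 1

    def test_null_calibration(self):
        """Mean flag count on null data matches the pairwise KS family-wise rate."""
        counts = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            df = _frame(rng.normal(size=(110, 107)))
            batch = pd.Series(np.where(rng.random(110) < 0.5, "a", "b"),
                              index=df.index, name="b")
            counts.append(ks_flag_count(df, batch, alpha=0.05)[1])
        # expected 107 * 0.05 = 5.35 flags if the test held its level exactly;
        # the two-sample KS test is conservative at these sample sizes
        assert abs(np.mean(counts) - 107 * 0.05) <= 2.0


class TestNested:
    def test_single_variable_equals_plain_combat(self, default_cohort):
        z, _ = zscore_features(default_cohort.features)
        plain, _ = combat_harmonize(z, default_cohort.batches["contrast"])
        res = nested_combat(default_cohort.features,
                            default_cohort.batches[["contrast"]])
        assert res.applied_order == ["contrast"]
        np.testing.assert_allclose(res.final_features.to_numpy(),
                                   plain.to_numpy(), atol=1e-10)

    def test_tied_counts_prefer_input_order(self, rng):
        df = _frame(rng.normal(size=(40, 5)))
        levels = pd.Series(["a"] * 20 + ["b"] * 20, index=df.index)
        batches = pd.DataFrame({"second": levels, "first": levels}, index=df.index)
        res = nested_combat(df, batches[["second", "first"]])
        # identical variables give identical counts at iteration 1
        assert res.applied_order[0] == "second"

    def test_exactly_one_iteration_per_variable(self, default_cohort):
        res = nested_combat(default_cohort.features, default_cohort.batches)
        assert len(res.per_iteration) == 2
        assert sorted(res.applied_order) == ["contrast", "vendor"]
        assert len(res.per_iteration[0]) == 2 and len(res.per_iteration[1]) == 1

    def test_effect_bearing_variable_selected_first(self):
        """Distortions planted only on contrast pull contrast to the front."""
        cfg = SimulationConfig(gamma_sd={"contrast": 1.0, "vendor": 0.0},
                               delta_range={"contrast": (0.5, 2.0),
                                            "vendor": (1.0, 1.0)})
        wins = 0
        for seed in range(10):
            cohort = generate_cohort(cfg, seed=seed)
            res = nested_combat(cohort.features, cohort.batches)
            wins += res.applied_order[0] == "contrast"
        assert wins >= 9

    def test_adjustment_vanishes_with_effect_size(self):
        """Mean absolute adjustment is monotone in the planted effect size."""
        sizes = [(1.0, (0.5, 2.0)), (0.3, (0.8, 1.25)), (0.0, (1.0, 1.0))]
        adjustments = []
        for gsd, drange in sizes:
            cfg = SimulationConfig(gamma_sd=gsd, delta_range=drange)
            cohort = generate_cohort(cfg, seed=21)
            z, _ = zscore_features(cohort.features)
            res = nested_combat(cohort.features, cohort.batches)
            adjustments.append(np.abs(res.final_features.to_numpy()
                                      - z.to_numpy()).mean())
        assert adjustments[0] > adjustments[1] > adjustments[2]

    def test_empty_batch_table_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            nested_combat(default_cohort.features,
                          default_cohort.batches.iloc[:, :0])
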