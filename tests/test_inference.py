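"""Transforms, variance partitioning and regressions vs explicit arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deerseed.inference import (joint_partition, one_way_partition,
                                regress_load_on_ldd,
                                species_interaction_model, transform)


class TestTransform:
    def test_logit_half_is_zero(self):
        assert transform([0.5, 0.1], "logit", standardize=False)[0] == 0.0

    def test_logit_zero_smoothed_finite(self):
        out = transform([0.0, 0.4], "logit", standardize=False,
                        n_events=[100_000, 100_000])
        assert np.isfinite(out).all()
        # (0*(n-1) + 0.5)/n = 0.5/n
        assert out[0] == pytest.approx(np.log((0.5 / 1e5) / (1 - 0.5 / 1e5)))

    def test_log_of_one_and_e(self):
        out = transform([1.0, np.e], "log", standardize=False)
        np.testing.assert_allclose(out, [0.0, 1.0], atol=1e-12)

    def test_log_with_zeros_adds_half_minimum(self):
        out = transform([0.0, 2.0], "log", standardize=False)
        assert out[0] == pytest.approx(np.log(1.0))  # 0 + 2/2

    def test_standardize_gives_zero_mean_unit_sd(self):
        out = transform([0.1, 0.5, 0.9], "logit", standardize=True)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0)

    def test_zero_variance_standardize_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            transform([0.5, 0.5], "logit", standardize=True)

    def test_logit_out_of_range_raises(self):
        with pytest.raises(ValueError):
            transform([1.2], "logit", standardize=False)


class TestOneWayPartition:
    def test_perfect_separation(self):
        r = one_way_partition([0, 0, 1, 1], ["A", "A", "B", "B"])
        assert r.r_squared == pytest.approx(1.0)
        assert r.df_factor == 1 and r.df_residual == 2

    def test_against_explicit_sums_of_squares(self):
        # 6-point example computed by hand-rolled SS arithmetic
        y = np.array([2.0, 4.0, 3.0, 8.0, 9.0, 10.0])
        g = ["A", "A", "A", "B", "B", "B"]
        r = one_way_partition(y, g)
        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        means = {"A": y[:3].mean(), "B": y[3:].mean()}
        ss_factor = sum(3 * (m - grand) ** 2 for m in means.values())
        ss_resid = ss_total - ss_factor
        f = (ss_factor / 1) / (ss_resid / 4)
        assert r.r_squared == pytest.approx(ss_factor / ss_total, abs=1e-10)
        assert r.f_statistic == pytest.approx(f, abs=1e-10)
        assert r.p_value == pytest.approx(stats.f.sf(f, 1, 4), abs=1e-12)

    def test_null_r_squared_expectation(self):
        # pure noise: E[R^2] = df_factor / (n - 1)
        rng = np.random.default_rng(10)
        g = np.repeat(list("ABCDE"), 12)
        r2 = [one_way_partition(rng.standard_normal(60), g).r_squared
              for _ in range(200)]
        assert np.mean(r2) == pytest.approx(4 / 59, abs=0.015)

    def test_pvalues_uniform_under_null(self):
        rng = np.random.default_rng(11)
        g = np.repeat(list("ABCD"), 8)
        ps = [one_way_partition(rng.standard_normal(32), g).p_value
              for _ in range(1000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_level_raises(self):
        with pytest.raises(ValueError):
            one_way_partition([1.0, 2.0], ["A", "A"])


class TestJointPartition:
    def _balanced(self):
        a = np.repeat(["A1", "A2"], 8)
        b = np.tile(np.repeat(["B1", "B2"], 4), 2)
        return a, b

    def test_pure_factor_a_effect(self):
        a, b = self._balanced()
        y = np.where(a == "A1", 0.0, 5.0) + np.tile([0, .1, -.1, 0], 4)
        parts, combined = joint_partition(y, a, b, names=("ind", "mon"))
        by_name = {p.factor: p for p in parts}
        assert by_name["ind (fitted first)"].r_squared > 0.99
        assert by_name["mon (fitted second)"].r_squared < 0.01

    def test_orthogonal_design_is_order_invariant(self):
        a, b = self._balanced()
        rng = np.random.default_rng(12)
        y = rng.standard_normal(16)
        parts, _ = joint_partition(y, a, b)
        shares = {p.factor: p.r_squared for p in parts}
        assert shares["a (fitted first)"] == pytest.approx(
            shares["a (fitted second)"], abs=1e-10)

    def test_combined_at_least_each_one_way(self):
        rng = np.random.default_rng(13)
        a = rng.choice(["A1", "A2", "A3"], 40)
        b = rng.choice(["B1", "B2"], 40)
        y = rng.standard_normal(40)
        _, combined = joint_partition(y, a, b)
        one_a = one_way_partition(y, a).r_squared
        one_b = one_way_partition(y, b).r_squared
        assert combined >= max(one_a, one_b) - 1e-12

    def test_aliased_factors_raise(self):
        a = ["A", "A", "B", "B"]
        with pytest.raises(ValueError, match="aliased"):
            joint_partition([1.0, 2.0, 3.0, 4.0], a, a)


class TestRegressLoadOnLdd:
    def test_identical_loads_give_zero_slope(self):
        r = regress_load_on_ldd([2.0, 2.0, 2.0, 2.0],
                                [0.1, 0.2, 0.3, 0.4])
        assert r.slope == pytest.approx(0.0, abs=1e-12)

    def test_collinear_pair_gives_r2_one(self):
        ldd = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        loads = np.exp(transform(ldd, "logit", standardize=True))
        r = regress_load_on_ldd(loads, ldd)
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(1.0)

    def test_against_closed_form_slope(self):
        loads = np.array([1.0, 3.0, 2.0, 8.0, 5.0])
        ldd = np.array([0.05, 0.2, 0.15, 0.4, 0.3])
        r = regress_load_on_ldd(loads, ldd)
        y = transform(loads, "log", standardize=True)
        x = transform(ldd, "logit", standardize=True)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / \
            ((x - x.mean()) ** 2).sum()
        assert r.slope == pytest.approx(slope, abs=1e-10)

    def test_zero_variance_predictor_raises(self):
        with pytest.raises(ValueError, match="predictor"):
            regress_load_on_ldd([1.0, 2.0, 3.0], [0.2, 0.2, 0.2])


class TestSpeciesInteractionModel:
    def _cells(self, slopes, noise=0.0, n=12, seed=14):
        rng = np.random.default_rng(seed)
        frames = []
        for i, slope in enumerate(slopes):
            ldd = np.linspace(0.05, 0.6, n)
            logit = np.log(ldd / (1 - ldd))
            q = np.exp(slope * logit + noise * rng.standard_normal(n)) + 0.01
            frames.append(pd.DataFrame({
                "species": f"sp{i}", "q": q, "ldd": ldd, "n_events": 1000}))
        return pd.concat(frames, ignore_index=True)

    def test_shared_relationship_has_tiny_interaction(self):
        res = species_interaction_model(self._cells([0.8, 0.8], noise=0.05))
        # null expectation of the partial R^2 is ~ df_num/df_den
        assert res.partial_r_squared < 0.2
        assert res.p_value > 0.05

    def test_opposite_noise_free_slopes_saturate_f(self):
        res = species_interaction_model(self._cells([1.0, -1.0], noise=0.0))
        assert res.partial_r_squared > 0.99

    def test_partial_r2_matches_direct_arithmetic(self):
        cells = self._cells([0.5, -0.2], noise=0.3)
        res = species_interaction_model(cells)
        y = transform(cells["q"].to_numpy(), "log", standardize=True)
        x = transform(cells["ldd"].to_numpy(), "logit", standardize=True,
                      n_events=cells["n_events"].to_numpy())
        is_b = (cells["species"] == "sp1").to_numpy(float)
        ones = np.ones_like(x)
        X_red = np.column_stack([ones, is_b, x])
        X_full = np.column_stack([ones, is_b, x, is_b * x])
        ss = {}
        for name, X in (("red", X_red), ("full", X_full)):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            ss[name] = ((y - X @ beta) ** 2).sum()
        expected = (ss["red"] - ss["full"]) / ss["red"]
        assert res.partial_r_squared == pytest.approx(expected, abs=1e-10)

    def test_single_species_raises(self):
        with pytest.raises(ValueError):
            species_interaction_model(self._cells([0.5]))
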