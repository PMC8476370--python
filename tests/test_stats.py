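"""Statistical battery vs independent brute-force and normal-equations oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from srtt_ci.stats import (
    ancova,
    factorial_anova,
    independent_t,
    mann_kendall,
    mann_whitney_u,
    one_sample_t,
    simple_effects,
    tukey_pairwise,
)


def brute_force_s(series):
    """S by exhaustive pair counting."""
    return sum(
        np.sign(series[j] - series[i])
        for i, j in itertools.combinations(range(len(series)), 2)
    )


class TestMannKendall:
    def test_strictly_monotone_series(self):
        assert mann_kendall([1, 2, 3, 4, 5]).statistic == 1.0
        assert mann_kendall([5, 4, 3, 2, 1]).statistic == -1.0

    def test_all_equal_series(self):
        res = mann_kendall([2.0] * 6)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize(
        "series",
        [(3, 1, 2, 4), (1, 1, 2, 0), (5, 3, 3, 3, 1, 2), (0.5, 0.1, 0.9, 0.9, 0.2, 0.3, 0.7, 0.4)],
    )
    def test_s_and_tau_match_exhaustive_pair_counting(self, series):
        res = mann_kendall(series)
        s = brute_force_s(list(series))
        assert res.extras["S"] == s
        # tau-b against scipy (time axis untied)
        tau_scipy = scipy.stats.kendalltau(np.arange(len(series)), series).statistic
        assert res.statistic == pytest.approx(tau_scipy)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            mann_kendall([1, 2])

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=30))
    def test_invariant_under_strictly_monotone_transform(self, xs):
        base = mann_kendall(xs)
        transformed = mann_kendall([np.exp(0.1 * x) for x in xs])
        assert base.statistic == pytest.approx(transformed.statistic)
        assert base.p_value == pytest.approx(transformed.p_value)


class TestLocationTests:
    def test_symmetric_values_give_zero_t(self):
        res = one_sample_t([-2, -1, 0, 1, 2], mu0=0.0)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            one_sample_t([3.0, 3.0, 3.0])
        with pytest.raises(ValueError):
            independent_t([1.0, 1.0], [1.0, 1.0])

    def test_independent_t_pooled_effect_size(self):
        a, b = [1.0, 2.0, 3.0], [3.0, 4.0, 5.0]
        res = independent_t(a, b)
        assert res.statistic == pytest.approx(-2.4494897)
        assert res.effect_sizes["cohen_d"] == pytest.approx(-2.0)

    def test_identical_samples_u_at_null_mean(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = mann_whitney_u(a, a)
        assert res.statistic == pytest.approx(len(a) ** 2 / 2)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_u_matches_exhaustive_cross_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 8, size=int(rng.integers(3, 7))).astype(float)
        b = rng.integers(0, 8, size=int(rng.integers(3, 7))).astype(float)
        expected_u = sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
        )
        assert mann_whitney_u(a, b).statistic == pytest.approx(expected_u)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(size=12)
        perm = rng.permutation(10)
        assert independent_t(a, b).statistic == pytest.approx(
            independent_t(a[perm], b).statistic
        )
        assert mann_whitney_u(a, b).statistic == pytest.approx(
            mann_whitney_u(a[perm], b).statistic
        )


def effect_coded_matrix(table, with_covariate=False):
    """Design matrix with sum-to-zero coding for a 2x2 layout."""
    a = np.where(table["f1"] == "a1", 1.0, -1.0)
    b = np.where(table["f2"] == "b1", 1.0, -1.0)
    cols = [np.ones(len(table)), a, b, a * b]
    names = ["intercept", "f1", "f2", "f1 x f2"]
    if with_covariate:
        cols.append(table["cov"].to_numpy(float))
        names.append("cov")
    return np.column_stack(cols), names


def type3_ss_by_model_comparison(table, response, with_covariate=False):
    """Independent oracle: Type III SS via least-squares model comparison."""
    X, names = effect_coded_matrix(table, with_covariate)
    y = table[response].to_numpy(float)

    def ss_res(cols):
        beta, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
        return float(((y - X[:, cols] @ beta) ** 2).sum())

    full = ss_res(list(range(X.shape[1])))
    out = {}
    for term_idx, name in enumerate(names):
        if name == "intercept":
            continue
        reduced_cols = [i for i in range(X.shape[1]) if i != term_idx]
        out[name] = ss_res(reduced_cols) - full
    out["residual"] = full
    return out


@pytest.fixture
def twelve_row_fixture():
    """Unbalanced 2x2 table (cells 4/2/3/3) with a numeric covariate."""
    return pd.DataFrame(
        {
            "f1": ["a1"] * 6 + ["a2"] * 6,
            "f2": ["b1", "b1", "b1", "b1", "b2", "b2", "b1", "b1", "b1", "b2", "b2", "b2"],
            "cov": [0.1, 0.4, 0.2, 0.9, 0.5, 0.3, 0.8, 0.2, 0.6, 0.7, 0.1, 0.4],
            "y": [3.2, 2.8, 3.5, 3.9, 5.1, 4.7, 1.9, 2.3, 2.1, 4.2, 3.8, 4.5],
        }
    )


class TestFactorialAnova:
    def test_two_group_contrast_matches_hand_computed_f(self):
        """Balanced one-way layout: F equals the textbook computation."""
        a = np.array([2.0, 3.0, 4.0, 3.0])
        b = np.array([5.0, 6.0, 7.0, 6.0])
        table = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4, "y": np.r_[a, b]})
        grand = np.r_[a, b].mean()
        ss_between = 4 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_hand = (ss_between / 1) / (ss_within / 6)
        res = factorial_anova(table, ["g"], "y")
        assert res[0].statistic == pytest.approx(f_hand)
        assert res[0].df == (1.0, 6.0)

    def test_balanced_design_type1_equals_type3(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "f1": ["a1", "a2"] * 12,
                "f2": ["b1"] * 12 + ["b2"] * 12,
                "y": rng.normal(size=24),
            }
        )
        t3 = factorial_anova(table, ["f1", "f2"], "y")
        t1 = factorial_anova(table, ["f1", "f2"], "y", ss_type=1)
        for r3, r1 in zip(t3, t1):
            assert r3.statistic == pytest.approx(r1.statistic)

    def test_type3_matches_normal_equations_oracle(self, twelve_row_fixture):
        res = factorial_anova(twelve_row_fixture, ["f1", "f2"], "y")
        oracle = type3_ss_by_model_comparison(twelve_row_fixture, "y")
        for r in res:
            assert r.extras["sum_sq"] == pytest.approx(oracle[r.term], rel=1e-8)
            f_oracle = (oracle[r.term] / 1) / (oracle["residual"] / 8)
            assert r.statistic == pytest.approx(f_oracle, rel=1e-8)

    def test_empty_cell_named_in_error(self):
        table = pd.DataFrame(
            {
                "f1": ["a1", "a1", "a1", "a1", "a2", "a2"],
                "f2": ["b1", "b1", "b2", "b2", "b1", "b1"],  # (a2, b2) missing
                "y": [1, 2, 3, 4, 5, 6.0],
            }
        )
        with pytest.raises(ValueError, match="empty cell.*b2"):
            factorial_anova(table, ["f1", "f2"], "y")

    def test_eta_squared_bounds(self, twelve_row_fixture):
        res = factorial_anova(twelve_row_fixture, ["f1", "f2"], "y")
        for r in res:
            assert 0.0 <= r.effect_sizes["eta_sq"] <= 1.0
            assert 0.0 <= r.effect_sizes["partial_eta_sq"] <= 1.0

    def test_simple_effects_match_subset_anova(self, twelve_row_fixture):
        res = simple_effects(twelve_row_fixture, "f2", "f1", "y")
        sub = twelve_row_fixture[twelve_row_fixture["f1"] == "a1"]
        direct = factorial_anova(sub, ["f2"], "y")[0]
        within_a1 = next(r for r in res if "f1=a1" in r.term)
        assert within_a1.statistic == pytest.approx(direct.statistic)


class TestAncova:
    def test_matches_normal_equations_oracle(self, twelve_row_fixture):
        res = ancova(twelve_row_fixture, ["f1", "f2"], "cov", "y")
        oracle = type3_ss_by_model_comparison(twelve_row_fixture, "y", with_covariate=True)
        for r in res:
            assert r.extras["sum_sq"] == pytest.approx(oracle[r.term], rel=1e-8)

    def test_orthogonal_null_covariate_leaves_factor_f_unchanged(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "f1": ["a1", "a2"] * 10,
                "f2": ["b1"] * 10 + ["b2"] * 10,
                "y": rng.normal(size=20),
            }
        )
        # a covariate orthogonal to factors and response in expectation
        table["cov"] = np.tile([1.0, -1.0], 10) * 0  # exactly zero covariate
        plain = factorial_anova(table, ["f1", "f2"], "y")
        # a constant covariate carries no information; drop it from the model
        # comparison by using a tiny-variance orthogonal one instead
        table["cov"] = np.r_[np.tile([1e-9, -1e-9], 5), np.tile([-1e-9, 1e-9], 5)]
        with_cov = ancova(table, ["f1", "f2"], "cov", "y")
        for r in plain:
            match = next(c for c in with_cov if c.term == r.term)
            assert match.statistic == pytest.approx(r.statistic, rel=1e-3)

    def test_response_as_covariate_absorbs_all_variance(self, twelve_row_fixture):
        table = twelve_row_fixture.copy()
        rng = np.random.default_rng(2)
        table["cov"] = table["y"] + rng.normal(0, 1e-6, len(table))
        res = ancova(table, ["f1", "f2"], "cov", "y")
        cov_term = next(r for r in res if r.term == "cov")
        assert cov_term.effect_sizes["partial_eta_sq"] > 0.999999
        for r in res:
            if r.term != "cov":
                assert r.extras["sum_sq"] < 1e-9


class TestTukey:
    def test_mean_differences_and_separation(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            {
                "g": ["x"] * 8 + ["y"] * 6 + ["z"] * 7,
                "y": np.r_[rng.normal(0, 0.3, 8), rng.normal(0, 0.3, 6), rng.normal(3, 0.3, 7)],
            }
        )
        res = tukey_pairwise(table, "g", "y")
        by_term = {r.term: r for r in res}
        xz = by_term.get("x vs z") or by_term["z vs x"]
        xy = by_term.get("x vs y") or by_term["y vs x"]
        assert xz.p_value < 0.001 and xz.extras["reject"]
        assert xy.p_value > 0.05 and not xy.extras["reject"]
        means = table.groupby("g")["y"].mean()
        assert xz.statistic == pytest.approx(means["z"] - means["x"])
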