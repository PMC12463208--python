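"""Spline basis, conditional-logistic likelihood and fit, Z-tests, reruns."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import cyclomort as cm
from cyclomort.model import (ModelSpec, clogit, clogit_loglik, natural_cubic_basis,
                             or_ci, subgroup_z)

from conftest import EXPOSURE_ONLY

DATA = Path(__file__).parent / "data"

# Fitted values of lm(y ~ splines::ns(x, df=4)) in R 4.3.3 for
# x = seq(0, 10, length.out = 21), y = sin(x) + 0.1 x^2 (frozen oracle).
R_NS_FITTED = np.array([
    0.168208516420, 0.502028435576, 0.806204005427, 1.051090876666,
    1.207044699989, 1.244421126089, 1.156456412844, 1.027909246856,
    0.966418921910, 1.079624731792, 1.475165970285, 2.221773212986,
    3.232542162736, 4.381659804187, 5.543313121991, 6.591689100800,
    7.429913239636, 8.076865094997, 8.580362737752, 8.988224238771,
    9.348267668920])

# survival::clogit on tests/data/clogit_small_synthetic.csv (frozen oracle).
R_CLOGIT_BETA = np.array([0.3074926062, -0.3773261737])
R_CLOGIT_SE = np.array([0.2303312720, 0.7409408033])


class TestNaturalCubicBasis:
    def test_column_count_and_linearity_in_tails(self):
        x = np.linspace(0, 1, 100)
        B = natural_cubic_basis(x, df=3)
        assert B.shape == (100, 3)
        # evaluate far outside the boundary: second differences vanish
        xx = np.array([-10.0, -9.0, -8.0, 11.0, 12.0, 13.0])
        knots = np.quantile(x, np.linspace(0, 1, 4)[1:-1])
        Bt = natural_cubic_basis(xx, df=3, knots=knots, boundary_knots=(0.0, 1.0))
        for j in range(3):
            left = np.diff(Bt[:3, j], 2)
            right = np.diff(Bt[3:, j], 2)
            assert np.allclose(left, 0, atol=1e-9)
            assert np.allclose(right, 0, atol=1e-9)

    def test_continuity_at_boundary_knot(self):
        x = np.linspace(0, 1, 50)
        knots = np.quantile(x, np.linspace(0, 1, 7)[1:-1])
        at = natural_cubic_basis(np.array([1.0]), df=6, knots=knots,
                                 boundary_knots=(0.0, 1.0))
        just_inside = natural_cubic_basis(np.array([1.0 - 1e-9]), df=6,
                                          knots=knots, boundary_knots=(0.0, 1.0))
        assert np.allclose(at, just_inside, atol=1e-7)

    def test_spans_same_space_as_r_ns(self):
        x = np.linspace(0, 10, 21)
        y = np.sin(x) + 0.1 * x ** 2
        B = natural_cubic_basis(x, df=4)
        X = np.column_stack([np.ones_like(x), B])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(X @ coef, R_NS_FITTED, atol=1e-9)

    def test_self_consistency_fit(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 10, 300))
        B0 = natural_cubic_basis(x, df=5)
        signal = B0 @ rng.normal(size=5)
        B = natural_cubic_basis(x, df=5)
        X = np.column_stack([np.ones_like(x), B])
        resid = signal - X @ np.linalg.lstsq(X, signal, rcond=None)[0]
        assert np.abs(resid).max() < 1e-9

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            natural_cubic_basis(np.ones(50), df=4)

    def test_df_below_three_rejected(self):
        with pytest.raises(ValueError):
            natural_cubic_basis(np.linspace(0, 1, 10), df=2)


def discordant_pair_frame(n_case_exposed, n_control_exposed, n_concordant=5):
    """1:1 matched pairs with binary exposure."""
    rows = []
    g = 0
    for _ in range(n_case_exposed):
        rows += [(g, 1, 1), (g, 0, 0)]; g += 1
    for _ in range(n_control_exposed):
        rows += [(g, 1, 0), (g, 0, 1)]; g += 1
    for _ in range(n_concordant):
        rows += [(g, 1, 1), (g, 0, 1)]; g += 1
    df = pd.DataFrame(rows, columns=["set_id", "y", "exposed_lag0"])
    df["role"] = np.where(df["y"] == 1, "case", "control")
    return df


class TestClogit:
    def test_discordant_pair_closed_form(self):
        # 20 pairs with only the case exposed, 10 with only the control:
        # beta = ln(20/10), se = sqrt(1/20 + 1/10)
        df = discordant_pair_frame(20, 10)
        res = cm.clogit_fit(df, EXPOSURE_ONLY)
        assert res.beta == pytest.approx(np.log(2), abs=1e-8)
        assert res.se == pytest.approx(np.sqrt(1 / 20 + 1 / 10), abs=1e-8)
        assert res.n_sets_informative == 30

    def test_matches_r_survival_clogit(self):
        df = pd.read_csv(DATA / "clogit_small_synthetic.csv")
        beta, cov, *_ = clogit(df[["x", "z"]].to_numpy(), df["y"].to_numpy(),
                               df["set"].to_numpy())
        assert np.allclose(beta, R_CLOGIT_BETA, atol=1e-8)
        assert np.allclose(np.sqrt(np.diag(cov)), R_CLOGIT_SE, atol=1e-8)

    def test_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit
        rng = np.random.default_rng(42)
        n_sets = 60
        sizes = rng.integers(2, 5, n_sets)
        g = np.repeat(np.arange(n_sets), sizes)
        X = rng.normal(size=(len(g), 2))
        y = np.zeros(len(g), int)
        for s in range(n_sets):
            rows = np.flatnonzero(g == s)
            y[rng.choice(rows)] = 1
        sm_fit = ConditionalLogit(y, X, groups=g).fit(disp=False)
        beta, cov, *_ = clogit(X, y, g)
        # statsmodels' optimizer stops at a looser tolerance than ours
        assert np.allclose(beta, sm_fit.params, atol=1e-4)
        assert np.allclose(np.sqrt(np.diag(cov)), sm_fit.bse, atol=1e-4)

    def test_loglik_equals_brute_force_softmax(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_sets = int(rng.integers(1, 6))
            sizes = rng.integers(2, 5, n_sets)
            g = np.repeat(np.arange(n_sets), sizes)
            X = rng.normal(size=(len(g), 2))
            y = np.zeros(len(g), int)
            for s in range(n_sets):
                y[rng.choice(np.flatnonzero(g == s))] = 1
            beta = rng.normal(size=2)
            # direct softmax evaluation
            want = 0.0
            for s in range(n_sets):
                rows = np.flatnonzero(g == s)
                eta = X[rows] @ beta
                want += eta[y[rows] == 1][0] - np.log(np.exp(eta).sum())
            assert clogit_loglik(beta, X, y, g) == pytest.approx(want, abs=1e-12)

    def test_all_concordant_raises(self):
        df = discordant_pair_frame(0, 0, n_concordant=8)
        with pytest.raises(ValueError, match="informative|exposure"):
            cm.clogit_fit(df, EXPOSURE_ONLY)

    def test_complete_separation_flagged(self):
        df = discordant_pair_frame(25, 0)
        res = cm.clogit_fit(df, EXPOSURE_ONLY)
        assert not res.converged

    def test_set_level_shift_leaves_beta_unchanged(self):
        rng = np.random.default_rng(9)
        df = cm.simulate_matched_sets(300, 1.4, rng)
        df["cov"] = rng.normal(size=len(df))
        X = df[["exposed_lag0", "cov"]].to_numpy()
        y = (df["role"] == "case").to_numpy(int)
        g = df["set_id"].to_numpy()
        b1, *_ = clogit(X, y, g)
        shift = pd.Series(g).map({s: i * 3.7 for i, s in enumerate(pd.unique(g))})
        X2 = X.copy()
        X2[:, 1] = X2[:, 1] + shift.to_numpy()
        b2, *_ = clogit(X2, y, g)
        assert np.allclose(b1, b2, atol=1e-6)


class TestOrCi:
    def test_zero_beta_zero_se(self):
        assert or_ci(0.0, 0.0) == (1.0, 1.0, 1.0)

    def test_log_symmetry(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=100, derandomize=True)
        @given(b=st.floats(min_value=-5, max_value=5),
               s=st.floats(min_value=0, max_value=5))
        def check(b, s):
            o, lo, hi = or_ci(b, s)
            assert np.log(hi / o) == pytest.approx(np.log(o / lo), abs=1e-10)
            assert lo <= o <= hi

        check()

    def test_ln2_half(self):
        # exp(ln 2 +/- 1.96 * 0.5) evaluated directly
        o, lo, hi = or_ci(np.log(2), 0.5)
        assert (round(o, 3), round(lo, 3), round(hi, 3)) == (2.0, 0.751, 5.329)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            or_ci(0.0, -0.1)


class TestSubgroupZ:
    def fr(self, beta, se):
        return cm.FitResult(beta=beta, se=se, or_=np.exp(beta), ci_low=0,
                            ci_high=0, p_value=0, n_sets=1,
                            n_sets_informative=1, converged=True, n_iter=1,
                            loglik=0.0)

    def test_equal_betas(self):
        z, p = subgroup_z(self.fr(0.3, 0.1), self.fr(0.3, 0.2))
        assert (z, p) == (0.0, 1.0)

    def test_worked_arithmetic(self):
        z, p = subgroup_z(self.fr(0.2, 0.05), self.fr(0.1, 0.05))
        assert z == pytest.approx(0.1 / np.sqrt(0.005), rel=1e-9)
        assert p == pytest.approx(0.157, abs=5e-4)

    def test_antisymmetry(self):
        z1, p1 = subgroup_z(self.fr(0.4, 0.1), self.fr(0.1, 0.15))
        z2, p2 = subgroup_z(self.fr(0.1, 0.15), self.fr(0.4, 0.1))
        assert z1 == -z2 and p1 == p2

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            subgroup_z(self.fr(0.2, 0.0), self.fr(0.1, 0.0))


class TestStratifiedAnalysis:
    def _with_stratum(self, rng, or_a, or_b, n=1500):
        a = cm.simulate_matched_sets(n, or_a, rng)
        b = cm.simulate_matched_sets(n, or_b, rng)
        a["stratum"] = "A"
        b["stratum"] = "B"
        b["set_id"] = "B" + b["set_id"]
        return pd.concat([a, b], ignore_index=True)

    def test_identical_strata_z_zero(self):
        df = cm.simulate_matched_sets(400, 1.3, np.random.default_rng(6))
        two = pd.concat([df.assign(stratum="A"),
                         df.assign(stratum="B", set_id="B" + df["set_id"])],
                        ignore_index=True)
        fits, pairs = cm.stratified_analysis(two, "stratum", EXPOSURE_ONLY)
        assert fits["A"].beta == pytest.approx(fits["B"].beta, abs=1e-10)
        assert pairs["z"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_effect_only_in_stratum_a_recovered(self):
        df = self._with_stratum(np.random.default_rng(18), 1.5, 1.0)
        fits, pairs = cm.stratified_analysis(df, "stratum", EXPOSURE_ONLY)
        assert fits["A"].or_ > fits["B"].or_
        assert fits["A"].ci_low <= 1.5 <= fits["A"].ci_high
        assert fits["B"].ci_low <= 1.0 <= fits["B"].ci_high

    def test_single_level_no_comparisons(self):
        df = cm.simulate_matched_sets(100, 1.2, np.random.default_rng(10))
        df["stratum"] = "only"
        fits, pairs = cm.stratified_analysis(df, "stratum", EXPOSURE_ONLY)
        assert list(fits) == ["only"] and pairs.empty


class TestSensitivitySuite:
    def test_variants_on_simulated_data(self):
        rng = np.random.default_rng(12)
        df = cm.simulate_matched_sets(1200, 1.4, rng)
        df["sex"] = rng.choice(["male", "female"], len(df))
        df["country"] = "C1"
        out = cm.sensitivity_suite(df, EXPOSURE_ONLY)
        base = out["base"]
        assert isinstance(base, cm.FitResult)
        # sex independent of exposure: adding it barely moves the estimate
        assert abs(out["add_sex"].or_ - base.or_) < 0.01
        # leave-one-out with a single group leaves no data: reported, not fatal
        assert isinstance(out["drop_C1"], str) and "error" in out["drop_C1"]
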