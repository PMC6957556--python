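"""Correlations, hierarchical regression, BCa bootstrap, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from planconn import stats as st


class TestCorrelate:
    def test_exact_linear_relation(self):
        x = np.linspace(0, 10, 30)
        r, p, method = st.correlate(x, 2 * x + 1, method="pearson")
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_monotone_nonlinear_prefers_spearman(self):
        x = np.linspace(-3, 3, 40)
        y = x**3
        rs, _, _ = st.correlate(x, y, method="spearman")
        rp, _, _ = st.correlate(x, y, method="pearson")
        assert rs == pytest.approx(1.0)
        assert rp < 1.0

    def test_auto_picks_spearman_for_skewed_data(self, rng):
        x = rng.lognormal(0, 1.5, 60)  # heavily skewed
        y = x + rng.normal(0, 0.1, 60)
        _, _, method = st.correlate(x, y, method="auto")
        assert method == "spearman"
        a = rng.normal(0, 1, 60)
        b = 0.5 * a + rng.normal(0, 1, 60)
        _, _, method = st.correlate(a, b, method="auto")
        assert method == "pearson"

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(30)
        x = rng.normal(0, 1, 30)
        y = 0.45 * x + rng.normal(0, 1, 30)
        r, p, _ = st.correlate(x, y, method="pearson")
        perm_r = []
        perm_rng = np.random.default_rng(7)
        for _ in range(10000):
            perm_r.append(abs(np.corrcoef(x, perm_rng.permutation(y))[0, 1]))
        p_perm = np.mean(np.asarray(perm_r) >= abs(r))
        mc_se = np.sqrt(p_perm * (1 - p_perm) / 10000)
        assert p == pytest.approx(p_perm, abs=max(4 * mc_se, 0.01))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            st.correlate(np.ones(10), np.arange(10.0))


def make_table(rng, n=200, b_ge=9.79, noise=1.0):
    age = rng.normal(48, 14, n)
    ge = rng.normal(0.45, 0.04, n)
    motion = rng.normal(0.07, 0.03, n)
    rt = 0.09 * age + b_ge * ge - 16.46 * motion + rng.normal(0, noise, n)
    return pd.DataFrame({"age": age, "GE": ge, "motion": motion, "rt": rt})


BLOCKS = st.RegressionBlocks(outcome="rt", blocks=[["age"], ["GE"], ["motion"]])


class TestHierarchicalFit:
    def test_outcome_identical_to_first_block(self, rng):
        df = make_table(rng)
        df["rt"] = 3.0 * df["age"] - 1.0
        fits = st.hierarchical_fit(df, BLOCKS)
        assert fits[0].r2 == pytest.approx(1.0)
        assert fits[-1].r2 == pytest.approx(1.0)
        assert fits[-1].coef["GE"] == pytest.approx(0.0, abs=1e-8)

    def test_r2_nondecreasing_over_blocks(self, rng):
        for _ in range(30):
            df = make_table(rng, n=60)
            fits = st.hierarchical_fit(df, BLOCKS)
            r2 = [f.r2 for f in fits]
            assert all(r2[i + 1] >= r2[i] - 1e-12 for i in range(len(r2) - 1))
            # cross-check against the explained-variance identity
            resid = df["rt"] - df["rt"].mean()
            assert fits[0].r2 <= 1.0 and fits[0].r2 >= 0.0

    def test_generating_coefficients_recovered(self):
        rng = np.random.default_rng(1234)
        df = make_table(rng, n=5000, noise=0.5)
        fits = st.hierarchical_fit(df, BLOCKS)
        final = fits[-1]
        for name, truth in [("age", 0.09), ("GE", 9.79), ("motion", -16.46)]:
            assert abs(final.coef[name] - truth) < 2 * final.se[name]

    def test_rank_deficiency_names_collinear_columns(self, rng):
        df = make_table(rng, n=50)
        df["GE"] = 2.0 * df["age"]  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            st.hierarchical_fit(df, BLOCKS)

    def test_matches_statsmodels_reference(self, rng):
        import statsmodels.api as sm

        df = make_table(rng, n=80)
        fits = st.hierarchical_fit(df, BLOCKS)
        X = sm.add_constant(df[["age", "GE", "motion"]])
        ref = sm.OLS(df["rt"], X).fit()
        for name in ("age", "GE", "motion"):
            assert fits[-1].coef[name] == pytest.approx(ref.params[name], abs=1e-10)
            assert fits[-1].se[name] == pytest.approx(ref.bse[name], abs=1e-10)
        assert fits[-1].r2 == pytest.approx(ref.rsquared, abs=1e-12)


class TestStandardizedBeta:
    def test_equal_sds_give_unity(self):
        assert st.standardized_beta(1.0, 2.0, 2.0) == 1.0

    def test_equals_slope_of_standardized_regression(self, rng):
        df = make_table(rng, n=100)
        fits = st.hierarchical_fit(df, BLOCKS)
        z = (df - df.mean()) / df.std(ddof=1)
        zfits = st.hierarchical_fit(z, BLOCKS)
        for name in ("age", "GE", "motion"):
            assert fits[-1].beta[name] == pytest.approx(zfits[-1].coef[name], abs=1e-10)

    def test_invariant_to_predictor_rescaling(self, rng):
        df = make_table(rng, n=100)
        fits = st.hierarchical_fit(df, BLOCKS)
        df2 = df.copy()
        df2["GE"] = df2["GE"] * 1000.0
        fits2 = st.hierarchical_fit(df2, BLOCKS)
        assert fits2[-1].beta["GE"] == pytest.approx(fits[-1].beta["GE"], abs=1e-10)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            st.standardized_beta(1.0, 0.0, 1.0)


class TestBCaInterval:
    def test_symmetric_replicates_reduce_to_percentile(self):
        rng = np.random.default_rng(5)
        half = rng.normal(0, 1, 2000)
        boots = 10.0 + np.concatenate([half, -half])  # exactly symmetric about 10
        jacks = np.full(30, 10.0) + np.linspace(-1e-9, 1e-9, 30)  # a ~ 0
        lo, hi, diag = st.bca_interval(10.0, boots, jacks)
        assert diag["z0"] == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(np.quantile(boots, 0.025), abs=1e-9)
        assert hi == pytest.approx(np.quantile(boots, 0.975), abs=1e-9)

    def test_skewed_jackknife_moves_endpoints(self):
        rng = np.random.default_rng(8)
        boots = rng.normal(0, 1, 4000)
        sym_jacks = np.linspace(-1, 1, 30)
        skew_jacks = np.concatenate([np.full(25, -0.1), np.full(5, 2.0)])
        lo0, hi0, d0 = st.bca_interval(float(np.median(boots)), boots, sym_jacks)
        lo1, hi1, d1 = st.bca_interval(float(np.median(boots)), boots, skew_jacks)
        assert d0["a"] == pytest.approx(0.0, abs=1e-12)
        assert d1["a"] != 0.0
        assert (lo0, hi0) != (lo1, hi1)

    def test_degenerate_one_sided_replicates_clamped_not_hidden(self):
        boots = np.linspace(1.0, 2.0, 500)  # all above the point estimate
        jacks = np.linspace(0, 1, 20)
        lo, hi, diag = st.bca_interval(0.5, boots, jacks)
        assert diag["clamped"]
        assert np.isfinite([lo, hi]).all()

    def test_zero_variance_replicates_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            st.bca_interval(1.0, np.ones(100), np.arange(10.0))


class TestBootstrapRegression:
    def test_deterministic_given_seed(self, rng):
        df = make_table(rng, n=62)
        a = st.bootstrap_regression(df, BLOCKS, n_boot=400, seed=9)
        b = st.bootstrap_regression(df, BLOCKS, n_boot=400, seed=9)
        for ca, cb in zip(a.coefficients, b.coefficients):
            assert (ca.ci_low, ca.ci_high, ca.p_bca) == (cb.ci_low, cb.ci_high, cb.p_bca)
        c = st.bootstrap_regression(df, BLOCKS, n_boot=400, seed=10)
        assert any(
            ca.ci_low != cc.ci_low for ca, cc in zip(a.coefficients, c.coefficients)
        )

    def test_ci_zero_exclusion_consistent_with_p(self, rng):
        for _ in range(5):
            df = make_table(rng, n=62, noise=2.0)
            res = st.bootstrap_regression(df, BLOCKS, n_boot=500, seed=3)
            for c in res.coefficients:
                excludes = c.ci_low > 0 or c.ci_high < 0
                if c.p_bca < 0.049:  # grid resolution guard
                    assert excludes
                if c.p_bca > 0.051:
                    assert not excludes

    def test_strong_effect_detected_with_positive_sign(self, rng):
        df = make_table(rng, n=62, noise=0.5)
        res = st.bootstrap_regression(df, BLOCKS, n_boot=500, seed=1)
        ge = next(c for c in res.coefficients if c.name == "GE")
        assert ge.b > 0
        assert ge.p_bca < 0.05
        assert res.models[-1].r2 >= res.models[0].r2

    def test_table_shape(self, rng):
        df = make_table(rng, n=62)
        res = st.bootstrap_regression(df, BLOCKS, n_boot=300, seed=2)
        frame = res.to_frame()
        assert list(frame.columns) == [
            "outcome", "predictor", "B", "SE", "CI_low", "CI_high", "Beta", "P_bca", "R2"
        ]
        assert len(frame) == 3


def brute_force_bh(pvals, q):
    """Independent step-up: scan thresholds over the sorted P values."""
    m = len(pvals)
    order = np.argsort(pvals)
    sorted_p = np.asarray(pvals)[order]
    k = 0
    for i in range(m):
        if sorted_p[i] <= (i + 1) / m * q:
            k = i + 1
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, sorted_p[i] * m / (i + 1))
        adj[order[i]] = running
    return reject, adj


class TestFDR:
    def test_matches_brute_force_step_up(self, rng):
        for _ in range(50):
            m = int(rng.integers(2, 15))
            pvals = rng.uniform(0, 1, m)
            res = st.fdr_bh({f"t{i}": p for i, p in enumerate(pvals)}, q=0.05)
            reject, adj = brute_force_bh(pvals, 0.05)
            for i in range(m):
                assert res.adjusted[f"t{i}"] == pytest.approx(adj[i], abs=1e-12)
                assert res.reject[f"t{i}"] == reject[i]
                assert res.adjusted[f"t{i}"] >= res.raw[f"t{i}"] - 1e-15

    def test_two_nominal_hits_among_eight_can_fail_correction(self):
        # two subnetwork tests nominally significant (raw P 0.018 and 0.039)
        # among eight: the step-up bound fails and both adjusted P exceed 0.05
        pvals = {
            "eff_DMN": 0.018, "cc_DMN": 0.039,
            "eff_FPN": 0.4, "cc_FPN": 0.5, "eff_DAN": 0.6,
            "cc_DAN": 0.7, "eff_VAN": 0.8, "cc_VAN": 0.9,
        }
        res = st.fdr_bh(pvals, q=0.05)
        assert not any(res.reject.values())
        assert res.adjusted["eff_DMN"] > 0.05
        assert res.adjusted["cc_DMN"] > 0.05

    def test_all_ones_no_rejections(self):
        res = st.fdr_bh({"a": 1.0, "b": 1.0, "c": 1.0})
        assert not any(res.reject.values())
        assert all(v == 1.0 for v in res.adjusted.values())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.fdr_bh({"a": 1.5})


class TestResidualize:
    def test_orthogonal_covariates_leave_correlation_unchanged(self, rng):
        n = 400
        x = rng.normal(0, 1, n)
        y = 0.6 * x + rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)  # independent of both
        r_raw = np.corrcoef(x, y)[0, 1]
        r_partial, _ = st.partial_correlation(y, x, z)
        assert r_partial == pytest.approx(r_raw, abs=0.02)

    def test_matches_recursive_partial_correlation_formula(self, rng):
        n = 120
        z = rng.normal(0, 1, n)
        x = 0.5 * z + rng.normal(0, 1, n)
        y = -0.3 * z + 0.4 * x + rng.normal(0, 1, n)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        got, _ = st.partial_correlation(y, x, z)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_fully_explained_outcome_flagged(self, rng):
        n = 50
        z = rng.normal(0, 1, n)
        y = 2.0 * z + 1.0  # exactly determined by the covariate
        x = rng.normal(0, 1, n)
        with pytest.raises(ValueError, match="undefined"):
            st.partial_correlation(y, x, z)
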