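"""The covariance-structure engine: grammar, implied covariance, the
OLS-equivalence oracle, robust corrections, and equivariance properties."""

import numpy as np
import pandas as pd
import pytest

from otiskit.errors import CycleDetected, DuplicatePath, NonPDSample, UnknownVariable
from otiskit.sem import fit_ml, implied_covariance, parse_model, robust_adjust
from otiskit.sem.fit import _f_and_grad, _ols_start


def random_recursive_data(rng, p, n):
    """Data from a random fully-recursive standardized system plus the
    just-identified model text describing it."""
    names = [f"v{i}" for i in range(p)]
    X = np.empty((n, p))
    X[:, 0] = rng.standard_normal(n)
    lines = []
    for i in range(1, p):
        coefs = rng.uniform(-0.5, 0.5, size=i)
        X[:, i] = X[:, :i] @ coefs + rng.standard_normal(n)
        lines.append(f"{names[i]} ~ " + " + ".join(names[:i]))
    return pd.DataFrame(X, columns=names), "\n".join(lines)


class TestParseModel:
    def test_minimal_regression(self):
        spec = parse_model("y ~ x")
        assert spec.free_b == [(spec.index("y"), spec.index("x"))]
        # two free variances, no free covariance (single exogenous variable)
        assert len(spec.free_psi) == 2
        assert spec.df == 3 - 2 - 1 == 0

    def test_self_regression_rejected(self):
        with pytest.raises(CycleDetected):
            parse_model("y ~ y")

    def test_cycle_rejected(self):
        with pytest.raises(CycleDetected):
            parse_model("y ~ x\nx ~ y")

    def test_duplicate_rejected(self):
        with pytest.raises(DuplicatePath):
            parse_model("y ~ x + x")

    def test_unknown_variable_with_explicit_list(self):
        with pytest.raises(UnknownVariable):
            parse_model("y ~ x", variables=["y"])

    def test_covariance_statement(self):
        spec = parse_model("y ~ x\ny2 ~ x\ny ~~ y2", saturated_exogenous=False)
        i, j = spec.index("y"), spec.index("y2")
        assert (min(i, j), max(i, j)) in [(min(a, b), max(a, b)) for a, b in spec.free_psi]


class TestImpliedCovariance:
    def test_zero_paths_give_psi(self):
        spec = parse_model("y ~ x")
        theta = np.array([0.0, 1.3, 0.7])
        Sigma = implied_covariance(spec, theta)
        assert np.allclose(np.sort(np.diag(Sigma)), [0.7, 1.3])
        assert Sigma[0, 1] == 0.0

    def test_hand_algebra_single_path(self):
        """y = b x with Var(x)=1, Var(e)=psi: Sigma = [[1, b], [b, b^2+psi]]."""
        spec = parse_model("y ~ x")
        b, psi = 0.8, 0.5
        k_y, k_x = spec.index("y"), spec.index("x")
        theta = np.zeros(3)
        theta[0] = b
        # free_psi order: variances in variable order
        for pos, (i, j) in enumerate(spec.free_psi, start=1):
            theta[pos] = psi if i == k_y else 1.0
        Sigma = implied_covariance(spec, theta)
        assert Sigma[k_x, k_x] == pytest.approx(1.0)
        assert Sigma[k_y, k_x] == pytest.approx(b)
        assert Sigma[k_y, k_y] == pytest.approx(b**2 + psi)

    def test_symmetric_for_random_theta(self, rng):
        spec = parse_model("m ~ x\ny ~ m + x")
        theta = rng.uniform(0.1, 1.0, spec.n_free)
        Sigma = implied_covariance(spec, theta)
        assert np.allclose(Sigma, Sigma.T)


class TestGradient:
    def test_analytic_matches_finite_differences(self, rng):
        spec = parse_model("m ~ x\ny ~ m")
        df, _ = random_recursive_data(rng, 3, 200), None
        X = df[0][["v0", "v1", "v2"]].to_numpy()
        S = np.cov(X, rowvar=False)
        S = S / np.outer(np.sqrt(np.diag(S)), np.sqrt(np.diag(S)))
        _, ld = np.linalg.slogdet(S)
        theta = np.array([0.3, 0.2, 1.1, 0.8, 0.9])
        _, g = _f_and_grad(spec, theta, S, ld)
        num = np.empty_like(theta)
        for k in range(len(theta)):
            e = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[k] += e
            tm[k] -= e
            num[k] = (_f_and_grad(spec, tp, S, ld)[0] - _f_and_grad(spec, tm, S, ld)[0]) / (2 * e)
        assert np.allclose(g, num, atol=1e-7)


class TestOlsOracle:
    @pytest.mark.parametrize("p,seed", [(3, 0), (4, 1), (5, 2), (6, 3)])
    def test_just_identified_equals_per_equation_ols(self, p, seed):
        """The engine's primary correctness oracle: every path of a
        just-identified recursive model equals the least-squares slope."""
        rng = np.random.default_rng(seed)
        df, text = random_recursive_data(rng, p, 250)
        spec = parse_model(text)
        fit = fit_ml(spec, df)
        assert fit.F_ML == pytest.approx(0.0, abs=1e-10)
        assert fit.T == pytest.approx(0.0, abs=1e-7)
        est = dict(zip(fit.param_names, fit.theta))
        import statsmodels.api as sm

        for child_i, _ in {(i, None) for i, _ in spec.free_b}:
            child = spec.variables[child_i]
            parents = spec.parents(child)
            res = sm.OLS(df[child], sm.add_constant(df[parents])).fit()
            for par in parents:
                assert est[f"{child} ~ {par}"] == pytest.approx(res.params[par], abs=1e-6)

    def test_three_variable_chain_recovery(self):
        """Simulation recovery: x -> m -> y at n=5000 within 3 SE."""
        rng = np.random.default_rng(42)
        n = 5000
        x = rng.standard_normal(n)
        m = 0.5 * x + np.sqrt(0.75) * rng.standard_normal(n)
        y = 0.4 * m + np.sqrt(0.84) * rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        spec = parse_model("m ~ x\ny ~ m")
        fit = fit_ml(spec, df)
        est = dict(zip(fit.param_names, fit.theta))
        se = dict(zip(fit.param_names, fit.naive_se))
        assert abs(est["m ~ x"] - 0.5) < 3 * se["m ~ x"]
        assert abs(est["y ~ m"] - 0.4) < 3 * se["y ~ m"]


class TestRobustAdjust:
    def test_normal_data_ratio_near_one(self):
        rng = np.random.default_rng(10)
        n = 5000
        x = rng.standard_normal(n)
        m = 0.5 * x + rng.standard_normal(n)
        y = 0.4 * m + rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        fit = robust_adjust(fit_ml(parse_model("m ~ x\ny ~ m"), df), df)
        ratio = fit.robust_se / fit.naive_se
        assert np.all(np.abs(ratio - 1) < 0.1)
        assert abs(fit.scaling_c - 1) < 0.15
        assert fit.scaling_c > 0

    def test_heavy_tails_inflate_robust_se(self):
        """t(5) errors: excess kurtosis makes sandwich variance SEs exceed
        the normal-theory ones for the variance parameters."""
        rng = np.random.default_rng(11)
        n = 5000
        x = rng.standard_t(5, n)
        y = 0.5 * x + rng.standard_t(5, n)
        df = pd.DataFrame({"x": x, "y": y})
        fit = robust_adjust(fit_ml(parse_model("y ~ x"), df), df)
        names = fit.param_names
        var_idx = [k for k, nm in enumerate(names) if "~~" in nm]
        assert np.mean(fit.robust_se[var_idx] / fit.naive_se[var_idx]) > 1.2

    def test_scaled_statistic_positive(self, frame_big):
        from otiskit.models import weight_model_spec

        fit = robust_adjust(fit_ml(weight_model_spec(), frame_big), frame_big)
        assert fit.scaling_c > 0
        assert fit.T_scaled == pytest.approx(fit.T / fit.scaling_c)


class TestEquivariance:
    def test_rescaling_a_variable(self):
        """Multiplying a variable by k rescales unstandardized paths by the
        k-ratio and leaves standardized ones unchanged."""
        rng = np.random.default_rng(4)
        df, text = random_recursive_data(rng, 4, 400)
        spec = parse_model(text)
        fit1 = fit_ml(spec, df)
        df2 = df.copy()
        k = 37.5
        df2["v1"] = df2["v1"] * k
        fit2 = fit_ml(spec, df2)
        std1, std2 = fit1.standardized(), fit2.standardized()
        assert np.allclose(std1, std2, atol=1e-8)
        est1 = dict(zip(fit1.param_names, fit1.theta))
        est2 = dict(zip(fit2.param_names, fit2.theta))
        assert est2["v1 ~ v0"] == pytest.approx(k * est1["v1 ~ v0"], rel=1e-8)
        assert est2["v2 ~ v1"] == pytest.approx(est1["v2 ~ v1"] / k, rel=1e-8)

    def test_t_statistic_calibrated_under_true_model(self):
        """T ~ chi2_df: empirical rejection at 0.05 within the binomial CI
        over repeated simulations of a small over-identified model."""
        from scipy import stats as sps

        rng = np.random.default_rng(99)
        n_rep, n = 400, 150
        rejections = 0
        spec = parse_model("m ~ x\ny ~ m")
        for _ in range(n_rep):
            x = rng.standard_normal(n)
            m = 0.5 * x + rng.standard_normal(n)
            y = 0.4 * m + rng.standard_normal(n)
            df = pd.DataFrame({"x": x, "m": m, "y": y})
            fit = fit_ml(spec, df)
            if sps.chi2.sf(fit.T, fit.df) < 0.05:
                rejections += 1
        rate = rejections / n_rep
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < ci + 0.01


class TestErrors:
    def test_nonpd_sample_rejected(self, rng):
        x = rng.standard_normal(50)
        df = pd.DataFrame({"x": x, "y": x.copy(), "z": rng.standard_normal(50)})
        with pytest.raises(NonPDSample):
            fit_ml(parse_model("z ~ x + y"), df)

    def test_more_variables_than_cases_rejected(self, rng):
        df = pd.DataFrame(rng.standard_normal((3, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            fit_ml(parse_model("a ~ b + c + d"), df)

    def test_ols_start_reproduces_sample_cov_when_saturated(self, rng):
        df, text = random_recursive_data(rng, 4, 300)
        spec = parse_model(text)
        S = np.cov(df.to_numpy(), rowvar=False)
        S = S / np.outer(np.sqrt(np.diag(S)), np.sqrt(np.diag(S)))
        theta0 = _ols_start(spec, S)
        assert np.allclose(implied_covariance(spec, theta0), S, atol=1e-10)
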