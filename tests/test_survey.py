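import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from rarliver.survey import (SurveyLogLinear, SurveyLogit, SurveyOrdinal,
                             working_lrt)


def sim_logit(n=1000, seed=0, sigma_w=0.5, beta1=0.7):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = (rng.random(n) < 0.4).astype(float)
    eta = -1.5 + beta1 * x + 0.4 * z
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    w = rng.lognormal(0, sigma_w, n)
    w /= w.mean()
    X = pd.DataFrame({"const": np.ones(n), "x": x, "z": z})
    return y, X, w


class TestSurveyLogit:
    def test_unit_weights_match_ml(self):
        y, X, _ = sim_logit()
        ours = SurveyLogit(y, X, weights=np.ones(len(y))).fit()
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-6)

    def test_two_by_five_cross_product_ratio(self):
        """No-covariate OR(Q1 vs Q5) equals the weighted 2x2 odds ratio."""
        rng = np.random.default_rng(4)
        n = 3000
        q = rng.integers(1, 6, n)
        w = rng.lognormal(0, 0.6, n)
        y = (rng.random(n) < np.where(q == 1, 0.25, 0.12)).astype(float)
        X = pd.DataFrame({"const": np.ones(n)})
        for k in (1, 2, 3, 4):
            X[f"Q{k}"] = (q == k).astype(float)
        fit = SurveyLogit(y, X, w).fit()
        a = w[(q == 1) & (y == 1)].sum()
        b = w[(q == 1) & (y == 0)].sum()
        c = w[(q == 5) & (y == 1)].sum()
        d = w[(q == 5) & (y == 0)].sum()
        assert np.exp(fit.params["Q1"]) == pytest.approx((a / b) / (c / d),
                                                         rel=1e-6)

    def test_binary_outcome_required(self):
        with pytest.raises(ValueError, match="binary"):
            SurveyLogit(np.array([0.0, 0.5, 1.0]), np.ones((3, 1)))

    def test_nonpositive_weights_rejected(self):
        y, X, _ = sim_logit(n=50)
        with pytest.raises(ValueError, match="positive"):
            SurveyLogit(y, X, weights=np.zeros(50))

    def test_separation_flagged(self):
        y = np.array([0.0] * 20 + [1.0] * 20)
        X = pd.DataFrame({"const": np.ones(40), "x": y * 2 - 1})
        fit = SurveyLogit(y, X).fit()
        assert fit.diagnostics["quasi_separation"]
        assert not fit.converged

    def test_sandwich_matches_r_oracle(self, tmp_path):
        """Point estimates and robust SEs agree with R glm + sandwich::vcovHC."""
        rscript = shutil.which("Rscript")
        if rscript is None:
            pytest.fail("Rscript not available for the independent oracle")
        y, X, w = sim_logit(n=120, seed=9)
        df = X.assign(y=y, w=w)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(sandwich))
            d <- read.csv("{csv}")
            m <- glm(y ~ x + z, data=d, weights=w, family=quasibinomial())
            V <- vcovHC(m, type="HC1")
            cat(coef(m), sqrt(diag(V)), sep="\\n")
        """))
        out = subprocess.run([rscript, str(script)], capture_output=True,
                             text=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        r_coef, r_se = np.array(vals[:3]), np.array(vals[3:])
        ours = SurveyLogit(y, X, w).fit()
        np.testing.assert_allclose(ours.params.to_numpy(), r_coef, rtol=1e-5)
        np.testing.assert_allclose(ours.bse.to_numpy(), r_se, rtol=1e-4)


class TestSurveyLogLinear:
    def sim(self, n=500, seed=2):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        levels = np.exp(3.0 + 0.3 * x + rng.normal(0, 0.4, n))
        w = rng.lognormal(0, 0.5, n)
        X = pd.DataFrame({"const": np.ones(n), "x": x})
        return levels, X, w / w.mean()

    def test_unit_weights_match_ols(self):
        levels, X, _ = self.sim()
        ours = SurveyLogLinear(levels, X).fit()
        ref = sm.OLS(np.log(levels), X).fit()
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-10)

    def test_level_rescaling_shifts_only_intercept(self):
        levels, X, w = self.sim()
        a = SurveyLogLinear(levels, X, w).fit()
        b = SurveyLogLinear(10.0 * levels, X, w).fit()
        assert b.params["const"] == pytest.approx(a.params["const"] + np.log(10))
        assert b.params["x"] == pytest.approx(a.params["x"], abs=1e-10)

    def test_nonpositive_levels_rejected(self):
        X = pd.DataFrame({"const": np.ones(3)})
        with pytest.raises(ValueError, match="positive"):
            SurveyLogLinear(np.array([1.0, 0.0, 2.0]), X)


class TestSurveyOrdinal:
    def sim(self, n=600, seed=5, beta=0.8):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = np.digitize(beta * x + rng.logistic(size=n), [-1.0, 0.5, 1.5])
        w = rng.lognormal(0, 0.5, n)
        return y.astype(float), pd.DataFrame({"x": x}), w / w.mean()

    def test_unit_weights_match_ordered_model(self):
        y, X, _ = self.sim()
        ours = SurveyOrdinal(y, X).fit()
        ref = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
        assert ours.params["x"] == pytest.approx(ref.params.iloc[0], abs=1e-4)

    def test_two_levels_reduce_to_logistic(self):
        y, X, w = self.sim()
        binary = (y >= 2).astype(float)
        ord_fit = SurveyOrdinal(binary, X, w).fit()
        logit = SurveyLogit(binary, X.assign(const=1.0)[["const", "x"]], w).fit()
        assert ord_fit.params["x"] == pytest.approx(logit.params["x"], abs=1e-4)
        assert ord_fit.bse["x"] == pytest.approx(logit.bse["x"], rel=0.02)

    def test_proportional_odds_recovery(self):
        y, X, w = self.sim(n=4000, seed=6, beta=0.8)
        fit = SurveyOrdinal(y, X, w).fit()
        assert fit.params["x"] == pytest.approx(0.8, abs=0.15)

    def test_permuted_exposure_is_null(self):
        y, X, w = self.sim(n=2000, seed=7)
        rng = np.random.default_rng(8)
        Xp = pd.DataFrame({"x": rng.permutation(X["x"].to_numpy())})
        fit = SurveyOrdinal(y, Xp, w).fit()
        assert abs(fit.params["x"]) < 3 * fit.bse["x"]

    def test_constant_column_rejected(self):
        y, X, _ = self.sim(n=50)
        with pytest.raises(ValueError, match="constant columns"):
            SurveyOrdinal(y, X.assign(const=1.0))

    def test_absent_level_collapsed_with_warning(self):
        y, X, _ = self.sim(n=200)
        y[y == 2] = 3  # level 2 absent
        with pytest.warns(UserWarning, match="collapsed"):
            SurveyOrdinal(y, X)


class TestWorkingLrt:
    def test_unit_weights_match_ordinary_lrt(self):
        y, X, _ = sim_logit(n=800, seed=11)
        w = np.ones(len(y))
        full = SurveyLogit(y, X, w).fit()
        reduced = SurveyLogit(y, X[["const", "x"]], w).fit()
        stat, df, p = working_lrt(full, reduced, ["z"])
        ref_full = sm.Logit(y, X).fit(disp=0)
        ref_red = sm.Logit(y, X[["const", "x"]]).fit(disp=0)
        ref_stat = 2 * (ref_full.llf - ref_red.llf)
        assert df == 1
        assert stat == pytest.approx(ref_stat, rel=0.02)

    def test_no_tested_coefficients(self):
        y, X, w = sim_logit(n=100)
        fit = SurveyLogit(y, X, w).fit()
        with pytest.raises(ValueError):
            working_lrt(fit, fit, [])
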