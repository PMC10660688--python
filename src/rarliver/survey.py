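"""Survey-weighted regression engines with sandwich (robust) variance.

Point estimates solve the weighted estimating equations
``sum_i w_i s_i(theta) = 0`` (pseudo-maximum-likelihood); statsmodels
supplies the weighted point fits (GLM / WLS / the proportional-odds
likelihood).  The variance is the survey sandwich

    V = A^{-1} B A^{-1},   A = -sum_i w_i H_i,   B = sum_i w_i^2 s_i s_i',

with an (n / (n - p)) small-sample factor on the meat.  Weights enter the
meat squared, which is what distinguishes survey (importance) weights from
frequency weights.  The interaction likelihood-ratio test is a "working"
LRT on the weighted log-likelihood with a first-order Rao-Scott correction:
the statistic is divided by the mean generalized design effect
``tr(A_22.1 V_22) / df`` so its null distribution is approximately
chi-squared even under variable weights; with unit weights the correction
is ~1 and the ordinary LRT is recovered.

Model classes follow the statsmodels convention: ``SurveyLogit(y, X, w).fit()``
returns a results object with ``params``, ``bse``, ``conf_int()``,
``pvalues`` and ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.numdiff import approx_fprime, approx_hess

__all__ = ["SurveyLogit", "SurveyLogLinear", "SurveyOrdinal",
           "SurveyResults", "working_lrt"]

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass
class SurveyResults:
    """Estimates, sandwich uncertainties and diagnostics for one weighted fit."""

    params: pd.Series
    cov_params: pd.DataFrame      # sandwich
    model_cov: pd.DataFrame       # model-based A^{-1} (for Rao-Scott)
    wllf: float                   # weighted log-likelihood at the estimate
    nobs: int
    model_name: str
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)),
                         index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.tvalues)),
                         index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.params - z * self.bse,
                             "upper": self.params + z * self.bse})

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame({"OR": np.exp(self.params),
                             "lower": np.exp(ci["lower"]),
                             "upper": np.exp(ci["upper"]),
                             "p": self.pvalues})

    def wald_test(self, name: str):
        """(z, p) Wald test of a single coefficient against zero."""
        z = float(self.params[name] / self.bse[name])
        return z, float(2 * stats.norm.sf(abs(z)))

    def summary(self) -> str:
        ci = self.conf_int()
        tab = pd.DataFrame({"coef": self.params, "se(robust)": self.bse,
                            "z": self.tvalues, "p": self.pvalues,
                            "[0.025": ci["lower"], "0.975]": ci["upper"]})
        head = (f"{self.model_name} (survey-weighted, sandwich SE)\n"
                f"n = {self.nobs}, weighted loglik = {self.wllf:.3f}, "
                f"converged = {self.converged}\n")
        return head + tab.to_string(float_format=lambda v: f"{v: .4f}")


def _as_matrix(exog) -> tuple:
    if isinstance(exog, pd.DataFrame):
        return exog.to_numpy(dtype=float), list(exog.columns)
    x = np.asarray(exog, dtype=float)
    return x, [f"x{i}" for i in range(x.shape[1])]


def _check_weights(w, n) -> np.ndarray:
    if w is None:
        return np.ones(n)
    w = np.asarray(w, dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be positive and finite")
    return w


def _sandwich(X, w, score_scalar, hess_scalar, names):
    """A^{-1} B A^{-1} for a single-index model with per-obs scalar score.

    ``score_scalar`` multiplies X rowwise to give the per-obs score vector;
    ``hess_scalar`` likewise for the (negative) Hessian contribution.
    """
    n, p = X.shape
    A = (X * (w * hess_scalar)[:, None]).T @ X
    U = X * (w * score_scalar)[:, None]
    # small-sample (HC1-style) correction on the meat
    meat = U.T @ U * n / max(n - p, 1)
    Ainv = np.linalg.pinv(A)
    cov = Ainv @ meat @ Ainv
    return (pd.DataFrame(cov, index=names, columns=names),
            pd.DataFrame(Ainv, index=names, columns=names))


class SurveyLogit:
    """Survey-weighted logistic regression (binary outcome).

    Parameters: ``endog`` 0/1 outcome, ``exog`` design matrix including a
    constant, ``weights`` positive survey weights (unit weights recover the
    ordinary ML fit).
    """

    def __init__(self, endog, exog, weights=None):
        self.y = np.asarray(endog, dtype=float)
        self.X, self.names = _as_matrix(exog)
        self.w = _check_weights(weights, self.y.size)
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")

    def fit(self) -> SurveyResults:
        glm = sm.GLM(self.y, self.X, family=sm.families.Binomial(),
                     freq_weights=self.w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm.fit(maxiter=200)
        mu = res.fittedvalues
        eps = 1e-10
        mu = np.clip(mu, eps, 1 - eps)
        separation = bool(np.any((mu < 1e-8) | (mu > 1 - 1e-8))) or \
            bool(np.any(np.abs(res.params) > 15))
        cov, model_cov = _sandwich(self.X, self.w, self.y - mu, mu * (1 - mu),
                                   self.names)
        wllf = float(np.sum(self.w * (self.y * np.log(mu)
                                      + (1 - self.y) * np.log(1 - mu))))
        return SurveyResults(
            params=pd.Series(res.params, index=self.names),
            cov_params=cov, model_cov=model_cov, wllf=wllf,
            nobs=self.y.size, model_name="logistic",
            converged=bool(res.converged) and not separation,
            diagnostics={"quasi_separation": separation})


class SurveyLogLinear:
    """Survey-weighted linear regression of log-transformed levels.

    ``endog`` must be strictly positive; the model is WLS on
    ``log(endog)`` with the survey sandwich variance.
    """

    def __init__(self, endog, exog, weights=None, log: bool = True):
        y = np.asarray(endog, dtype=float)
        if log:
            if np.any(y <= 0):
                raise ValueError("levels must be strictly positive to log-transform")
            y = np.log(y)
        self.y = y
        self.X, self.names = _as_matrix(exog)
        self.w = _check_weights(weights, self.y.size)

    def fit(self) -> SurveyResults:
        res = sm.WLS(self.y, self.X, weights=self.w).fit()
        resid = self.y - self.X @ res.params
        cov, model_cov = _sandwich(self.X, self.w, resid, np.ones(self.y.size),
                                   self.names)
        sigma2 = float(np.sum(self.w * resid ** 2) / self.w.sum())
        wllf = float(-0.5 * np.sum(self.w * (np.log(2 * np.pi * sigma2)
                                             + resid ** 2 / sigma2)))
        return SurveyResults(
            params=pd.Series(res.params, index=self.names),
            cov_params=cov, model_cov=model_cov, wllf=wllf,
            nobs=self.y.size, model_name="linear (log level)")


class SurveyOrdinal:
    """Survey-weighted proportional-odds (ordinal logistic) model.

    ``endog`` is an ordered integer outcome (e.g. the 0/1/2/3+ abnormal
    composite); levels absent from the data are collapsed away with a
    warning.  The weighted likelihood is maximized with scipy over
    statsmodels' OrderedModel parametrization (exog coefficients followed by
    monotone cut-points); the sandwich uses numerically differentiated
    per-observation scores.  With two outcome levels the fit reduces to the
    binary logistic model.
    """

    def __init__(self, endog, exog, weights=None):
        y = np.asarray(endog)
        self.X, self.names = _as_matrix(exog)
        const_cols = [n for n, s in zip(self.names, self.X.std(axis=0)) if s == 0]
        if const_cols:
            raise ValueError(
                f"remove constant columns {const_cols}: cut-points act as "
                "intercepts in the proportional-odds model")
        levels = np.unique(y)
        if levels.size < 2:
            raise ValueError("outcome must have at least 2 levels")
        span = float(levels.max() - levels.min())
        if span + 1 > levels.size:
            warnings.warn("outcome levels absent from data were collapsed",
                          stacklevel=2)
        self.levels = levels
        self.y = np.searchsorted(levels, y)
        self.w = _check_weights(weights, self.y.size)
        self._om = OrderedModel(self.y, self.X, distr="logit")

    def fit(self) -> SurveyResults:
        om, w = self._om, self.w

        def negll(params):
            ll = om.loglikeobs(params)
            return -float(np.sum(w * ll))

        start = om.start_params
        res = optimize.minimize(negll, start, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 500})
        if not res.success:  # polish with Nelder-Mead if BFGS stalls
            res = optimize.minimize(negll, res.x, method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10,
                                             "maxiter": 5000})
        params = res.x
        score_obs = approx_fprime(params, om.loglikeobs)  # (n, p)
        A = approx_hess(params, lambda p: -np.sum(w * om.loglikeobs(p)))
        sw = score_obs * w[:, None]
        n, p = sw.shape
        meat = sw.T @ sw * n / max(n - p, 1)
        Ainv = np.linalg.pinv(A)
        cov = Ainv @ meat @ Ainv

        k = self.X.shape[1]
        names = list(self.names) + [f"cut_{i}" for i in range(len(params) - k)]
        return SurveyResults(
            params=pd.Series(params, index=names),
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            model_cov=pd.DataFrame(Ainv, index=names, columns=names),
            wllf=-float(res.fun), nobs=n,
            model_name="proportional odds", converged=bool(res.success),
            diagnostics={"levels": self.levels.tolist()})


def working_lrt(full: SurveyResults, reduced: SurveyResults, tested: list):
    """Rao-Scott corrected working likelihood-ratio test of nested weighted fits.

    ``tested`` names the coefficients present in the full fit but fixed to
    zero in the reduced fit.  Under weights the naive weighted LRT statistic
    ``2 (wllf_full - wllf_reduced)`` is asymptotically a weighted sum of
    chi-squares with weights the eigenvalues of ``A_22.1 V_22`` (model-based
    information of the tested block times its sandwich covariance).  The
    second-order (Satterthwaite) Rao-Scott correction divides the statistic
    by ``delta_bar * (1 + cv^2)`` and refers it to chi-squared with
    ``df / (1 + cv^2)`` effective degrees of freedom, matching the first two
    moments of that null distribution; with unit weights the eigenvalues are
    ~1 and the ordinary LRT is recovered.  Returns
    ``(corrected statistic, nominal df, p)``.
    """
    df = len(tested)
    if df == 0:
        raise ValueError("no tested coefficients")
    lrt = 2.0 * (full.wllf - reduced.wllf)
    idx = [list(full.params.index).index(t) for t in tested]
    Vn = full.model_cov.to_numpy()[np.ix_(idx, idx)]
    Vs = full.cov_params.to_numpy()[np.ix_(idx, idx)]
    deltas = np.linalg.eigvals(np.linalg.solve(Vn, Vs)).real
    delta_bar = float(np.mean(deltas))
    cv2 = float(np.mean((deltas - delta_bar) ** 2)) / max(delta_bar, 1e-12) ** 2
    stat = max(lrt, 0.0) / max(delta_bar * (1.0 + cv2), 1e-12)
    df_eff = df / (1.0 + cv2)
    return stat, df, float(stats.chi2.sf(stat, df_eff))
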