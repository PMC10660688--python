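"""Sigmoidally-transformed extended cosine model for 24 h rest-activity rhythms.

The mean activity at clock time ``t`` (hours) is modelled as

    E[y(t)] = minimum + amplitude * antilogistic(cos((t - acrophase) * pi / 12), alpha, beta)

where ``antilogistic(c) = expit(beta * (c - alpha))`` squashes the cosine
through a logistic link.  ``alpha`` (width, in (-1, 1)) controls how much of
the day is spent near the peak; ``beta`` (steepness, > 0) controls how fast
the curve transitions between rest and activity — in the large-``beta`` limit
the fitted curve approaches a square wave.  The pseudo-F statistic compares
this five-parameter fit to a flat-mean model and quantifies overall
rhythmicity: higher F, more robust rhythm.

Usage follows the statsmodels convention::

    model = ExtendedCosineModel(hours, activity)
    res = model.fit()
    res.pseudo_f, res.amplitude, res.acrophase
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

__all__ = ["antilogistic", "ExtendedCosineModel", "ExtendedCosineResults"]

_N_PARAMS = 5  # minimum, amplitude, acrophase, alpha, beta

ALPHA_BOUNDS = (-0.99, 0.99)
BETA_BOUNDS = (0.1, 50.0)


def antilogistic(c, alpha: float, beta: float):
    """Logistic squashing of the cosine term: ``expit(beta * (c - alpha))``.

    Parameters
    ----------
    c : array_like
        Cosine values (any real; in model use, ``c`` lies in [-1, 1]).
    alpha : float
        Width parameter, must lie in (-1, 1).
    beta : float
        Steepness parameter, must be > 0.

    Returns
    -------
    Values in (0, 1), monotone increasing in ``c``; equals 0.5 at
    ``c == alpha``.  Numerically stable for large ``|beta * (c - alpha)|``.
    """
    if not -1.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (-1, 1), got {alpha}")
    if not beta > 0.0:
        raise ValueError(f"beta must be > 0, got {beta}")
    return expit(beta * (np.asarray(c, dtype=float) - alpha))


def _curve(t_hours, minimum, amplitude, acrophase, alpha, beta):
    c = np.cos((np.asarray(t_hours, dtype=float) - acrophase) * np.pi / 12.0)
    return minimum + amplitude * expit(beta * (c - alpha))


@dataclass
class ExtendedCosineResults:
    """Fit results for one participant's extended cosine model.

    ``minimum`` and ``amplitude`` are reported on the fitted-curve scale:
    ``minimum`` is the curve nadir and ``amplitude`` the peak-minus-nadir
    difference, so ``mesor = minimum + amplitude / 2`` holds exactly.
    ``acrophase`` is the clock time (hours in [0, 24)) of the fitted peak.
    """

    minimum: float
    amplitude: float
    acrophase: float
    alpha: float
    beta: float
    mesor: float
    amp_mesor_ratio: float
    pseudo_f: float
    rss: float
    rss_null: float
    n_obs: int
    converged: bool
    raw_params: dict = field(repr=False, default_factory=dict)

    def predict(self, t_hours):
        """Fitted mean activity at clock time(s) ``t_hours`` (24 h periodic)."""
        p = self.raw_params
        return _curve(t_hours, p["minimum"], p["amplitude"], p["acrophase"],
                      p["alpha"], p["beta"])

    def summary(self) -> str:
        rows = [
            ("pseudo F", self.pseudo_f),
            ("amplitude (peak - nadir)", self.amplitude),
            ("mesor", self.mesor),
            ("amplitude:mesor", self.amp_mesor_ratio),
            ("acrophase (h)", self.acrophase),
            ("minimum (nadir)", self.minimum),
            ("alpha (width)", self.alpha),
            ("beta (steepness)", self.beta),
            ("n obs", self.n_obs),
            ("converged", self.converged),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Extended cosine fit", "=" * (width + 14)]
        for k, v in rows:
            if isinstance(v, float):
                lines.append(f"{k:<{width}}  {v:12.4f}")
            else:
                lines.append(f"{k:<{width}}  {v!s:>12}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "pseudo_f": self.pseudo_f,
            "amplitude": self.amplitude,
            "mesor": self.mesor,
            "amp_mesor_ratio": self.amp_mesor_ratio,
            "acrophase": self.acrophase,
            "minimum": self.minimum,
            "alpha": self.alpha,
            "beta": self.beta,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }

    def plot(self, ax=None):
        """Plot the fitted 24 h curve (and the data if the model is attached)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0.0, 24.0, 289)
        ax.plot(grid, self.predict(grid), label="fitted curve")
        ax.set_xlabel("clock time (h)")
        ax.set_ylabel("activity")
        ax.legend()
        return ax


class ExtendedCosineModel:
    """Least-squares extended cosine model for a 5-min binned activity series.

    Parameters
    ----------
    t_hours : array_like
        Clock time of each observation in hours (time-of-day; values outside
        [0, 24) are wrapped by the 24 h periodicity of the curve).
    activity : array_like
        Observed activity; NaNs are dropped (missing bins are simply omitted
        from the least-squares sum).
    min_obs : int
        Minimum number of non-missing observations required to fit
        (default 576 = two days of 5-min bins).
    """

    def __init__(self, t_hours, activity, min_obs: int = 576):
        t = np.asarray(t_hours, dtype=float)
        y = np.asarray(activity, dtype=float)
        if t.shape != y.shape:
            raise ValueError("t_hours and activity must have the same shape")
        keep = np.isfinite(y) & np.isfinite(t)
        self.t = t[keep]
        self.y = y[keep]
        self.min_obs = min_obs
        if self.t.size < min_obs:
            raise ValueError(
                f"insufficient data: {self.t.size} non-missing observations, "
                f"need at least {min_obs}"
            )

    @classmethod
    def from_bins(cls, bins: pd.DataFrame, min_obs: int = 576) -> "ExtendedCosineModel":
        """Build from a 5-min bin table with columns ``bin_5min`` and ``activity``."""
        t = (bins["bin_5min"].to_numpy(dtype=float) * 5.0 + 2.5) / 60.0
        return cls(t, bins["activity"].to_numpy(dtype=float), min_obs=min_obs)

    # -- fitting ---------------------------------------------------------

    def _residuals(self, params):
        m, a, phi, al, be = params
        return _curve(self.t, m, a, phi, al, be) - self.y

    def fit(self, n_refine: int = 3) -> ExtendedCosineResults:
        """Fit by bounded nonlinear least squares with a multi-start grid.

        The objective is multimodal in acrophase, so candidate starts are laid
        on an acrophase grid every 2 h crossed with alpha in {-0.6, 0, 0.6};
        the ``n_refine`` best-RSS starts are polished with
        :func:`scipy.optimize.least_squares` and the best solution kept.
        """
        y = self.y
        n = y.size
        rss_null = float(np.sum((y - y.mean()) ** 2))

        m0 = max(float(np.percentile(y, 5)), 0.0)
        a0 = max(float(np.percentile(y, 95)) - m0, 1e-8)
        b0 = 2.0

        starts = [
            np.array([m0, a0, phi, al, b0])
            for phi in np.arange(0.0, 24.0, 2.0)
            for al in (-0.6, 0.0, 0.6)
        ]
        grid_rss = [float(np.sum(self._residuals(s) ** 2)) for s in starts]
        order = np.argsort(grid_rss)[:n_refine]

        lo = np.array([0.0, 0.0, -np.inf, ALPHA_BOUNDS[0], BETA_BOUNDS[0]])
        hi = np.array([np.inf, np.inf, np.inf, ALPHA_BOUNDS[1], BETA_BOUNDS[1]])

        best, best_rss, converged = None, np.inf, False
        for i in order:
            try:
                sol = least_squares(self._residuals, starts[i], bounds=(lo, hi),
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            rss = float(np.sum(sol.fun ** 2))
            if rss < best_rss:
                best, best_rss, converged = sol.x, rss, bool(sol.success)

        # the flat model (amplitude -> 0) is nested; never report a fit worse
        # than the flat-mean null
        flat = np.array([max(float(y.mean()), 0.0), 0.0, 0.0, 0.0, b0])
        flat_rss = float(np.sum(self._residuals(flat) ** 2))
        if best is None or best_rss > flat_rss:
            best, best_rss, converged = flat, flat_rss, True

        m, a, phi, al, be = (float(v) for v in best)
        phi = phi % 24.0

        # report amplitude/minimum on the fitted-curve scale (peak - nadir);
        # acrophase as the argmax of the fitted curve on a 1-min grid
        grid = np.arange(1440) / 60.0
        curve = _curve(grid, m, a, phi, al, be)
        peak = float(curve.max())
        nadir = float(curve.min())
        acrophase = float(grid[int(np.argmax(curve))]) if a > 0 else 0.0
        amplitude = peak - nadir
        minimum = nadir
        mesor = minimum + amplitude / 2.0

        pseudo_f = self._pseudo_f(best_rss, rss_null, n)

        return ExtendedCosineResults(
            minimum=minimum,
            amplitude=amplitude,
            acrophase=acrophase,
            alpha=al,
            beta=be,
            mesor=mesor,
            amp_mesor_ratio=amplitude / mesor if mesor > 0 else np.nan,
            pseudo_f=pseudo_f,
            rss=best_rss,
            rss_null=rss_null,
            n_obs=int(n),
            converged=converged,
            raw_params={"minimum": m, "amplitude": a, "acrophase": phi,
                        "alpha": al, "beta": be},
        )

    @staticmethod
    def _pseudo_f(rss: float, rss_null: float, n_obs: int) -> float:
        """Goodness-of-fit F ratio of the cosine fit against the flat-mean null.

        F = [(rss_null - rss) / (k - 1)] / [rss / (n - k)] with k = 5.
        A constant series (rss == rss_null) gives F = 0.
        """
        k = _N_PARAMS
        if n_obs <= k:
            raise ValueError(f"need more than {k} observations, got {n_obs}")
        num = rss_null - rss
        if num <= 0.0:
            return 0.0
        if rss <= 0.0:
            return np.inf
        return float((num / (k - 1)) / (rss / (n_obs - k)))


def pseudo_f(fit: ExtendedCosineResults) -> float:
    """Pseudo-F statistic of a fitted model (convenience accessor)."""
    return ExtendedCosineModel._pseudo_f(fit.rss, fit.rss_null, fit.n_obs)
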