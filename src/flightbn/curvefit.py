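"""Upper-bound flight-environment response curves.

The flight response to a meteorological driver is characterized by the
*upper bound* of observed activity: the covariate axis is split into
intervals, the maximum observed catch per trap-hour in each interval is
taken, and a parametric curve is fitted to those interval maxima:

* temperature: Gaussian,  Y = k * exp(-(T - mu)^2 / (2 sigma^2));
* wind (decaying): negative exponential,  Y = y0 * exp(w / b), b < 0;
* wind/light/humidity (humped): gamma GAM with inverse link.

Outliers are screened once by Cook's distance (> 1 flags, refit excluding
flagged); goodness of fit is Wherry's adjusted R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .discretize import DiscretizationScheme


def gaussian_curve(t, k: float, mu: float, sigma: float):
    """Peak catch k at mode mu, width sigma (same units as t)."""
    t = np.asarray(t, dtype=float)
    return k * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def negexp_curve(x, y0: float, b: float):
    """Intercept y0 at x = 0; decays when b < 0."""
    x = np.asarray(x, dtype=float)
    return y0 * np.exp(x / b)


def interval_maxima(x, catch, scheme: DiscretizationScheme) -> pd.DataFrame:
    """Maximum observed catch per interval of ``scheme``; empty bins omitted.

    Returns columns lo, hi, mid, max_catch, n.  The bin abscissa used for
    curve fitting is the interval midpoint.
    """
    x = np.asarray(x, dtype=float)
    catch = np.asarray(catch, dtype=float)
    if x.size == 0:
        raise ValueError("no data")
    ok = np.isfinite(x) & np.isfinite(catch)
    x, catch = x[ok], catch[ok]
    idx = scheme.assign(x)
    lo_edge = scheme.lo if scheme.lo is not None else float(x.min())
    hi_edge = scheme.hi if scheme.hi is not None else float(x.max())
    edges = np.concatenate([[lo_edge], scheme.cuts, [hi_edge]])
    rows = []
    for b in range(scheme.n_states):
        sel = idx == b
        if not sel.any():
            continue
        rows.append(
            {
                "lo": edges[b],
                "hi": edges[b + 1],
                "mid": (edges[b] + edges[b + 1]) / 2.0,
                "max_catch": float(catch[sel].max()),
                "n": int(sel.sum()),
            }
        )
    if not rows:
        raise ValueError("no data fell in any interval")
    return pd.DataFrame(rows)


@dataclass
class GaussianFit:
    k: float
    mu: float
    sigma: float
    adj_r2: float
    se: tuple[float, float, float] | None = None
    outliers_removed: list = field(default_factory=list)

    def predict(self, t):
        return gaussian_curve(t, self.k, self.mu, self.sigma)

    def to_dict(self) -> dict:
        return {
            "family": "gaussian",
            "k": self.k,
            "mu": self.mu,
            "sigma": self.sigma,
            "adj_r2": self.adj_r2,
            "se": list(self.se) if self.se is not None else None,
            "outliers_removed": self.outliers_removed,
        }


@dataclass
class NegExpFit:
    y0: float
    b: float
    adj_r2: float
    se: tuple[float, float] | None = None
    outliers_removed: list = field(default_factory=list)

    def predict(self, x):
        return negexp_curve(x, self.y0, self.b)

    def to_dict(self) -> dict:
        return {
            "family": "negexp",
            "y0": self.y0,
            "b": self.b,
            "adj_r2": self.adj_r2,
            "se": list(self.se) if self.se is not None else None,
            "outliers_removed": self.outliers_removed,
        }


def adjusted_r2_wherry(r2: float, n: int, p: int) -> float:
    """Wherry's shrinkage:  1 - (1 - R^2) (n - 1)/(n - p - 1)."""
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 outside [0, 1]")
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("response has zero variance (degenerate)")
    return max(0.0, 1.0 - ss_res / ss_tot)


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge."""


def _fit_nls(func, x, y, p0, bounds, n_restarts: int = 20, seed: int = 0):
    rng = np.random.default_rng(seed)
    last_err = None
    p0 = np.asarray(p0, dtype=float)
    for attempt in range(n_restarts + 1):
        trial = p0 if attempt == 0 else p0 * rng.uniform(0.5, 1.5, size=p0.shape)
        trial = np.clip(trial, bounds[0], bounds[1])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    func, x, y, p0=trial, bounds=bounds, maxfev=20000
                )
            return popt, pcov
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
    raise FitError(f"nonlinear fit failed after {n_restarts} restarts: {last_err}")


def fit_gaussian(bins: pd.DataFrame, seed: int = 0) -> GaussianFit:
    """Gaussian NLS on (interval midpoint, interval maximum).

    Initialization: k0 = max(y), mu0 = midpoint of the maximal bin, sigma0 =
    catch-weighted SD of the midpoints; up to 20 jittered restarts.
    """
    x = bins["mid"].to_numpy(dtype=float)
    y = bins["max_catch"].to_numpy(dtype=float)
    if (y > 0).sum() < 4:
        raise ValueError("need at least 4 bins with positive maxima")
    if np.allclose(y, y[0]):
        raise ValueError("interval maxima are constant (degenerate)")
    w = np.clip(y, 0, None)
    mu0 = x[np.argmax(y)]
    sigma0 = float(np.sqrt(np.average((x - np.average(x, weights=w + 1e-12)) ** 2, weights=w + 1e-12)))
    sigma0 = max(sigma0, 1e-3)
    p0 = [float(y.max()), float(mu0), sigma0]
    span = float(x.max() - x.min())
    bounds = ([1e-12, x.min() - span, 1e-9], [np.inf, x.max() + span, np.inf])
    popt, pcov = _fit_nls(lambda t, k, mu, s: gaussian_curve(t, k, mu, s), x, y, p0, bounds, seed=seed)
    yhat = gaussian_curve(x, *popt)
    adj = adjusted_r2_wherry(_r2(y, yhat), len(y), 3)
    se = tuple(np.sqrt(np.diag(pcov))) if np.all(np.isfinite(pcov)) else None
    return GaussianFit(float(popt[0]), float(popt[1]), float(popt[2]), adj, se)


def fit_negexp(bins: pd.DataFrame, seed: int = 0) -> NegExpFit:
    """Negative-exponential NLS:  Y = y0 * exp(x / b)."""
    x = bins["mid"].to_numpy(dtype=float)
    y = bins["max_catch"].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 bins")
    # log-linear start where y > 0
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        b0 = 1.0 / slope if slope != 0 else -1.0
        y00 = float(np.exp(intercept))
    else:
        b0, y00 = -1.0, float(max(y.max(), 1e-6))
    p0 = [y00, b0]
    bounds = ([1e-12, -np.inf], [np.inf, np.inf])
    popt, pcov = _fit_nls(lambda t, y0, b: negexp_curve(t, y0, b), x, y, p0, bounds, seed=seed)
    yhat = negexp_curve(x, *popt)
    adj = adjusted_r2_wherry(_r2(y, yhat), len(y), 2)
    se = tuple(np.sqrt(np.diag(pcov))) if np.all(np.isfinite(pcov)) else None
    return NegExpFit(float(popt[0]), float(popt[1]), adj, se)


def _jacobian(predict, params, x, eps=1e-6):
    params = np.asarray(params, dtype=float)
    J = np.empty((len(x), len(params)))
    for j in range(len(params)):
        step = eps * max(1.0, abs(params[j]))
        hi = params.copy()
        hi[j] += step
        lo = params.copy()
        lo[j] -= step
        J[:, j] = (predict(x, *hi) - predict(x, *lo)) / (2 * step)
    return J


def cooks_outliers(fit, bins: pd.DataFrame, refit=None) -> dict:
    """Cook's distance per observation for a nonlinear fit; flag D > 1.

    Uses the linearized hat matrix H = J (J'J)^-1 J' at the fitted
    parameters.  Screening is a single pass: flag, remove, refit once with
    the supplied ``refit`` callable (signature like fit_gaussian).
    Returns {"cooks_d", "flagged", "refit"}.
    """
    x = bins["mid"].to_numpy(dtype=float)
    y = bins["max_catch"].to_numpy(dtype=float)
    if isinstance(fit, GaussianFit):
        params = (fit.k, fit.mu, fit.sigma)
        predict = gaussian_curve
    elif isinstance(fit, NegExpFit):
        params = (fit.y0, fit.b)
        predict = negexp_curve
    else:
        raise TypeError(f"unsupported fit type {type(fit)}")
    p = len(params)
    resid = y - predict(x, *params)
    n = len(x)
    dof = max(n - p, 1)
    s2 = float(resid @ resid) / dof
    J = _jacobian(predict, params, x)
    JtJ = J.T @ J
    H = J @ np.linalg.pinv(JtJ) @ J.T
    h = np.clip(np.diag(H), 0.0, 1.0 - 1e-9)
    # residuals at numerical-noise scale mean a perfect fit: no outliers
    if s2 <= (1e-7 * max(1.0, float(np.abs(y).max()))) ** 2:
        cooks = np.zeros(n)
    else:
        cooks = (resid**2 / (p * s2)) * (h / (1.0 - h) ** 2)
    flagged = [int(i) for i in np.nonzero(cooks > 1.0)[0]]
    refit_result = None
    if flagged and refit is not None:
        kept = bins.drop(bins.index[flagged]).reset_index(drop=True)
        refit_result = refit(kept)
        refit_result.outliers_removed = flagged
    return {"cooks_d": cooks, "flagged": flagged, "refit": refit_result}


@dataclass
class GamFit:
    """Penalized-spline gamma GAM (inverse link) over wind/PAR/RH smooths."""

    terms: list
    edf: dict
    adj_r2: float
    llf: float
    llf_null: float
    lrt_stat: float
    lrt_df: float
    lrt_pvalue: float
    fitted: np.ndarray
    result: object = None

    @property
    def significant(self) -> bool:
        return self.lrt_pvalue < 0.05

    def to_dict(self) -> dict:
        return {
            "family": "gamma_gam",
            "terms": self.terms,
            "edf": self.edf,
            "adj_r2": self.adj_r2,
            "lrt_stat": self.lrt_stat,
            "lrt_df": self.lrt_df,
            "lrt_pvalue": self.lrt_pvalue,
        }


def fit_gam_gamma(
    response,
    covariates: pd.DataFrame,
    df_spline: int = 8,
    zero_offset: bool = True,
) -> GamFit:
    """Gamma GAM with inverse link over the given smooth covariates.

    Zero responses (empty-bin maxima) are lifted by the smallest positive
    response * 1e-3 so the gamma support is respected.  Significance
    against the intercept-only gamma GLM uses the dispersion-adjusted
    likelihood-ratio statistic (deviance difference over the alternative's
    estimated dispersion) referred to an F distribution, the form required
    when the gamma dispersion is estimated.
    """
    import statsmodels.api as sm
    from scipy import stats
    from statsmodels.gam.api import BSplines, GLMGam

    y = np.asarray(response, dtype=float)
    X = covariates.copy()
    if (y < 0).any():
        raise ValueError("negative response values")
    if (y == 0).any():
        if not zero_offset:
            raise ValueError("non-positive response values")
        positive = y[y > 0]
        if positive.size == 0:
            raise ValueError("all responses are zero")
        y = y + positive.min() * 1e-3
    cols = list(X.columns)
    df_spline = min(df_spline, max(4, len(y) // (2 * len(cols))))
    bs = BSplines(X[cols], df=[df_spline] * len(cols), degree=[3] * len(cols))
    family = sm.families.Gamma(link=sm.families.links.InversePower())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = GLMGam(y, np.ones((len(y), 1)), smoother=bs, family=family).fit()
        null = sm.GLM(y, np.ones((len(y), 1)), family=family).fit()
    lrt = float((null.deviance - res.deviance) / res.scale)
    df = max(float(res.df_model), 1.0)
    pval = float(stats.f.sf(max(lrt, 0.0) / df, df, float(res.df_resid)))
    fitted = np.asarray(res.fittedvalues)
    r2 = _r2(y, fitted)
    n = len(y)
    p = int(np.ceil(df))
    adj = adjusted_r2_wherry(r2, n, p) if n > p + 1 else float("nan")
    edf = {c: df / len(cols) for c in cols}
    return GamFit(
        terms=cols,
        edf=edf,
        adj_r2=adj,
        llf=float(res.llf),
        llf_null=float(null.llf),
        lrt_stat=float(lrt),
        lrt_df=df,
        lrt_pvalue=pval,
        fitted=fitted,
        result=res,
    )
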