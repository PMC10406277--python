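"""Covariate-free local false discovery rate baseline.

The mixture density f of the signed test statistics is estimated by
Lindsey's method -- histogram counts modeled with a Poisson generalized
linear model whose log mean is a polynomial in the bin midpoints -- and the
empirical null f0 ~ Normal(delta0, sigma0^2) with null proportion p0 is read
off a quadratic fit to log f on the central part of the distribution (the
"zero assumption": statistics near the center are overwhelmingly null).
lfdr(t) = p0 f0(t) / f(t), capped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = ["LfdrFit", "DensityFit", "fit_mixture_density", "central_matching_null",
           "lfdr_values", "fit_lfdr"]


@dataclass
class DensityFit:
    """Poisson-regression (Lindsey) estimate of the mixture density."""

    grid: np.ndarray               # bin midpoints
    f_grid: np.ndarray             # normalized density on the grid
    edges: np.ndarray
    counts: np.ndarray
    coef: np.ndarray               # polynomial coefficients on the standardized scale
    degree: int
    loc: float                     # standardization of the polynomial argument
    scale: float
    log_norm: float                # log of the density normalization constant

    def __call__(self, t) -> np.ndarray:
        """Evaluate the fitted density; arguments are clipped to the fit range."""
        t = np.clip(np.asarray(t, dtype=float), self.grid[0], self.grid[-1])
        z = (t - self.loc) / self.scale
        return np.exp(np.polynomial.polynomial.polyval(z, self.coef) - self.log_norm)


def fit_mixture_density(t, n_bins: int = 120, degree: int = 7) -> DensityFit:
    """Estimate the marginal density of signed statistics by Lindsey's method.

    Histogram counts are modeled as Poisson with log mean polynomial in the
    standardized bin midpoints.  On GLM failure the degree is reduced and the
    fit retried; degrees below 2 raise.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 3 * n_bins // 2:
        raise ValueError("need a long vector of statistics for density estimation")
    counts, edges = np.histogram(t, bins=n_bins)
    mids = 0.5 * (edges[:-1] + edges[1:])
    loc, scale = float(t.mean()), float(t.std())
    z = (mids - loc) / scale

    last_err: Exception | None = None
    for deg in range(degree, 1, -1):
        design = np.vander(z, deg + 1, increasing=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(counts, design, family=sm.families.Poisson()).fit(maxiter=200)
            if not np.all(np.isfinite(res.params)):
                raise ValueError("non-finite GLM coefficients")
            coef = res.params
            break
        except Exception as err:  # retry with a smoother polynomial
            last_err = err
    else:
        raise RuntimeError(f"Poisson density fit failed down to degree 2: {last_err}")

    log_mu = np.polynomial.polynomial.polyval(z, coef)
    width = float(edges[1] - edges[0])
    # normalize exp(log_mu) so the grid density integrates to one
    log_norm = float(np.log(np.sum(np.exp(log_mu - log_mu.max())) * width) + log_mu.max())
    f_grid = np.exp(log_mu - log_norm)
    return DensityFit(grid=mids, f_grid=f_grid, edges=edges, counts=counts,
                      coef=coef, degree=len(coef) - 1, loc=loc, scale=scale,
                      log_norm=log_norm)


def central_matching_null(
    density: DensityFit, center_mass: float = 0.5
) -> tuple[float, float, float]:
    """Empirical null (delta0, sigma0, p0) from a quadratic fit to log f.

    The quadratic is fitted on the grid points carrying the central
    ``center_mass`` fraction of the estimated density; its vertex gives the
    null center, its curvature the null sd, and its height the null
    proportion (capped at 1).  A non-concave quadratic raises.
    """
    if not 0 < center_mass < 1:
        raise ValueError("center_mass must lie in (0, 1)")
    width = float(density.edges[1] - density.edges[0])
    cdf = np.cumsum(density.f_grid) * width
    lo_q, hi_q = (1 - center_mass) / 2, (1 + center_mass) / 2
    sel = (cdf >= lo_q) & (cdf <= hi_q)
    if sel.sum() < 5:
        raise ValueError("central window too narrow for a quadratic fit")
    x = density.grid[sel]
    y = np.log(density.f_grid[sel])
    if not np.all(np.isfinite(y)):
        raise ValueError("estimated density vanishes on the central window")
    c2, c1, c0 = np.polyfit(x, y, 2)
    if c2 >= 0:
        raise ValueError("log-density not concave at the center; no empirical null")
    sigma0_sq = -1.0 / (2.0 * c2)
    delta0 = c1 * sigma0_sq
    sigma0 = float(np.sqrt(sigma0_sq))
    # height of the matched weighted-null density at its mode
    log_p0 = c0 + delta0**2 / (2 * sigma0_sq) + 0.5 * np.log(2 * np.pi * sigma0_sq)
    p0 = float(min(1.0, np.exp(log_p0)))
    return float(delta0), sigma0, p0


@dataclass
class LfdrFit:
    """Fitted covariate-free lfdr model."""

    delta0_hat: float
    sigma0_hat: float
    p0_hat: float
    density: DensityFit
    lfdr: np.ndarray

    def lfdr_at(self, t) -> np.ndarray:
        return lfdr_values(t, self)


def lfdr_values(t, fit: LfdrFit) -> np.ndarray:
    """p0 f0(t) / f(t), capped at 1; zero estimated density maps to 1."""
    t = np.asarray(t, dtype=float)
    f0 = stats.norm.pdf(t, loc=fit.delta0_hat, scale=fit.sigma0_hat)
    f = fit.density(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = fit.p0_hat * f0 / f
    out = np.where(f <= 0, 1.0, out)
    return np.minimum(out, 1.0)


def fit_lfdr(t, n_bins: int = 120, degree: int = 7, center_mass: float = 0.5) -> LfdrFit:
    """Fit the full baseline on signed statistics and evaluate lfdr per input."""
    density = fit_mixture_density(t, n_bins=n_bins, degree=degree)
    delta0, sigma0, p0 = central_matching_null(density, center_mass=center_mass)
    fit = LfdrFit(delta0_hat=delta0, sigma0_hat=sigma0, p0_hat=p0,
                  density=density, lfdr=np.empty(0))
    fit.lfdr = lfdr_values(np.asarray(t, dtype=float), fit)
    return fit
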