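"""Scikit-learn style estimators wrapping the mixture model and the baseline.

``BayesianLocalFdr`` fits the covariate-modulated two-group mixture by MCMC
and scores per-link posterior null probabilities; ``EfronLocalFdr`` is the
covariate-free empirical-null baseline.  Both follow the fit/predict_proba
protocol, validate their inputs, expose fitted attributes with trailing
underscores, and compose with sklearn model-selection utilities through
``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import efron
from .decision import DecisionResult, oracle_reject
from .mixture import HyperParams, LinkStatsTable, blfdr_posterior
from .sampler import SamplerConfig, blfdr_from_summary, run_chains

__all__ = ["BayesianLocalFdr", "EfronLocalFdr"]


def _as_table(X) -> LinkStatsTable:
    if isinstance(X, LinkStatsTable):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("X must be a LinkStatsTable or an (m, 2) array of [t_f, t_s]")
    return LinkStatsTable(arr[:, 0], arr[:, 1])


class BayesianLocalFdr(BaseEstimator):
    """Covariate-modulated Bayesian local false discovery rate model.

    Parameters mirror the model's hyperparameters and the MCMC protocol; see
    :class:`~blfdr.mixture.HyperParams` and
    :class:`~blfdr.sampler.SamplerConfig`.  The default protocol is the full
    study protocol (3 x 325,000 iterations); pass ``preset="desk"`` or
    ``preset="quick"`` for shorter chains.

    Attributes
    ----------
    summary_ : PosteriorSummary
        Pooled posterior medians, credible intervals and diagnostics.
    params_ : ModelParams
        Posterior medians as a plug-in parameter point.
    blfdr_ : ndarray of shape (m,)
        Posterior null probability of each training link.
    """

    _PRESETS = {
        "paper": dict(),
        "desk": dict(n_iter=20_000, burn_in=5_000, thin=10),
        "quick": dict(n_chains=1, n_iter=2_000, burn_in=500, thin=3),
    }

    def __init__(
        self,
        mu1: float = 0.674,
        preset: str = "paper",
        n_chains: int | None = None,
        n_iter: int | None = None,
        burn_in: int | None = None,
        thin: int | None = None,
        mtm_tries: int = 5,
        mtm_scale_alpha: float = 0.1,
        mtm_scale_gamma: float = 0.1,
        random_state: int = 0,
    ):
        self.mu1 = mu1
        self.preset = preset
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.mtm_tries = mtm_tries
        self.mtm_scale_alpha = mtm_scale_alpha
        self.mtm_scale_gamma = mtm_scale_gamma
        self.random_state = random_state

    def _config(self) -> SamplerConfig:
        if self.preset not in self._PRESETS:
            raise ValueError(f"unknown preset '{self.preset}'")
        kw = dict(self._PRESETS[self.preset])
        for name in ("n_chains", "n_iter", "burn_in", "thin"):
            val = getattr(self, name)
            if val is not None:
                kw[name] = val
        kw.update(
            mtm_tries=self.mtm_tries,
            mtm_scale_alpha=self.mtm_scale_alpha,
            mtm_scale_gamma=self.mtm_scale_gamma,
            seed=self.random_state,
        )
        return SamplerConfig(**kw)

    def _hyper(self) -> HyperParams:
        return HyperParams(mu1=self.mu1)

    def fit(self, X, y=None):
        table = _as_table(X)
        hyper = self._hyper()
        self.summary_ = run_chains(table, self._config(), hyper)
        self.params_ = self.summary_.median_params()
        self.blfdr_ = blfdr_from_summary(table, self.summary_, hyper)
        self.acceptance_rates_ = self.summary_.acceptance_rates
        self.n_features_in_ = 2
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def blfdr(self, X) -> np.ndarray:
        """Posterior null probability per link at the posterior medians."""
        self._check_fitted()
        table = _as_table(X)
        return np.asarray(
            blfdr_posterior(table.t_f, table.t_s, self.params_, self._hyper())
        )

    def predict_proba(self, X) -> np.ndarray:
        """Column-stacked [P(null), P(alternative)] per link."""
        p0 = self.blfdr(X)
        return np.column_stack([p0, 1.0 - p0])

    def decide(self, X=None, q: float = 0.2) -> DecisionResult:
        """Oracle FDR decision at level q (training links when X is None)."""
        self._check_fitted()
        scores = self.blfdr_ if X is None else self.blfdr(X)
        return oracle_reject(scores, q)


class EfronLocalFdr(BaseEstimator):
    """Covariate-free empirical-null local fdr baseline.

    Fits the marginal density of signed statistics by Poisson regression on
    histogram counts (Lindsey's method) and the empirical null by central
    matching; ``predict_proba`` evaluates p0 f0 / f capped at 1.
    """

    def __init__(self, n_bins: int = 120, degree: int = 7, center_mass: float = 0.5):
        self.n_bins = n_bins
        self.degree = degree
        self.center_mass = center_mass

    def fit(self, X, y=None):
        t = np.asarray(X, dtype=float).reshape(-1)
        fit = efron.fit_lfdr(
            t, n_bins=self.n_bins, degree=self.degree, center_mass=self.center_mass
        )
        self.fit_ = fit
        self.delta0_ = fit.delta0_hat
        self.sigma0_ = fit.sigma0_hat
        self.p0_ = fit.p0_hat
        self.lfdr_ = fit.lfdr
        self.n_features_in_ = 1
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "fit_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        t = np.asarray(X, dtype=float).reshape(-1)
        p0 = efron.lfdr_values(t, self.fit_)
        return np.column_stack([p0, 1.0 - p0])

    def decide(self, X=None, q: float = 0.2) -> DecisionResult:
        if not hasattr(self, "fit_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        scores = self.lfdr_ if X is None else self.predict_proba(X)[:, 0]
        return oracle_reject(scores, q)
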