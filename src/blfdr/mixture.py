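"""Two-group mixture model for absolute connectivity test statistics.

The null component is a folded normal centered at zero (a half-normal) with
unknown scale ``sigma0_sq``; the alternative component is a gamma density
shifted to start at ``mu1``, the median of the standard folded normal, whose
shape is a log-linear function of the structural-connectivity (SC) statistic.
The prior probability that a link is non-null follows a logistic regression
on the SC statistic, so structural evidence modulates both the mixing weight
and the alternative density of the functional-connectivity (FC) statistic.

All density arithmetic is done on the log scale; posterior null probabilities
(the BLfdr values) use a stable log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

__all__ = [
    "LinkStatsTable",
    "HyperParams",
    "ModelParams",
    "folded_normal_pdf",
    "folded_normal_logpdf",
    "gamma_shape",
    "shifted_gamma_pdf",
    "shifted_gamma_logpdf",
    "prior_prob_alt",
    "prior_prob_null",
    "mixture_density",
    "complete_data_loglik",
    "blfdr_posterior",
]

#: Median of the standard folded normal distribution; the fixed location of
#: the shifted-gamma alternative component.  Statistics at or below this
#: value are treated as null a priori.
MU1_DEFAULT = 0.674


def _as_1d_nonneg(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains missing or non-finite values")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative (absolute statistics)")
    return arr


@dataclass(frozen=True)
class LinkStatsTable:
    """Absolute per-link test statistics for FC and SC.

    Parameters
    ----------
    t_f : array-like of shape (m,)
        Absolute FC test statistics, one per link.
    t_s : array-like of shape (m,)
        Absolute SC test statistics, aligned with ``t_f``.
    link_labels : sequence of (str, str), optional
        ROI pair labels for each link.
    """

    t_f: np.ndarray
    t_s: np.ndarray
    link_labels: Sequence[tuple[str, str]] | None = None

    def __post_init__(self):
        t_f = _as_1d_nonneg(self.t_f, "t_f")
        t_s = _as_1d_nonneg(self.t_s, "t_s")
        if len(t_f) != len(t_s):
            raise ValueError("t_f and t_s must have equal length")
        if len(t_f) < 2:
            raise ValueError("need at least two links")
        if self.link_labels is not None and len(self.link_labels) != len(t_f):
            raise ValueError("link_labels length mismatch")
        object.__setattr__(self, "t_f", t_f)
        object.__setattr__(self, "t_s", t_s)

    @property
    def m(self) -> int:
        return len(self.t_f)

    def to_frame(self) -> pd.DataFrame:
        labels = self.link_labels or [("", "")] * self.m
        return pd.DataFrame(
            {
                "roi_a": [a for a, _ in labels],
                "roi_b": [b for _, b in labels],
                "t_f": self.t_f,
                "t_s": self.t_s,
            }
        )

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LinkStatsTable":
        required = {"t_f", "t_s"}
        if not required.issubset(df.columns):
            raise ValueError(f"table must contain columns {sorted(required)}")
        if df[["t_f", "t_s"]].isna().any().any():
            raise ValueError("rows with missing statistics are rejected")
        labels = None
        if {"roi_a", "roi_b"}.issubset(df.columns):
            labels = list(zip(df["roi_a"].astype(str), df["roi_b"].astype(str)))
        return cls(df["t_f"].to_numpy(float), df["t_s"].to_numpy(float), labels)

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "LinkStatsTable":
        return cls.from_frame(pd.read_csv(path, sep=sep))


def _check_spd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (2, 2) or not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be a symmetric 2x2 matrix")
    if np.any(np.linalg.eigvalsh(mat) <= 0):
        raise ValueError(f"{name} must be positive definite")
    return mat


@dataclass(frozen=True)
class HyperParams:
    """Fixed constants of the mixture model and its priors.

    ``mu1`` is the shifted-gamma location (median of the standard folded
    normal); ``a_beta, b_beta`` the Gamma(1, 1) prior on the gamma rate;
    ``a_sigma, b_sigma`` the Inverse-Gamma(3, 2) prior on the null scale
    (mean 1, variance 1); ``Sigma_alpha, Sigma_gamma`` bivariate-normal prior
    covariances for the coefficient blocks; ``nu`` the degrees of freedom of
    the multivariate-t Metropolis proposal.  The null location is fixed at
    zero and is not user-settable.
    """

    mu1: float = MU1_DEFAULT
    a_beta: float = 1.0
    b_beta: float = 1.0
    a_sigma: float = 3.0
    b_sigma: float = 2.0
    Sigma_alpha: np.ndarray = field(default_factory=lambda: np.eye(2))
    Sigma_gamma: np.ndarray = field(default_factory=lambda: np.eye(2))
    nu: int = 4

    #: Null location; the folded normal degenerates to the half-normal.
    mu0: float = field(default=0.0, init=False)

    def __post_init__(self):
        if self.mu1 <= 0:
            raise ValueError("mu1 must be positive")
        for name in ("a_beta", "b_beta", "a_sigma", "b_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nu <= 0:
            raise ValueError("nu must be a positive integer")
        object.__setattr__(self, "Sigma_alpha", _check_spd(self.Sigma_alpha, "Sigma_alpha"))
        object.__setattr__(self, "Sigma_gamma", _check_spd(self.Sigma_gamma, "Sigma_gamma"))


@dataclass
class ModelParams:
    """One point in the model's parameter space."""

    alpha: tuple[float, float] = (0.0, 0.0)
    gamma: tuple[float, float] = (0.0, 0.0)
    beta: float = 1.0
    sigma0_sq: float = 1.0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.sigma0_sq <= 0:
            raise ValueError("sigma0_sq must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha[0], self.alpha[1], self.beta,
             self.gamma[0], self.gamma[1], self.sigma0_sq]
        )

    names = ("alpha0", "alpha1", "beta", "gamma0", "gamma1", "sigma0_sq")

    @classmethod
    def from_dict(cls, d) -> "ModelParams":
        return cls(
            alpha=(d["alpha0"], d["alpha1"]),
            gamma=(d["gamma0"], d["gamma1"]),
            beta=d["beta"],
            sigma0_sq=d["sigma0_sq"],
        )


# ---------------------------------------------------------------------------
# component densities


def folded_normal_logpdf(t, sigma0_sq: float):
    """Log density of the zero-location folded normal (half-normal).

    With the location fixed at zero the two reflection terms coincide, so the
    density is twice the normal density: sqrt(2/(pi*s2)) * exp(-t^2/(2*s2)).
    Returns -inf for t < 0.
    """
    if sigma0_sq <= 0:
        raise ValueError("sigma0_sq must be positive")
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        out = 0.5 * np.log(2.0 / (np.pi * sigma0_sq)) - t**2 / (2.0 * sigma0_sq)
    return np.where(t < 0, -np.inf, out)


def folded_normal_pdf(t, sigma0_sq: float):
    """Density of |X| for X ~ Normal(0, sigma0_sq); zero for t < 0."""
    return np.exp(folded_normal_logpdf(t, sigma0_sq))


def gamma_shape(t_s, alpha):
    """Log-linear shape of the alternative gamma: exp(alpha0 + alpha1 * t_s)."""
    a0, a1 = alpha
    return np.exp(a0 + a1 * np.asarray(t_s, dtype=float))


def shifted_gamma_logpdf(t, shape, rate, mu1: float = MU1_DEFAULT):
    """Log density of mu1 + Gamma(shape, rate); -inf at or below mu1."""
    shape = np.asarray(shape, dtype=float)
    if np.any(shape <= 0) or np.any(np.asarray(rate) <= 0):
        raise ValueError("shape and rate must be positive")
    t = np.asarray(t, dtype=float)
    d = t - mu1
    with np.errstate(divide="ignore", invalid="ignore"):
        out = shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(d) - rate * d
    return np.where(d > 0, out, -np.inf)


def shifted_gamma_pdf(t, shape, rate, mu1: float = MU1_DEFAULT):
    """Density of the shifted-gamma alternative; exactly zero for t <= mu1."""
    return np.exp(shifted_gamma_logpdf(t, shape, rate, mu1))


def prior_prob_alt(t_s, gamma):
    """Prior P(link is alternative | t_s): logistic in the SC statistic."""
    g0, g1 = gamma
    return expit(g0 + g1 * np.asarray(t_s, dtype=float))


def prior_prob_null(t_s, gamma):
    """Prior P(link is null | t_s) = 1 - prior_prob_alt; computed stably."""
    g0, g1 = gamma
    return expit(-(g0 + g1 * np.asarray(t_s, dtype=float)))


def _log_pi(t_s, gamma):
    """(log pi1, log pi0) computed with log1p-exp stability."""
    g0, g1 = gamma
    eta = g0 + g1 * np.asarray(t_s, dtype=float)
    log_pi1 = -np.logaddexp(0.0, -eta)
    log_pi0 = -np.logaddexp(0.0, eta)
    return log_pi1, log_pi0


def _component_logdens(t_f, t_s, params: ModelParams, hyper: HyperParams):
    """Weighted log component densities (log pi0 + log f0, log pi1 + log f1)."""
    log_pi1, log_pi0 = _log_pi(t_s, params.gamma)
    log_f0 = folded_normal_logpdf(t_f, params.sigma0_sq)
    shape = gamma_shape(t_s, params.alpha)
    log_f1 = shifted_gamma_logpdf(t_f, shape, params.beta, hyper.mu1)
    return log_pi0 + log_f0, log_pi1 + log_f1


def mixture_density(t_f, t_s, params: ModelParams, hyper: HyperParams | None = None):
    """Marginal density of the FC statistic given the SC statistic."""
    hyper = hyper or HyperParams()
    ln0, ln1 = _component_logdens(t_f, t_s, params, hyper)
    return np.exp(ln0) + np.exp(ln1)


def blfdr_posterior(t_f, t_s, params: ModelParams, hyper: HyperParams | None = None):
    """Posterior null probability per link (the BLfdr value).

    pi0*f0 / (pi0*f0 + pi1*f1), evaluated in log space.  Exactly 1 whenever
    t_f <= mu1 (the alternative density has no support there).
    """
    hyper = hyper or HyperParams()
    ln0, ln1 = _component_logdens(t_f, t_s, params, hyper)
    if np.any(np.isneginf(ln0) & np.isneginf(ln1)):
        raise FloatingPointError("both mixture components vanished")
    # P(null) = 1 / (1 + exp(ln1 - ln0))
    out = expit(-(np.asarray(ln1) - np.asarray(ln0)))
    return out


def complete_data_loglik(
    table: LinkStatsTable,
    w,
    params: ModelParams,
    hyper: HyperParams | None = None,
) -> float:
    """Complete-data log likelihood given latent membership indicators ``w``."""
    hyper = hyper or HyperParams()
    w = np.asarray(w)
    if w.shape != table.t_f.shape or not np.isin(w, (0, 1)).all():
        raise ValueError("w must be a binary vector of length m")
    if np.any((w == 1) & (table.t_f <= hyper.mu1)):
        raise ValueError("w_i = 1 with t_f <= mu1 has zero density")
    ln0, ln1 = _component_logdens(table.t_f, table.t_s, params, hyper)
    return float(np.sum(np.where(w == 1, ln1, ln0)))
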