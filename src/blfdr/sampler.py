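"""Gibbs sampler for the covariate-modulated two-group mixture model.

Per sweep the sampler updates, in order: the latent membership indicators
``w`` (exact Bernoulli full conditional), the gamma-shape coefficient block
``alpha`` and the logistic-prior block ``gamma`` (each by one multiple-try
Metropolis step with symmetric multivariate-t proposals), the gamma rate
``beta`` (conjugate Gamma draw) and the null scale ``sigma0_sq`` (conjugate
Inverse-Gamma draw).

Proposal scales for the two Metropolis blocks are adapted during burn-in
toward a 20-50% acceptance rate and frozen afterwards, so the retained
portion of each chain is a draw from a fixed-kernel Markov chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .mixture import HyperParams, LinkStatsTable, ModelParams

__all__ = [
    "SamplerConfig",
    "ChainState",
    "PosteriorSummary",
    "initialize",
    "update_beta",
    "update_sigma0_sq",
    "update_latent",
    "update_alpha_mtm",
    "update_gamma_mtm",
    "mtm_step",
    "run_chains",
    "blfdr_from_summary",
]

PARAM_NAMES = ModelParams.names


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC protocol and initialization constants.

    The defaults reproduce the full study protocol: three chains of 325,000
    iterations, 25,000 burn-in, thinning interval 100, retaining 3 x 3,000 =
    9,000 pooled draws.  ``desk()`` returns a shorter profile for interactive
    work and testing.
    """

    n_chains: int = 3
    n_iter: int = 325_000
    burn_in: int = 25_000
    thin: int = 100
    pi0_init: float = 0.94
    beta_init: float = 0.1
    sigma0_sq_init: float = 1.0
    mtm_tries: int = 5
    mtm_scale_alpha: float = 0.1
    mtm_scale_gamma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1 or self.mtm_tries < 1 or self.n_chains < 1:
            raise ValueError("thin, mtm_tries and n_chains must be >= 1")
        if not 0 < self.pi0_init <= 1:
            raise ValueError("pi0_init must be in (0, 1]")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def paper(cls, **kw) -> "SamplerConfig":
        return cls(**kw)

    @classmethod
    def desk(cls, **kw) -> "SamplerConfig":
        """Short profile: 3 x 20,000 iterations, 5,000 burn-in, thin 10."""
        defaults = dict(n_iter=20_000, burn_in=5_000, thin=10)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class ChainState:
    """One MCMC state: parameters, latent indicators and their probabilities."""

    alpha: tuple[float, float]
    gamma: tuple[float, float]
    beta: float
    sigma0_sq: float
    w: np.ndarray
    p: np.ndarray

    def params(self) -> ModelParams:
        return ModelParams(self.alpha, self.gamma, self.beta, self.sigma0_sq)


class _Workspace:
    """Per-dataset precomputed arrays shared by all update steps."""

    def __init__(self, table: LinkStatsTable, hyper: HyperParams):
        self.t_f = table.t_f
        self.t_s = table.t_s
        self.m = table.m
        self.sup = table.t_f > hyper.mu1          # support of the alternative
        self.d = np.where(self.sup, self.t_f - hyper.mu1, 1.0)
        self.log_d = np.log(self.d)
        self.t_f_sq = self.t_f**2
        self.Sa_inv = np.linalg.inv(hyper.Sigma_alpha)
        self.Sg_inv = np.linalg.inv(hyper.Sigma_gamma)
        self.hyper = hyper
        # subset views over the alternative support (w can be 1 only there)
        self.t_s_sup = self.t_s[self.sup]
        self.t_f_sup = self.t_f[self.sup]
        self.t_f_sq_sup = self.t_f_sq[self.sup]
        self.d_sup = self.d[self.sup]
        self.log_d_sup = self.log_d[self.sup]
        self.n_sup = int(self.sup.sum())
        self.total_t_f_sq = float(self.t_f_sq.sum())


# ---------------------------------------------------------------------------
# initialization


def initialize(
    table: LinkStatsTable,
    config: SamplerConfig,
    hyper: HyperParams | None = None,
) -> ChainState:
    """Starting state: empirical-quantile threshold for w, logistic fit for gamma.

    The threshold lambda0 is the ``pi0_init`` empirical quantile of the
    absolute FC statistics (linear interpolation); links with t_f >= lambda0
    and t_f > mu1 start in the alternative component.  gamma starts at the
    maximum-likelihood logistic-regression coefficients of w0 on t_s, with a
    marginal-frequency fallback when the regression is degenerate.
    """
    hyper = hyper or HyperParams()
    if config.pi0_init >= 1.0:
        # degenerate prior guess: no link starts in the alternative component
        w0 = np.zeros(table.m, dtype=np.int8)
    else:
        lam0 = float(np.quantile(table.t_f, config.pi0_init))
        w0 = ((table.t_f >= lam0) & (table.t_f > hyper.mu1)).astype(np.int8)
    gamma0 = _init_gamma(w0, table.t_s)
    p0 = w0.astype(float)
    return ChainState(
        alpha=(0.0, 0.0),
        gamma=gamma0,
        beta=config.beta_init,
        sigma0_sq=config.sigma0_sq_init,
        w=w0,
        p=p0,
    )


def _init_gamma(w0: np.ndarray, t_s: np.ndarray) -> tuple[float, float]:
    frac = float(np.clip(np.mean(w0), 0.01, 0.99))
    fallback = (float(logit(frac)), 0.0)
    if w0.min() == w0.max():
        warnings.warn("degenerate initial w; using marginal-frequency gamma init")
        return fallback
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(w0, sm.add_constant(t_s)).fit(disp=0, maxiter=100)
        g = fit.params
        if not np.all(np.isfinite(g)):
            raise ValueError
        return (float(g[0]), float(g[1]))
    except Exception:
        warnings.warn("logistic initialization failed; using marginal-frequency fallback")
        return fallback


# ---------------------------------------------------------------------------
# conjugate updates


def update_beta(
    state: ChainState,
    table: LinkStatsTable,
    hyper: HyperParams,
    rng: np.random.Generator,
) -> float:
    """Draw the gamma rate from its Gamma full conditional.

    shape = a_beta + sum_{w_i=1} exp(alpha0 + alpha1 t_s,i),
    rate  = b_beta + sum_{w_i=1} (t_f,i - mu1).
    """
    alt = state.w == 1
    a0, a1 = state.alpha
    shape = hyper.a_beta + np.exp(a0 + a1 * table.t_s[alt]).sum()
    rate = hyper.b_beta + (table.t_f[alt] - hyper.mu1).sum()
    return float(rng.gamma(shape, 1.0 / rate))


def update_sigma0_sq(
    state: ChainState,
    table: LinkStatsTable,
    hyper: HyperParams,
    rng: np.random.Generator,
) -> float:
    """Draw the null scale from its Inverse-Gamma full conditional.

    shape = a_sigma + n0/2, scale = b_sigma + (1/2) sum_{w_i=0} t_f,i^2.
    """
    nul = state.w == 0
    shape = hyper.a_sigma + 0.5 * nul.sum()
    scale = hyper.b_sigma + 0.5 * (table.t_f[nul] ** 2).sum()
    return float(1.0 / rng.gamma(shape, 1.0 / scale))


# ---------------------------------------------------------------------------
# latent indicators


def _membership_prob(ws: _Workspace, alpha, gamma, beta, sigma0_sq) -> np.ndarray:
    """P(w_i = 1 | ...) per link; zero off the alternative support."""
    hyper = ws.hyper
    g0, g1 = gamma
    eta = g0 + g1 * ws.t_s
    # log pi1 - log pi0 = eta
    log_f0 = 0.5 * np.log(2.0 / (np.pi * sigma0_sq)) - ws.t_f_sq / (2.0 * sigma0_sq)
    a0, a1 = alpha
    shape = np.exp(np.minimum(a0 + a1 * ws.t_s, 500.0))
    log_beta = np.log(beta)
    log_f1 = shape * log_beta - gammaln(shape) + (shape - 1.0) * ws.log_d - beta * ws.d
    p = expit(eta + log_f1 - log_f0)
    p[~ws.sup] = 0.0
    return p


def update_latent(
    state: ChainState,
    table: LinkStatsTable,
    hyper: HyperParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Redraw membership indicators from their Bernoulli full conditional."""
    ws = _Workspace(table, hyper)
    p = _membership_prob(ws, state.alpha, state.gamma, state.beta, state.sigma0_sq)
    w = (rng.random(ws.m) < p).astype(np.int8)
    return w, p


# ---------------------------------------------------------------------------
# multiple-try Metropolis


def _mvt_perturb(rng: np.random.Generator, n: int, scale: float, nu: int) -> np.ndarray:
    """Symmetric multivariate-t(nu) perturbations, shape (n, 2)."""
    z = rng.standard_normal((n, 2))
    g = rng.chisquare(nu, (n, 1)) / nu
    return scale * z / np.sqrt(g)


def _logsumexp1d(lw: np.ndarray) -> float:
    mx = lw.max()
    if np.isneginf(mx):
        return -np.inf
    return float(mx + np.log(np.exp(lw - mx).sum()))


def mtm_step(
    x: np.ndarray,
    log_target,
    scale: float,
    rng: np.random.Generator,
    k: int = 5,
    nu: int = 4,
) -> tuple[np.ndarray, bool]:
    """One multiple-try Metropolis step with symmetric t proposals.

    Draws k candidates around x, selects one with probability proportional to
    its target density, draws k-1 reference points around the selection (the
    current point completes the reference set), and accepts with probability
    min(1, sum of candidate weights / sum of reference weights).  With k = 1
    this reduces to ordinary Metropolis.  ``log_target`` is evaluated on a
    batch of points, shape (n, 2) -> (n,); non-finite values get zero weight.
    """
    x = np.asarray(x, dtype=float)
    ys = x + _mvt_perturb(rng, k, scale, nu)
    lw_y = np.asarray(log_target(ys), dtype=float)
    lw_y[~np.isfinite(lw_y)] = -np.inf
    if np.all(np.isneginf(lw_y)):
        return x, False
    num = _logsumexp1d(lw_y)
    probs = np.exp(lw_y - num)
    cum = np.cumsum(probs)
    j = min(int(np.searchsorted(cum, rng.random() * cum[-1])), k - 1)
    y = ys[j]
    refs = y + _mvt_perturb(rng, k - 1, scale, nu) if k > 1 else np.empty((0, 2))
    lw_x = np.asarray(log_target(np.vstack([refs, x[None, :]])), dtype=float)
    lw_x[~np.isfinite(lw_x)] = -np.inf
    den = _logsumexp1d(lw_x)
    if np.log(rng.random()) < num - den:
        return y, True
    return x, False


def _alpha_log_target(ws: _Workspace, alt_t_s, alt_log_d, log_beta):
    """Batched unnormalized log conditional of the shape coefficients."""
    Sa_inv = ws.Sa_inv
    coef = log_beta + alt_log_d

    def log_target(a):
        a = np.atleast_2d(a)
        expo = np.minimum(a[:, 0:1] + np.outer(a[:, 1], alt_t_s), 500.0)
        lp = -0.5 * np.einsum("ni,ij,nj->n", a, Sa_inv, a)
        shape = np.exp(expo)
        out = lp + (shape * coef - gammaln(shape)).sum(axis=1)
        return out

    return log_target


def _gamma_log_target(ws: _Workspace, n1: float, s1: float):
    """Batched unnormalized log conditional of the logistic-prior coefficients."""
    Sg_inv = ws.Sg_inv
    t_s = ws.t_s

    def log_target(g):
        g = np.atleast_2d(g)
        eta = g[:, 0:1] + np.outer(g[:, 1], t_s)
        lp = -0.5 * np.einsum("ni,ij,nj->n", g, Sg_inv, g)
        return lp + g[:, 0] * n1 + g[:, 1] * s1 - np.logaddexp(0.0, eta).sum(axis=1)

    return log_target


def update_alpha_mtm(
    state: ChainState,
    table: LinkStatsTable,
    hyper: HyperParams,
    config: SamplerConfig,
    rng: np.random.Generator,
    scale: float | None = None,
) -> tuple[tuple[float, float], bool]:
    """One MTM step for the gamma-shape coefficients given w."""
    ws = _Workspace(table, hyper)
    alt = state.w == 1
    log_target = _alpha_log_target(ws, ws.t_s[alt], ws.log_d[alt], np.log(state.beta))
    x, acc = mtm_step(
        np.asarray(state.alpha),
        log_target,
        scale if scale is not None else config.mtm_scale_alpha,
        rng,
        k=config.mtm_tries,
        nu=hyper.nu,
    )
    return (float(x[0]), float(x[1])), acc


def update_gamma_mtm(
    state: ChainState,
    table: LinkStatsTable,
    hyper: HyperParams,
    config: SamplerConfig,
    rng: np.random.Generator,
    scale: float | None = None,
) -> tuple[tuple[float, float], bool]:
    """One MTM step for the logistic-prior coefficients given w."""
    ws = _Workspace(table, hyper)
    w = np.asarray(state.w)
    log_target = _gamma_log_target(ws, float(w.sum()), float((w * ws.t_s).sum()))
    x, acc = mtm_step(
        np.asarray(state.gamma),
        log_target,
        scale if scale is not None else config.mtm_scale_gamma,
        rng,
        k=config.mtm_tries,
        nu=hyper.nu,
    )
    return (float(x[0]), float(x[1])), acc


# ---------------------------------------------------------------------------
# chain driver


def _run_single_chain(
    table: LinkStatsTable,
    config: SamplerConfig,
    hyper: HyperParams,
    rng: np.random.Generator,
):
    ws = _Workspace(table, hyper)
    state = initialize(table, config, hyper)
    alpha = np.asarray(state.alpha, dtype=float)
    gamma = np.asarray(state.gamma, dtype=float)
    beta = state.beta
    sigma0_sq = state.sigma0_sq

    n_ret = config.n_retained_per_chain
    draws = np.empty((n_ret, 6))
    scale_a = config.mtm_scale_alpha
    scale_g = config.mtm_scale_gamma
    win_a = win_g = 0
    n_acc_a = n_acc_g = 0
    n_post = 0
    ADAPT_WINDOW, ADAPT_TARGET = 50, 0.3
    k, nu = config.mtm_tries, hyper.nu
    out = 0
    log_2pi = np.log(2.0 / np.pi)

    for it in range(config.n_iter):
        # latent indicators: Bernoulli full conditional on the support subset
        eta_sup = gamma[0] + gamma[1] * ws.t_s_sup
        log_f0_sup = 0.5 * (log_2pi - np.log(sigma0_sq)) - ws.t_f_sq_sup / (2.0 * sigma0_sq)
        shape_sup = np.exp(np.minimum(alpha[0] + alpha[1] * ws.t_s_sup, 500.0))
        log_f1_sup = (shape_sup * np.log(beta) - gammaln(shape_sup)
                      + (shape_sup - 1.0) * ws.log_d_sup - beta * ws.d_sup)
        p_sup = expit(eta_sup + log_f1_sup - log_f0_sup)
        w_sup = rng.random(ws.n_sup) < p_sup

        # alpha block
        log_target_a = _alpha_log_target(
            ws, ws.t_s_sup[w_sup], ws.log_d_sup[w_sup], np.log(beta)
        )
        alpha, a_ok = mtm_step(alpha, log_target_a, scale_a, rng, k=k, nu=nu)
        # gamma block (w is zero off the support, so subset sums suffice)
        n1 = float(w_sup.sum())
        s1 = float(ws.t_s_sup[w_sup].sum())
        log_target_g = _gamma_log_target(ws, n1, s1)
        gamma, g_ok = mtm_step(gamma, log_target_g, scale_g, rng, k=k, nu=nu)

        win_a += a_ok
        win_g += g_ok
        if it >= config.burn_in:
            n_acc_a += a_ok
            n_acc_g += g_ok
            n_post += 1
        elif (it + 1) % ADAPT_WINDOW == 0:
            # Robbins-Monro style scale adaptation, burn-in only
            scale_a = float(np.clip(scale_a * np.exp(win_a / ADAPT_WINDOW - ADAPT_TARGET), 1e-3, 10.0))
            scale_g = float(np.clip(scale_g * np.exp(win_g / ADAPT_WINDOW - ADAPT_TARGET), 1e-3, 10.0))
            win_a = win_g = 0

        # conjugate blocks
        shape_b = hyper.a_beta + np.exp(np.minimum(alpha[0] + alpha[1] * ws.t_s_sup[w_sup], 500.0)).sum()
        rate_b = hyper.b_beta + ws.d_sup[w_sup].sum()
        beta = rng.gamma(shape_b, 1.0 / rate_b)
        shape_s = hyper.a_sigma + 0.5 * (ws.m - n1)
        scale_s = hyper.b_sigma + 0.5 * (ws.total_t_f_sq - ws.t_f_sq_sup[w_sup].sum())
        sigma0_sq = 1.0 / rng.gamma(shape_s, 1.0 / scale_s)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and out < n_ret:
            draws[out] = (alpha[0], alpha[1], beta, gamma[0], gamma[1], sigma0_sq)
            out += 1

    acc_rates = {
        "alpha": n_acc_a / max(n_post, 1),
        "gamma": n_acc_g / max(n_post, 1),
    }
    return draws[:out], acc_rates, (scale_a, scale_g)


@dataclass
class PosteriorSummary:
    """Pooled posterior medians, 95% credible intervals and diagnostics."""

    table: pd.DataFrame          # index: parameter; cols: median, q2.5, q97.5, rhat, ess
    acceptance_rates: dict
    n_retained: int
    draws: np.ndarray            # (n_chains, n_retained_per_chain, 6)
    converged: bool

    def median_params(self) -> ModelParams:
        med = self.table["median"]
        return ModelParams.from_dict(med.to_dict())

    def draws_frame(self) -> pd.DataFrame:
        n_chains, n_ret, _ = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(-1, 6), columns=PARAM_NAMES)
        df.insert(0, "chain", np.repeat(np.arange(n_chains), n_ret))
        df.insert(1, "draw", np.tile(np.arange(n_ret), n_chains))
        return df

    def report(self) -> str:
        lines = [
            f"retained draws: {self.n_retained}",
            f"acceptance rates: alpha={self.acceptance_rates['alpha']:.3f}, "
            f"gamma={self.acceptance_rates['gamma']:.3f}",
            f"converged (all rhat <= 1.1): {self.converged}",
            self.table.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def run_chains(
    table: LinkStatsTable,
    config: SamplerConfig | None = None,
    hyper: HyperParams | None = None,
) -> PosteriorSummary:
    """Run independent chains and pool retained draws.

    Chains get distinct child seeds spawned from ``config.seed``; the whole
    procedure is reproducible bit-for-bit given the seed.  A warning (not an
    error) is emitted when any split-chain rhat exceeds 1.1.
    """
    config = config or SamplerConfig()
    hyper = hyper or HyperParams()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_draws, accs = [], []
    for ss in seeds:
        draws, acc, _ = _run_single_chain(table, config, hyper, np.random.default_rng(ss))
        all_draws.append(draws)
        accs.append(acc)
    draws = np.stack(all_draws)           # (chain, draw, param)
    pooled = draws.reshape(-1, 6)

    med = np.median(pooled, axis=0)
    lo = np.quantile(pooled, 0.025, axis=0)
    hi = np.quantile(pooled, 0.975, axis=0)
    post = {name: draws[:, :, i] for i, name in enumerate(PARAM_NAMES)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(az.convert_to_dataset(post))
        ess_ds = az.ess(az.convert_to_dataset(post))
    rhat = np.array([float(rhat_ds[name]) for name in PARAM_NAMES])
    ess = np.array([float(ess_ds[name]) for name in PARAM_NAMES])

    summary_tbl = pd.DataFrame(
        {"median": med, "q2.5": lo, "q97.5": hi, "rhat": rhat, "ess": ess},
        index=list(PARAM_NAMES),
    )
    acc_rates = {
        "alpha": float(np.mean([a["alpha"] for a in accs])),
        "gamma": float(np.mean([a["gamma"] for a in accs])),
    }
    converged = bool(np.all(np.nan_to_num(rhat, nan=1.0) <= 1.1))
    if not converged:
        warnings.warn("rhat > 1.1 for at least one parameter; chains may not have mixed")
    return PosteriorSummary(
        table=summary_tbl,
        acceptance_rates=acc_rates,
        n_retained=pooled.shape[0],
        draws=draws,
        converged=converged,
    )


def blfdr_from_summary(
    table: LinkStatsTable,
    summary: PosteriorSummary,
    hyper: HyperParams | None = None,
) -> np.ndarray:
    """Plug posterior medians into the posterior null-probability formula."""
    from .mixture import blfdr_posterior

    params = summary.median_params()
    return np.asarray(blfdr_posterior(table.t_f, table.t_s, params, hyper or HyperParams()))
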