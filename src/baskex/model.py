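"""Posterior inference for the EXNEX mixture model and the independent model.

The EXNEX (exchangeability--nonexchangeability) model for a basket trial with
binary endpoints treats the response count in basket ``k`` as
``Y_k ~ Binomial(n_k, p_k)`` with ``theta_k = logit(p_k)``.  Each basket is,
with prior probability ``pi_k``, *exchangeable* with the others — its log-odds
are drawn from a common normal distribution ``N(mu, sigma^2)`` (a Bayesian
hierarchical model, the EX component) — and otherwise *nonexchangeable*,
analysed with its own fixed normal prior ``N(m_k, nu_k^2)`` (the NEX
component).  Mixture membership is carried by latent indicators
``delta_k ~ Bernoulli(pi_k)``::

    theta_k = delta_k * M1_k + (1 - delta_k) * M2_k
    M1_k ~ N(mu, sigma^2)          mu ~ N(mu0, nu_mu^2),  sigma ~ half-normal
    M2_k ~ N(m_k, nu_k^2)

Inference is by Metropolis-within-Gibbs: random-walk updates on each
``theta_k`` and on ``log sigma``, and exact Gibbs draws for ``mu`` (normal
full conditional) and each ``delta_k`` (Bernoulli full conditional, the two
mixture components being structurally distinct).  The sampler is vectorised
over a leading *batch* axis so that thousands of simulated datasets can be
fitted in one pass — calibration and operating-characteristic studies rely on
this.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "BasketData",
    "ExnexConfig",
    "NexPrior",
    "MCMCSettings",
    "PosteriorResult",
    "BatchPosterior",
    "nex_prior_params",
    "fit_independent",
    "fit_exnex",
    "fit_independent_batch",
    "fit_exnex_batch",
    "exceedance",
]

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BasketData:
    """Observed response counts ``y`` and sample sizes ``n`` for K baskets."""

    y: np.ndarray
    n: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        y = np.atleast_1d(np.asarray(self.y, dtype=np.int64))
        n = np.atleast_1d(np.asarray(self.n, dtype=np.int64))
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "n", n)
        if y.shape != n.shape or y.ndim != 1 or y.size < 1:
            raise ValueError("y and n must be 1-D vectors of equal length >= 1")
        if np.any(n <= 0):
            raise ValueError("sample sizes must be positive")
        if np.any(y < 0) or np.any(y > n):
            raise ValueError("counts must satisfy 0 <= y[k] <= n[k]")
        if self.labels is not None and len(self.labels) != y.size:
            raise ValueError("labels length must match number of baskets")

    @property
    def K(self) -> int:
        return int(self.y.size)


@dataclass(frozen=True)
class NexPrior:
    """Basket-specific NEX prior: ``theta_k ~ N(m_k, v2_k)``."""

    m: np.ndarray
    v2: np.ndarray

    def __post_init__(self) -> None:
        m = np.atleast_1d(np.asarray(self.m, dtype=float))
        v2 = np.atleast_1d(np.asarray(self.v2, dtype=float))
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "v2", v2)
        if np.any(v2 <= 0):
            raise ValueError("NEX prior variances must be positive")


def nex_prior_params(rho: np.ndarray | float) -> NexPrior:
    """NEX prior parameters from a plausible response-rate guess ``rho``.

    ``m_k = logit(rho_k)`` and ``v2_k = 1/rho_k + 1/(1 - rho_k)``, the
    variance of the log-odds of a single Bernoulli observation at rate
    ``rho_k`` — a deliberately weak, basket-specific prior.
    """
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any(rho_arr <= 0.0) or np.any(rho_arr >= 1.0):
        raise ValueError("rho must lie strictly inside (0, 1)")
    m = np.log(rho_arr / (1.0 - rho_arr))
    v2 = 1.0 / rho_arr + 1.0 / (1.0 - rho_arr)
    return NexPrior(m=m, v2=v2)


@dataclass(frozen=True)
class ExnexConfig:
    """Prior hyperparameters of the EXNEX and independent analysis models.

    Parameters
    ----------
    q0, q1
        Null and target response rates, ``0 < q0 < q1 < 1``.
    pi
        Prior exchangeability probability per basket (scalar broadcasts).
    rho
        Plausible response rate fixing the NEX prior via
        :func:`nex_prior_params`.
    mu_prior_mean, mu_prior_sd
        Prior on the EX common mean ``mu``; the mean defaults to
        ``logit(q0)``.
    sigma_prior_scale
        Scale of the half-normal prior on the between-basket sd ``sigma``.
    indep_prior_mean, indep_prior_sd
        Prior on ``theta_k`` in the independent (stratified) analysis model;
        the mean defaults to ``logit(q0)``.
    """

    q0: float = 0.2
    q1: float = 0.4
    pi: np.ndarray | float = 0.5
    rho: np.ndarray | float = 0.3
    mu_prior_mean: float | None = None
    mu_prior_sd: float = 10.0
    sigma_prior_scale: float = 1.0
    indep_prior_mean: float | None = None
    indep_prior_sd: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.q0 < 1.0) or not (self.q0 < self.q1 < 1.0):
            raise ValueError("require 0 < q0 < q1 < 1")
        pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        if np.any(pi < 0.0) or np.any(pi > 1.0):
            raise ValueError("pi must lie in [0, 1]")
        rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if np.any(rho <= 0.0) or np.any(rho >= 1.0):
            raise ValueError("rho must lie strictly inside (0, 1)")
        if self.mu_prior_sd <= 0 or self.indep_prior_sd <= 0:
            raise ValueError("prior sds must be positive")
        if self.sigma_prior_scale <= 0:
            raise ValueError("sigma prior scale must be positive")

    # broadcast helpers -----------------------------------------------------
    def pi_vector(self, K: int) -> np.ndarray:
        return np.broadcast_to(np.atleast_1d(np.asarray(self.pi, float)), (K,)).copy()

    def rho_vector(self, K: int) -> np.ndarray:
        return np.broadcast_to(np.atleast_1d(np.asarray(self.rho, float)), (K,)).copy()

    def nex_prior(self, K: int) -> NexPrior:
        return nex_prior_params(self.rho_vector(K))

    @property
    def mu0(self) -> float:
        return float(logit(self.q0)) if self.mu_prior_mean is None else float(self.mu_prior_mean)

    @property
    def indep_mean(self) -> float:
        return float(logit(self.q0)) if self.indep_prior_mean is None else float(self.indep_prior_mean)


@dataclass(frozen=True)
class MCMCSettings:
    """Chain layout and seed for the Metropolis-within-Gibbs sampler."""

    n_chains: int = 4
    n_warmup: int = 2500
    n_samples: int = 2500
    seed: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_samples, self.thin) < 1:
            raise ValueError("chain counts, lengths and thin must be positive")

    @property
    def n_kept(self) -> int:
        return self.n_samples // self.thin


#: lighter chain layout used by default inside calibration / simulation loops,
#: where thousands of datasets are fitted and per-fit Monte Carlo error is
#: pooled over replicates.
SIM_MCMC = MCMCSettings(n_chains=2, n_warmup=750, n_samples=2500)


@dataclass
class PosteriorResult:
    """Posterior draws and summaries for one dataset.

    ``theta_draws`` is (draws, K) with chains concatenated chain-major;
    ``delta_draws``, ``mu_draws`` and ``sigma_draws`` are absent (``None``)
    for the independent model.
    """

    theta_draws: np.ndarray
    exceed_prob: np.ndarray
    post_mean: np.ndarray
    post_sd: np.ndarray
    q0: float
    delta_draws: np.ndarray | None = None
    mu_draws: np.ndarray | None = None
    sigma_draws: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def p_draws(self) -> np.ndarray:
        return expit(self.theta_draws)


@dataclass
class BatchPosterior:
    """Summaries for a batch of datasets fitted jointly (no draws stored)."""

    exceed_prob: np.ndarray  # (B, K)
    post_mean: np.ndarray
    post_sd: np.ndarray
    delta_mean: np.ndarray | None
    q0: float
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# exceedance
# ---------------------------------------------------------------------------


def exceedance(p_draws: np.ndarray, q0: float) -> np.ndarray:
    """Per-basket fraction of posterior draws strictly above ``q0``.

    This is the Monte Carlo estimate of ``P(p_k > q0 | data)``, the decision
    quantity compared against the calibrated cut-off.
    """
    p = np.asarray(p_draws, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    if p.size == 0:
        raise ValueError("empty draw matrix")
    return np.mean(p > q0, axis=0)


# ---------------------------------------------------------------------------
# core sampler
# ---------------------------------------------------------------------------

_ADAPT_TARGET = 0.44  # canonical optimum for componentwise random walks


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _run_sampler(
    y: np.ndarray,
    n: np.ndarray,
    *,
    mixture: bool,
    m_nex: np.ndarray,
    v2_nex: np.ndarray,
    pi: np.ndarray | None,
    mu0: float,
    nu_mu2: float,
    sigma_scale: float,
    q0: float,
    settings: MCMCSettings,
    keep_draws: bool,
) -> dict:
    """Vectorised Metropolis-within-Gibbs over a batch of datasets.

    ``y`` is (B, K); all chain state lives in (B, C, K) / (B, C) arrays so a
    whole calibration batch advances in lock-step.  Proposal scales adapt
    toward 44% acceptance during warmup and are frozen afterwards, so the
    kept draws target the exact posterior.
    """
    B, K = y.shape
    C = settings.n_chains
    rng = np.random.default_rng(np.random.SeedSequence(settings.seed))

    yb = y[:, None, :].astype(float)  # (B,1,K)
    nb = np.broadcast_to(np.asarray(n, float), (K,))[None, None, :]

    m_nex = np.broadcast_to(m_nex, (K,))[None, None, :]
    v2_nex = np.broadcast_to(v2_nex, (K,))[None, None, :]

    # initial state: overdispersed around the empirical log-odds
    p_hat = (y + 0.5) / (np.asarray(n, float) + 1.0)
    theta = logit(p_hat)[:, None, :] + 0.5 * rng.standard_normal((B, C, K))
    ll_cur = yb * theta - nb * _softplus(theta)

    if mixture:
        pi_b = np.broadcast_to(pi, (K,))[None, None, :]
        delta = (rng.random((B, C, K)) < pi_b).astype(float)
        mu = mu0 + 0.5 * rng.standard_normal((B, C))
        log_sig = np.log(0.5) + 0.2 * rng.standard_normal((B, C))
        with np.errstate(divide="ignore"):
            logit_pi = np.log(pi_b) - np.log1p(-pi_b)
        step_s = np.full((B, C), 0.6)
    else:
        delta = mu = log_sig = None

    step_t = np.full((B, C, K), 1.0)

    n_iter = settings.n_warmup + settings.n_samples
    kept = 0
    # accumulators
    exc_cnt = np.zeros((B, K))
    p_sum = np.zeros((B, K))
    p2_sum = np.zeros((B, K))
    d_sum = np.zeros((B, K)) if mixture else None
    # per-chain theta moments for a between/within-chain diagnostic
    t_sum = np.zeros((B, C, K))
    t2_sum = np.zeros((B, C, K))

    n_kept_total = settings.n_kept
    if keep_draws:
        theta_store = np.empty((n_kept_total, B, C, K))
        delta_store = np.empty((n_kept_total, B, C, K)) if mixture else None
        mu_store = np.empty((n_kept_total, B, C)) if mixture else None
        sig_store = np.empty((n_kept_total, B, C)) if mixture else None
    else:
        theta_store = delta_store = mu_store = sig_store = None

    t_logit_q0 = float(logit(q0))

    for it in range(n_iter):
        warm = it < settings.n_warmup
        if mixture:
            sig2 = np.exp(2.0 * log_sig)
            pm = np.where(delta == 1.0, mu[:, :, None], m_nex)
            pv = np.where(delta == 1.0, sig2[:, :, None], v2_nex)
        else:
            pm, pv = m_nex, v2_nex

        # --- theta: componentwise random walk ---------------------------
        prop = theta + step_t * rng.standard_normal((B, C, K))
        ll_prop = yb * prop - nb * _softplus(prop)
        log_acc = (ll_prop - ll_cur) - 0.5 * ((prop - pm) ** 2 - (theta - pm) ** 2) / pv
        acc = np.log(rng.random((B, C, K))) < log_acc
        theta = np.where(acc, prop, theta)
        ll_cur = np.where(acc, ll_prop, ll_cur)
        if warm:
            gamma = (it + 1.0) ** -0.6
            step_t *= np.exp(gamma * (acc - _ADAPT_TARGET))

        if mixture:
            # --- delta: exact Gibbs (Bernoulli full conditional) ---------
            lo = (
                logit_pi
                - 0.5 * (theta - mu[:, :, None]) ** 2 / sig2[:, :, None]
                - log_sig[:, :, None]
                + 0.5 * (theta - m_nex) ** 2 / v2_nex
                + 0.5 * np.log(v2_nex)
            )
            delta = (rng.random((B, C, K)) < expit(lo)).astype(float)
            # honour degenerate mixture weights exactly
            delta = np.where(pi_b == 0.0, 0.0, delta)
            delta = np.where(pi_b == 1.0, 1.0, delta)

            # --- mu: exact Gibbs (normal full conditional) ---------------
            n_ex = delta.sum(axis=2)
            s_ex = (delta * theta).sum(axis=2)
            prec = 1.0 / nu_mu2 + n_ex / sig2
            mean = (mu0 / nu_mu2 + s_ex / sig2) / prec
            mu = mean + rng.standard_normal((B, C)) / np.sqrt(prec)

            # --- log sigma: random walk ----------------------------------
            ss = (delta * (theta - mu[:, :, None]) ** 2).sum(axis=2)

            def _lt(z: np.ndarray) -> np.ndarray:
                s2 = np.exp(2.0 * z)
                return (
                    -s2 / (2.0 * sigma_scale**2)
                    + z
                    - n_ex * z
                    - 0.5 * ss / s2
                )

            zp = log_sig + step_s * rng.standard_normal((B, C))
            acc_s = np.log(rng.random((B, C))) < _lt(zp) - _lt(log_sig)
            log_sig = np.where(acc_s, zp, log_sig)
            if warm:
                step_s *= np.exp(gamma * (acc_s - _ADAPT_TARGET))

        # --- accumulate --------------------------------------------------
        if not warm and (it - settings.n_warmup) % settings.thin == 0:
            p = expit(theta)
            exc_cnt += (theta > t_logit_q0).sum(axis=1)
            p_sum += p.sum(axis=1)
            p2_sum += (p * p).sum(axis=1)
            t_sum += theta
            t2_sum += theta * theta
            if mixture:
                d_sum += delta.sum(axis=1)
            if keep_draws:
                theta_store[kept] = theta
                if mixture:
                    delta_store[kept] = delta
                    mu_store[kept] = mu
                    sig_store[kept] = np.exp(log_sig)
            kept += 1

    N = kept * C
    post_mean = p_sum / N
    post_sd = np.sqrt(np.maximum(p2_sum / N - post_mean**2, 0.0))
    out = {
        "exceed_prob": exc_cnt / N,
        "post_mean": post_mean,
        "post_sd": post_sd,
        "delta_mean": (d_sum / N) if mixture else None,
        "n_draws": N,
    }
    # between/within-chain ratio on theta (plain Gelman-Rubin, no splitting)
    if C > 1:
        cm = t_sum / kept
        cv = t2_sum / kept - cm**2
        W = cv.mean(axis=1)
        Bv = kept * cm.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rhat = np.sqrt(((kept - 1) / kept * W + Bv / kept) / W)
        out["rhat_theta"] = rhat
    if keep_draws:
        out["theta_store"] = theta_store
        out["delta_store"] = delta_store
        out["mu_store"] = mu_store
        out["sigma_store"] = sig_store
    return out


def _flatten(store: np.ndarray) -> np.ndarray:
    # (S, 1, C, ...) -> (C*S, ...), chain-major
    s = store[:, 0]
    return np.concatenate([s[:, c] for c in range(s.shape[1])], axis=0)


def _diagnostics_from_store(theta_store: np.ndarray, result: dict) -> dict:
    """Convergence summary from kept draws (single-dataset fits only)."""
    S, _, C, K = theta_store.shape
    diag: dict = {"warnings": []}
    rhat = result.get("rhat_theta")
    ess = np.empty(K)
    for k in range(K):
        ess[k] = _ess_1d(theta_store[:, 0, :, k].T)
    diag["ess_theta"] = ess
    if rhat is not None:
        diag["rhat_theta"] = rhat[0]
        if np.any(rhat[0] > 1.05):
            msg = f"R-hat above 1.05 for theta: {np.round(rhat[0], 3)}"
            diag["warnings"].append(msg)
            logger.warning(msg)
    if np.any(ess < 400):
        msg = f"effective sample size below 400 for theta: {np.round(ess, 1)}"
        diag["warnings"].append(msg)
        logger.warning(msg)
    return diag


def _ess_1d(x: np.ndarray) -> float:
    """Effective sample size of (chains, draws) via initial positive sequences."""
    C, S = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    nfft = 1 << (2 * S - 1).bit_length()
    f = np.fft.rfft(xc, n=nfft, axis=1)
    ac = np.fft.irfft(f * np.conj(f), n=nfft, axis=1)[:, :S].real
    ac /= ac[:, :1]
    rho = ac.mean(axis=0)
    # Geyer initial monotone positive sequence
    tau = 1.0
    t = 1
    while t + 1 < S:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(C * S / max(tau, 1.0))


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------


def fit_independent(
    data: BasketData, config: ExnexConfig, mcmc: MCMCSettings
) -> PosteriorResult:
    """Fit each basket independently: ``theta_k ~ N(indep_mean, indep_sd^2)``.

    No cross-basket terms; equivalent to K separate one-basket models run
    with a shared random stream.
    """
    res = _run_sampler(
        data.y[None, :],
        data.n,
        mixture=False,
        m_nex=np.full(data.K, config.indep_mean),
        v2_nex=np.full(data.K, config.indep_prior_sd**2),
        pi=None,
        mu0=0.0,
        nu_mu2=1.0,
        sigma_scale=1.0,
        q0=config.q0,
        settings=mcmc,
        keep_draws=True,
    )
    theta = _flatten(res["theta_store"])
    return PosteriorResult(
        theta_draws=theta,
        exceed_prob=res["exceed_prob"][0],
        post_mean=res["post_mean"][0],
        post_sd=res["post_sd"][0],
        q0=config.q0,
        diagnostics=_diagnostics_from_store(res["theta_store"], res),
    )


def fit_exnex(data: BasketData, config: ExnexConfig, mcmc: MCMCSettings) -> PosteriorResult:
    """Fit the full EXNEX mixture to one dataset, returning joint draws."""
    nex = config.nex_prior(data.K)
    res = _run_sampler(
        data.y[None, :],
        data.n,
        mixture=True,
        m_nex=nex.m,
        v2_nex=nex.v2,
        pi=config.pi_vector(data.K),
        mu0=config.mu0,
        nu_mu2=config.mu_prior_sd**2,
        sigma_scale=config.sigma_prior_scale,
        q0=config.q0,
        settings=mcmc,
        keep_draws=True,
    )
    theta = _flatten(res["theta_store"])
    return PosteriorResult(
        theta_draws=theta,
        exceed_prob=res["exceed_prob"][0],
        post_mean=res["post_mean"][0],
        post_sd=res["post_sd"][0],
        q0=config.q0,
        delta_draws=_flatten(res["delta_store"]),
        mu_draws=_flatten(res["mu_store"]),
        sigma_draws=_flatten(res["sigma_store"]),
        diagnostics=_diagnostics_from_store(res["theta_store"], res),
    )


def fit_exnex_batch(
    Y: np.ndarray, n: np.ndarray, config: ExnexConfig, mcmc: MCMCSettings
) -> BatchPosterior:
    """Fit the EXNEX model jointly to a (B, K) batch of simulated datasets."""
    Y = np.asarray(Y)
    if Y.ndim != 2 or Y.shape[0] < 1 or Y.shape[1] < 1:
        raise ValueError("Y must be a (B, K) matrix with B, K >= 1")
    K = Y.shape[1]
    nex = config.nex_prior(K)
    res = _run_sampler(
        Y,
        n,
        mixture=True,
        m_nex=nex.m,
        v2_nex=nex.v2,
        pi=config.pi_vector(K),
        mu0=config.mu0,
        nu_mu2=config.mu_prior_sd**2,
        sigma_scale=config.sigma_prior_scale,
        q0=config.q0,
        settings=mcmc,
        keep_draws=False,
    )
    return BatchPosterior(
        exceed_prob=res["exceed_prob"],
        post_mean=res["post_mean"],
        post_sd=res["post_sd"],
        delta_mean=res["delta_mean"],
        q0=config.q0,
        diagnostics={"max_rhat_theta": float(np.nanmax(res["rhat_theta"])) if "rhat_theta" in res else math.nan},
    )


def fit_independent_batch(
    Y: np.ndarray, n: np.ndarray, config: ExnexConfig, mcmc: MCMCSettings
) -> BatchPosterior:
    """Fit the independent model jointly to a (B, K) batch of datasets."""
    Y = np.asarray(Y)
    if Y.ndim != 2 or Y.shape[0] < 1 or Y.shape[1] < 1:
        raise ValueError("Y must be a (B, K) matrix with B, K >= 1")
    K = Y.shape[1]
    res = _run_sampler(
        Y,
        n,
        mixture=False,
        m_nex=np.full(K, config.indep_mean),
        v2_nex=np.full(K, config.indep_prior_sd**2),
        pi=None,
        mu0=0.0,
        nu_mu2=1.0,
        sigma_scale=1.0,
        q0=config.q0,
        settings=mcmc,
        keep_draws=False,
    )
    return BatchPosterior(
        exceed_prob=res["exceed_prob"],
        post_mean=res["post_mean"],
        post_sd=res["post_sd"],
        delta_mean=None,
        q0=config.q0,
        diagnostics={"max_rhat_theta": float(np.nanmax(res["rhat_theta"])) if "rhat_theta" in res else math.nan},
    )
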