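"""Brute-force quadrature oracles for posterior exceedance probabilities.

These are deliberately independent of the package's MCMC sampler: everything
is computed by dense-grid numerical integration of the unnormalised
posterior, so they can serve as ground truth for small problems (K <= 2,
modest n; the independent model for any single basket).
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.special import expit, logit
from scipy.stats import binom, norm


def _binom_lik(theta: np.ndarray, y: int, n: int) -> np.ndarray:
    return binom.pmf(y, n, expit(theta))


def indep_exceed(
    y: int,
    n: int,
    q0: float,
    prior_mean: float,
    prior_sd: float,
    grid: int = 40001,
    half_width: float = 30.0,
) -> float:
    """P(p > q0 | y) for theta ~ N(prior_mean, prior_sd^2), by 1-D quadrature.

    The grid is centred on the threshold ``logit(q0)`` so the tail mass is a
    clean sub-grid trapezoid integral.
    """
    t = float(logit(q0))
    theta = t + np.linspace(-half_width, half_width, grid)
    f = _binom_lik(theta, y, n) * norm.pdf(theta, prior_mean, prior_sd)
    total = np.trapezoid(f, theta)
    above = np.trapezoid(f[theta >= t], theta[theta >= t])
    return float(above / total)


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += dx / 2.0
    w[1:] += dx / 2.0
    return w


def exnex_exceed(
    y: np.ndarray,
    n: np.ndarray,
    q0: float,
    pi: np.ndarray,
    m_nex: np.ndarray,
    v2_nex: np.ndarray,
    mu0: float,
    nu_mu: float,
    sigma_scale: float = 1.0,
    n_theta: int = 1121,
    mu_chunk: int = 64,
) -> np.ndarray:
    """Exceedance probabilities under the full EXNEX mixture by nested
    quadrature, summing analytically over the 2^K membership configurations.

    For a configuration with EX set E and NEX set N the marginal factorises:
    each NEX basket is a 1-D integral over theta, the EX block is a
    (mu, sigma) double integral of a product of 1-D theta integrals.
    Configuration weights combine the Bernoulli prior mass with the
    per-configuration marginal likelihood.  The theta grid contains the
    decision threshold exactly and the tail integral gives that point the
    half trapezoid weight, so no mass is double counted at the boundary.
    """
    y = np.asarray(y, int)
    n = np.asarray(n, int)
    K = y.size
    t = float(logit(q0))

    theta = t + np.linspace(-14.0, 14.0, n_theta)
    w_full = _trapezoid_weights(theta)
    w_above = np.where(theta > t, w_full, 0.0)
    i_t = np.argmin(np.abs(theta - t))
    w_above[i_t] = w_full[i_t] / 2.0  # boundary point: half trapezoid weight

    # mu grid: dense where the likelihood lives, sparse tails out to ~4 prior sd
    mu = np.unique(
        np.concatenate(
            [
                np.linspace(-14.0, 14.0, 561),
                np.linspace(mu0 - 4.0 * nu_mu, -14.0, 60),
                np.linspace(14.0, mu0 + 4.0 * nu_mu, 60),
            ]
        )
    )
    sig = np.linspace(1e-4, 5.0 * sigma_scale, 240)

    lik = np.array([_binom_lik(theta, y[k], n[k]) for k in range(K)])  # (K, T)
    lik_w = lik * w_full
    lik_a = lik * w_above

    # NEX pieces per basket: normaliser and mass above the threshold
    Z_nex = np.empty(K)
    A_nex = np.empty(K)
    for k in range(K):
        dens = norm.pdf(theta, m_nex[k], np.sqrt(v2_nex[k]))
        Z_nex[k] = float(np.sum(lik_w[k] * dens))
        A_nex[k] = float(np.sum(lik_a[k] * dens))

    # EX pieces on the (mu, sigma) grid, chunked over mu to bound memory:
    # z[k, i, j] = int lik_k(theta) N(theta; mu_i, sig_j^2) dtheta
    I, J = mu.size, sig.size
    z = np.empty((K, I, J))
    a = np.empty((K, I, J))
    for lo in range(0, I, mu_chunk):
        hi = min(lo + mu_chunk, I)
        dens = norm.pdf(theta[None, None, :], mu[lo:hi, None, None], sig[None, :, None])
        z[:, lo:hi] = np.einsum("kt,ijt->kij", lik_w, dens)
        a[:, lo:hi] = np.einsum("kt,ijt->kij", lik_a, dens)

    prior_mu = norm.pdf(mu, mu0, nu_mu)  # (I,)
    # proper half-normal density: the factor 2 matters relative to the
    # all-NEX configuration, whose marginal carries no sigma integral
    prior_sig = 2.0 * norm.pdf(sig, 0.0, sigma_scale)

    num = np.zeros(K)
    den = 0.0
    for cfg in product([0, 1], repeat=K):
        cfg_arr = np.array(cfg)
        w_prior = float(np.prod(np.where(cfg_arr == 1, pi, 1.0 - pi)))
        if w_prior == 0.0:
            continue
        ex = np.where(cfg_arr == 1)[0]
        nx = np.where(cfg_arr == 0)[0]
        z_nx = float(np.prod(Z_nex[nx])) if nx.size else 1.0
        if ex.size:
            prod_z = np.prod(z[ex], axis=0)  # (I, J)
            joint = prior_mu[:, None] * prior_sig[None, :] * prod_z
            M = float(np.trapezoid(np.trapezoid(joint, sig, axis=1), mu))
        else:
            joint = None
            M = 1.0
        w = w_prior * z_nx * M
        den += w
        for k in range(K):
            if cfg[k] == 0:
                e_k = A_nex[k] / Z_nex[k]
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    ratio = np.where(z[k] > 0, a[k] / np.where(z[k] > 0, z[k], 1.0), 0.0)
                e_k = float(np.trapezoid(np.trapezoid(joint * ratio, sig, axis=1), mu)) / M
            num[k] += w * e_k
    return num / den
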