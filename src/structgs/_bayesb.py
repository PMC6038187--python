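"""Numba Gibbs-sampler kernel for the BayesB marker-effect model.

Each marker effect follows a point-mass/normal mixture: with probability pi
the marker has an effect beta_j ~ N(0, s2_j) with its own variance s2_j
drawn from a scaled-inverse-chi-square prior; otherwise the effect is
exactly zero.  Integrating beta_j out of the likelihood gives the Bernoulli
update for the inclusion indicator, after which beta_j and s2_j are drawn
from their conjugate conditionals.  The chain state is fully determined by
the seed passed to the kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def bayesb_gibbs(
    X: np.ndarray,
    y: np.ndarray,
    pi: float,
    n_iter: int,
    burn_in: int,
    thin: int,
    nu_b: float,
    s_b: float,
    nu_e: float,
    s_e: float,
    seed: int,
):
    """Run the chain; returns (mean_effects, inclusion_freq, mean_mu, mean_sigma2_e, n_kept)."""
    np.random.seed(seed)
    n, m = X.shape
    xsq = np.zeros(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xsq[j] = s

    mu = y.mean()
    beta = np.zeros(m)
    incl = np.zeros(m, dtype=np.bool_)
    s2 = np.full(m, s_b)
    e = y - mu
    sigma2_e = max(e.var(), 1e-8)

    sum_beta = np.zeros(m)
    sum_incl = np.zeros(m)
    sum_mu = 0.0
    sum_se = 0.0
    n_kept = 0
    log_prior_odds = np.log(pi / (1.0 - pi)) if pi < 1.0 else np.inf

    for it in range(n_iter):
        # intercept
        e += mu
        mu = e.mean() + np.random.normal() * np.sqrt(sigma2_e / n)
        e -= mu

        for j in range(m):
            if incl[j]:
                bj = beta[j]
                for i in range(n):
                    e[i] += X[i, j] * bj
            rhs = 0.0
            for i in range(n):
                rhs += X[i, j] * e[i]
            cc = xsq[j]
            v1 = cc * s2[j] + sigma2_e
            if pi >= 1.0:
                take = True
            else:
                log_odds = log_prior_odds + 0.5 * (np.log(sigma2_e / v1) + rhs * rhs * s2[j] / (sigma2_e * v1))
                # numerically safe Bernoulli draw on the logit scale
                if log_odds > 35.0:
                    take = True
                elif log_odds < -35.0:
                    take = False
                else:
                    p1 = 1.0 / (1.0 + np.exp(-log_odds))
                    take = np.random.random() < p1
            if take:
                prec = cc + sigma2_e / s2[j]
                mean = rhs / prec
                bj = mean + np.random.normal() * np.sqrt(sigma2_e / prec)
                beta[j] = bj
                incl[j] = True
                for i in range(n):
                    e[i] -= X[i, j] * bj
            else:
                beta[j] = 0.0
                incl[j] = False
            # per-marker variance from its scaled-inverse-chi-square conditional
            if incl[j]:
                s2[j] = (nu_b * s_b + beta[j] * beta[j]) / np.random.chisquare(nu_b + 1.0)
            else:
                s2[j] = nu_b * s_b / np.random.chisquare(nu_b)
            if not np.isfinite(s2[j]) or s2[j] <= 0.0:
                s2[j] = s_b

        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma2_e = (nu_e * s_e + sse) / np.random.chisquare(nu_e + n)
        if not np.isfinite(sigma2_e) or sigma2_e <= 0.0:
            raise ValueError("BayesB chain diverged (non-finite residual variance)")

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(m):
                if incl[j]:
                    sum_beta[j] += beta[j]
                    sum_incl[j] += 1.0
            sum_mu += mu
            sum_se += sigma2_e
            n_kept += 1

    return sum_beta / n_kept, sum_incl / n_kept, sum_mu / n_kept, sum_se / n_kept, n_kept
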