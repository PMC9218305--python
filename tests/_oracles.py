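"""Independent numerical oracles used to check the samplers.

These deliberately avoid the package's own code paths: marginal prevalence
via adaptive quadrature of the logit-normal mixture, and the two-level
posterior via dense grid integration with Gauss-Hermite marginalisation of
the cluster effects.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.special import expit, logsumexp


def logit_normal_prevalence(beta0: float, total_var: float) -> float:
    """E[expit(beta0 + u)], u ~ N(0, total_var), by adaptive quadrature."""
    if total_var == 0:
        return float(expit(beta0))
    sd = np.sqrt(total_var)
    f = lambda u: expit(beta0 + u) * np.exp(-0.5 * (u / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    val, _ = quad(f, -12 * sd, 12 * sd, limit=200)
    return float(val)


def two_level_posterior_means(
    y: np.ndarray,
    n: np.ndarray,
    prior_shape: float = 0.001,
    prior_rate: float = 0.001,
    n_beta: int = 501,
    n_sigma: int = 601,
    n_nodes: int = 81,
    beta_range: tuple[float, float] = (-4.0, 4.0),
    log_s2_range: tuple[float, float] = (np.log(1e-4), np.log(300.0)),
) -> tuple[float, float]:
    """Posterior means of (beta0, sigma2) for the random-intercept model.

    Model: y_j ~ Binomial(n_j, expit(beta0 + c_j)), c_j ~ N(0, sigma2),
    flat prior on beta0, inverse-gamma(prior_shape, prior_rate) on sigma2.
    Cluster effects are integrated out with Gauss-Hermite quadrature; the
    (beta0, log sigma2) posterior is evaluated on a dense grid.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(weights) - 0.5 * np.log(np.pi)

    beta = np.linspace(*beta_range, n_beta)
    ls2 = np.linspace(*log_s2_range, n_sigma)
    s2 = np.exp(ls2)
    sd = np.sqrt(s2)

    # chunk the sigma axis to keep the 3-d temporaries small
    ll = np.zeros((n_beta, n_sigma))
    chunk = max(1, 4_000_000 // (n_beta * n_nodes))
    for lo in range(0, n_sigma, chunk):
        hi = min(lo + chunk, n_sigma)
        # eta[b, s, q] = beta_b + sqrt(2) * sd_s * node_q
        eta = beta[:, None, None] + np.sqrt(2.0) * sd[None, lo:hi, None] * nodes[None, None, :]
        log_p = -np.logaddexp(0.0, -eta)  # log expit
        log_q = -np.logaddexp(0.0, eta)  # log (1 - expit)
        for yj, nj in zip(y, n):
            ll[:, lo:hi] += logsumexp(yj * log_p + (nj - yj) * log_q + logw, axis=2)

    # IG prior density on sigma2 plus the Jacobian of the log grid
    log_post = ll - (prior_shape + 1.0) * ls2 - prior_rate / s2 + ls2
    log_post -= log_post.max()
    post = np.exp(log_post)
    z = post.sum()
    beta_mean = float((post.sum(axis=1) * beta).sum() / z)
    s2_mean = float((post.sum(axis=0) * s2).sum() / z)
    return beta_mean, s2_mean
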