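"""Exact Pólya-Gamma random variate generation.

The Gibbs sampler for the multilevel logistic model augments every Bernoulli
observation with a latent omega ~ PG(1, psi), where psi is the observation's
linear predictor.  Conditional on omega the logistic likelihood is Gaussian in
the random effects, which makes every full conditional conjugate.

This module implements the exact alternating-series rejection sampler for
PG(1, z) (Devroye's method for the Jacobi-type J*(1, z) density, with
PG(1, z) = J*(1, z/2) / 4) and a grouped helper that returns, for each group,
the sum of b independent PG(1, z) draws — i.e. one PG(b, z) variate.  All
kernels are numba-compiled and draw from a caller-supplied
``numpy.random.Generator`` so runs are reproducible and independent of global
RNG state.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["pg_draw", "pg_sum_grouped", "pg_mean", "pg_var"]

# Truncation point of the dual series representation; 0.64 balances the two
# proposal branches (truncated inverse-Gaussian below, exponential above).
_TRUNC = 0.64


@njit(cache=True, inline="always")
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True, inline="always")
def _coef(n, x):
    # n-th alternating-series coefficient a_n(x) of the J*(1, .) density,
    # using the left (x <= t) or right (x > t) expansion.
    h = n + 0.5
    if x > _TRUNC:
        return math.pi * h * math.exp(-h * h * math.pi * math.pi * x / 2.0)
    return (
        math.pi
        * h
        * math.pow(2.0 / (math.pi * x), 1.5)
        * math.exp(-2.0 * h * h / x)
    )


@njit(cache=True)
def _rtigauss(z, gen):
    # Inverse-Gaussian(mu = 1/z, lambda = 1) truncated to (0, t].
    t = _TRUNC
    x = t + 1.0
    if z < 1.0 / t:  # mu > t: rejection from the scaled chi^2 tail
        alpha = 0.0
        while gen.random() > alpha:
            e1 = gen.standard_exponential()
            e2 = gen.standard_exponential()
            while e1 * e1 > 2.0 * e2 / t:
                e1 = gen.standard_exponential()
                e2 = gen.standard_exponential()
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = gen.standard_normal()
            y = y * y
            half = mu * 0.5
            mu_y = mu * y
            x = mu + half * mu * y - half * math.sqrt(4.0 * mu * y + mu_y * mu_y)
            if gen.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _pg1(z, gen):
    # One exact PG(1, z) draw.
    zh = abs(z) * 0.5
    fz = math.pi * math.pi / 8.0 + zh * zh / 2.0
    t = _TRUNC

    # Mass of the exponential (right-tail) proposal branch.
    b = math.sqrt(1.0 / t) * (t * zh - 1.0)
    a = -math.sqrt(1.0 / t) * (t * zh + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - zh + math.log(_norm_cdf(b))
    xa = x0 + zh + math.log(_norm_cdf(a))
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    p_right = 1.0 / (1.0 + qdivp)

    while True:
        if gen.random() < p_right:
            x = t + gen.standard_exponential() / fz
        else:
            x = _rtigauss(zh, gen)
        # Squeeze by partial alternating sums of the series density.
        s = _coef(0, x)
        y = gen.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _coef(n, x)
                if y <= s:
                    return x * 0.25
            else:
                s += _coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def pg_draw(z, gen):
    """Draw one PG(1, z[i]) variate for every element of ``z``."""
    out = np.empty(z.shape[0])
    for i in range(z.shape[0]):
        out[i] = _pg1(z[i], gen)
    return out


@njit(cache=True)
def pg_sum_grouped(counts, z, gen):
    """For each group i, the sum of ``counts[i]`` iid PG(1, z[i]) draws.

    This is an exact PG(counts[i], z[i]) variate — the augmented precision
    contributed by a group of Bernoulli observations sharing one linear
    predictor (e.g. the children of one small area).
    """
    out = np.empty(z.shape[0])
    for i in range(z.shape[0]):
        acc = 0.0
        for _ in range(counts[i]):
            acc += _pg1(z[i], gen)
        out[i] = acc
    return out


def pg_mean(b: float, z: float) -> float:
    """E[PG(b, z)] = b/(2z) * tanh(z/2); the z -> 0 limit is b/4."""
    if z == 0.0:
        return b / 4.0
    return b / (2.0 * z) * math.tanh(z / 2.0)


def pg_var(b: float, z: float) -> float:
    """Var[PG(b, z)] = b/(4 z^3) * (sinh(z) - z) / cosh^2(z/2); limit b/24."""
    if z == 0.0:
        return b / 24.0
    return b / (4.0 * z**3) * (math.sinh(z) - z) / math.cosh(z / 2.0) ** 2
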