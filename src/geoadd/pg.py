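"""Exact Pólya-Gamma PG(1, c) sampling.

The logistic likelihood becomes conditionally Gaussian once each observation
is augmented with a latent omega_i ~ PG(1, eta_i); this module provides exact
draws of that variate via the Devroye alternating-series rejection sampler
for the Jacobi J*(1, z) distribution, using PG(1, c) = J*(1, c/2) / 4.

The scalar kernel is numba-compiled; seeding happens inside the compiled
function so a (values, seed) pair is fully deterministic.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["random_polya_gamma", "pg_mean"]

# Truncation point t* separating the inverse-Gaussian and exponential pieces
# of the proposal; 0.64 is the standard near-optimal choice.
_TRUNC = 0.64


def pg_mean(c: float | np.ndarray) -> float | np.ndarray:
    """Closed-form mean of PG(1, c): tanh(c/2)/(2c), with limit 1/4 at c=0."""
    c = np.asarray(c, dtype=float)
    out = np.full(c.shape, 0.25)
    nz = np.abs(c) > 1e-12
    out[nz] = np.tanh(c[nz] / 2.0) / (2.0 * c[nz])
    if out.ndim == 0:
        return float(out)
    return out


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _a_coef(n, x):
    # Alternating-series coefficients a_n(x) of the J*(1, z) density.
    np5 = n + 0.5
    if x > _TRUNC:
        return math.pi * np5 * math.exp(-0.5 * np5 * np5 * math.pi * math.pi * x)
    return (
        math.pi
        * np5
        * (2.0 / (math.pi * x)) ** 1.5
        * math.exp(-2.0 * np5 * np5 / x)
    )


@njit(cache=True)
def _mass_texpon(z):
    # Probability that the proposal draws from the exponential tail (x > t*).
    t = _TRUNC
    k = 0.125 * math.pi * math.pi + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(k) + k * t
    xb = x0 - z + math.log(_norm_cdf(b))
    xa = x0 + z + math.log(_norm_cdf(a))
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z, t):
    # Inverse-Gaussian IG(1/z, 1) truncated to (0, t].
    x = t + 1.0
    if z == 0.0 or t < 1.0 / z:
        # mu > t (includes z == 0): one-sided rejection from the Levy tail.
        alpha = 0.0
        while np.random.random() > alpha:
            e1 = -math.log(np.random.random())
            e2 = -math.log(np.random.random())
            while e1 * e1 > 2.0 * e2 / t:
                e1 = -math.log(np.random.random())
                e2 = -math.log(np.random.random())
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.standard_normal()
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _jstar_draw(z):
    # One draw from J*(1, z), z >= 0 (Devroye's alternating-series method).
    t = _TRUNC
    k = 0.125 * math.pi * math.pi + 0.5 * z * z
    p_exp = _mass_texpon(z)
    while True:
        if np.random.random() < p_exp:
            x = t - math.log(np.random.random()) / k
        else:
            x = _rtigauss(z, t)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def _pg1_array(c, seed):
    np.random.seed(seed)
    out = np.empty(c.shape[0])
    for i in range(c.shape[0]):
        out[i] = 0.25 * _jstar_draw(0.5 * abs(c[i]))
    return out


def random_polya_gamma(c, seed: int) -> np.ndarray:
    """Draw one PG(1, c_i) variate per element of ``c``.

    Parameters
    ----------
    c : array_like
        Tilting parameters (the linear predictor values); sign is irrelevant
        since PG(1, c) is symmetric in c.
    seed : int
        Seed in [0, 2**32); identical (c, seed) pairs give identical output.
    """
    c = np.ascontiguousarray(np.asarray(c, dtype=float).ravel())
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite tilting parameter passed to PG sampler")
    return _pg1_array(c, int(seed) % (2**32 - 1))
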