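"""Exact Pólya–Gamma PG(1, psi) sampling.

The PG(1, psi) auxiliary variable makes a Bernoulli-logistic likelihood
conditionally Gaussian: with omega ~ PG(1, psi) the logistic kernel
exp(psi*x) / (1 + exp(psi)) equals a Gaussian kernel in psi once omega is
conditioned on, which is what turns the binary-block updates of the MINDS
Gibbs sweep into ordinary Bayesian linear regressions.

Sampling uses the alternating-series rejection sampler of Devroye for the
Jacobi-type variable J*(1, z), with PG(1, psi) = J*(1, |psi|/2) / 4.  The
inner loop is numba-compiled; draws are driven by a ``numpy.random.Generator``
so the whole chain is reproducible from a single seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["sample_pg", "pg_mean"]

_TRUNC = 0.64  # series switch point t of the Devroye sampler
_HALF_PI2 = math.pi * math.pi / 8.0


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _mass_texpon(z):
    """P(chosen piece is the exponential right tail) for parameter z."""
    t = _TRUNC
    fz = _HALF_PI2 + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + math.log(_norm_cdf(b))
    xa = x0 + z + math.log(_norm_cdf(a))
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(rg, z):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, _TRUNC)."""
    t = _TRUNC
    x = t + 1.0
    if 1.0 / z > t:  # mu large: rejection from truncated inverse-chi-square
        while True:
            e1 = rg.exponential(1.0)
            e2 = rg.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / t:
                e1 = rg.exponential(1.0)
                e2 = rg.exponential(1.0)
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if rg.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while x > t:
            y = rg.normal()
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if rg.random() > mu / (mu + x):
                x = mu * mu / x
        return x


@njit(cache=True)
def _a_coef(n, x):
    """n-th coefficient of Devroye's alternating series at x."""
    t = _TRUNC
    np5 = n + 0.5
    if x <= t:
        return (
            math.pi
            * np5
            * math.pow(2.0 / math.pi / x, 1.5)
            * math.exp(-2.0 * np5 * np5 / x)
        )
    return math.pi * np5 * math.exp(-np5 * np5 * math.pi * math.pi * x / 2.0)


@njit(cache=True)
def _sample_jstar(rg, z):
    """One draw of J*(1, z), z >= 0 (Devroye alternating-series sampler)."""
    z = abs(z)
    fz = _HALF_PI2 + 0.5 * z * z
    p_right = _mass_texpon(z)
    while True:
        if rg.random() < p_right:
            x = _TRUNC + rg.exponential(1.0) / fz
        else:
            x = _rtigauss(rg, z) if z > 0.0 else _rtigauss_z0(rg)
        s = _a_coef(0, x)
        y = rg.random() * s
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
                    break  # reject, draw a fresh proposal


@njit(cache=True)
def _rtigauss_z0(rg):
    """Levy(0,1) (the z=0 limit of the inverse Gaussian) truncated to (0, t)."""
    t = _TRUNC
    while True:
        e1 = rg.exponential(1.0)
        e2 = rg.exponential(1.0)
        while e1 * e1 > 2.0 * e2 / t:
            e1 = rg.exponential(1.0)
            e2 = rg.exponential(1.0)
        x = t / ((1.0 + t * e1) * (1.0 + t * e1))
        if rg.random() <= 1.0:  # acceptance probability exp(0) at z=0
            return x


@njit(cache=True)
def _sample_pg_flat(rg, psi_flat, out):
    for i in range(psi_flat.shape[0]):
        out[i] = 0.25 * _sample_jstar(rg, 0.5 * abs(psi_flat[i]))


def sample_pg(psi, rng):
    """Draw PG(1, psi) variates, one per element of ``psi``.

    Parameters
    ----------
    psi : float or array_like
        Tilting parameter(s); the draw only depends on ``|psi|``.
    rng : numpy.random.Generator
        Source of randomness (shared with the surrounding Gibbs sweep).

    Returns
    -------
    numpy.ndarray or float
        Strictly positive draws with E[omega] = tanh(psi/2) / (2 psi).
    """
    arr = np.asarray(psi, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("sample_pg: psi must be finite")
    flat = np.ascontiguousarray(arr.reshape(-1))
    out = np.empty_like(flat)
    _sample_pg_flat(rng, flat, out)
    if arr.ndim == 0:
        return float(out[0])
    return out.reshape(arr.shape)


def pg_mean(psi):
    """Closed-form mean of PG(1, psi): tanh(psi/2)/(2 psi), 1/4 at psi=0."""
    arr = np.asarray(psi, dtype=np.float64)
    out = np.full(arr.shape, 0.25)
    nz = np.abs(arr) > 1e-12
    out[nz] = np.tanh(arr[nz] / 2.0) / (2.0 * arr[nz])
    if arr.ndim == 0:
        return float(out if not nz.ndim else out[()])
    return out
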