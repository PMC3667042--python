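"""Dispersal-survival kernels.

The colonization weight between two patches is the probability that a
disperser travels at least the inter-patch distance D.  The primary kernel is
the survival transformation of the log-sech dispersal kernel, a heavy-tailed
distance distribution fitted to forest-bird movement data:

    f(D) = 1 - (2/pi) * arctan((D / alpha)**(1/beta))

where ``alpha_km`` is the median dispersal distance (f(alpha) = 1/2 for every
shape) and ``beta`` a dimensionless shape parameter controlling tail weight.
Any one-argument survival function with f(0) = 1, nonincreasing in D, can be
substituted; a negative-exponential kernel exp(-D/alpha) is provided for
comparison with the classical incidence-function form.

The shipped defaults (alpha_km = 1.0, beta = 0.5) are placeholders for unit
tests and demonstrations, not fitted values; assessment runs must set kernel
parameters explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelParams",
    "LogSechKernel",
    "NegExpKernel",
    "survival_kernel",
    "log_sech_pdf",
    "make_kernel",
]

DEFAULT_ALPHA_KM = 1.0
DEFAULT_BETA = 0.5


def _check_distances(D):
    D = np.asarray(D, dtype=float)
    if (D < 0).any():
        raise ValueError("distances must be nonnegative")
    return D


@dataclass(frozen=True)
class LogSechKernel:
    """Survival transformation of the log-sech dispersal kernel.

    Parameters
    ----------
    alpha_km
        Median dispersal distance in km (> 0).
    beta
        Dimensionless shape (> 0); small beta approaches a step function at
        ``alpha_km``, large beta fattens both tails of log-distance.
    """

    alpha_km: float = DEFAULT_ALPHA_KM
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if not self.alpha_km > 0:
            raise ValueError("alpha_km must be positive")
        if not self.beta > 0:
            raise ValueError("beta must be positive")

    def __call__(self, D):
        """Probability of dispersing at least distance D (km); vectorized."""
        D = _check_distances(D)
        return 1.0 - (2.0 / np.pi) * np.arctan((D / self.alpha_km) ** (1.0 / self.beta))


#: Canonical parameter container for the log-sech survival kernel.
KernelParams = LogSechKernel


@dataclass(frozen=True)
class NegExpKernel:
    """Negative-exponential survival kernel exp(-D / alpha_km).

    The classical incidence-function connectivity weight; ``alpha_km`` is the
    mean (not median) dispersal distance.  Provided for comparison runs.
    """

    alpha_km: float = DEFAULT_ALPHA_KM

    def __post_init__(self) -> None:
        if not self.alpha_km > 0:
            raise ValueError("alpha_km must be positive")

    def __call__(self, D):
        D = _check_distances(D)
        return np.exp(-D / self.alpha_km)


def survival_kernel(D, params: LogSechKernel):
    """Evaluate the log-sech survival function f(D); vectorized over D."""
    return params(D)


def log_sech_pdf(d, params: LogSechKernel):
    """Probability density of the log-sech dispersal-distance distribution.

    Differentiating the cumulative 1 - f(D) gives, with u = ln(d/alpha)/beta,

        p(d) = sech(u) / (pi * beta * d),   d > 0,

    i.e. log-distance follows a hyperbolic-secant law centered at ln(alpha).
    Used as the quadrature oracle for the survival function.
    """
    d = np.asarray(d, dtype=float)
    u = np.log(d / params.alpha_km) / params.beta
    return 1.0 / (np.pi * params.beta * d * np.cosh(u))


def make_kernel(family: str = "logsech", alpha_km: float = DEFAULT_ALPHA_KM, beta: float = DEFAULT_BETA):
    """Build a survival kernel from config keys (family, alpha_km, beta)."""
    if family == "logsech":
        return LogSechKernel(alpha_km=alpha_km, beta=beta)
    if family == "negexp":
        return NegExpKernel(alpha_km=alpha_km)
    raise ValueError(f"unknown kernel family {family!r} (expected 'logsech' or 'negexp')")
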