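"""Discrete power-law fits for avalanche size and duration samples.

Model: P(X = x) = x^(-alpha) / zeta(alpha, xmin) for integer x >= xmin,
where zeta is the Hurwitz zeta function.  The exponent is estimated by
maximum likelihood (Clauset-style discrete MLE); the closed-form
approximation ``alpha ~ 1 + n / sum(ln(x_i / (xmin - 0.5)))`` serves as the
optimiser's initial bracket.  Goodness of fit is summarised by the
Kolmogorov-Smirnov distance between the empirical and fitted tail CDFs, and
an optional KS scan selects xmin.

Exponents are stored positive; reports render them with the conventional
negative sign (a fitted slope of "-1.52" is ``alpha = 1.52``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "PowerLawFit",
    "DegenerateFitError",
    "mle_alpha_discrete",
    "approx_alpha",
    "log_likelihood",
    "ks_distance",
    "select_xmin",
    "fit_sizes",
]

ALPHA_MAX = 20.0


class DegenerateFitError(ValueError):
    """The sample cannot constrain the exponent (e.g. all values equal)."""


@dataclass
class PowerLawFit:
    """MLE fit of a discrete power law to a tail sample."""

    alpha: float  # stored positive
    xmin: int
    sigma: float  # standard error of alpha
    D: float  # KS distance over the tail support
    n_tail: int

    @property
    def alpha_signed(self) -> float:
        """The exponent with the reporting sign convention (negative)."""
        return -self.alpha


def _tail(samples, xmin: int) -> np.ndarray:
    x = np.asarray(samples)
    if x.size and (np.any(x < 1) or np.any(x != np.floor(x))):
        raise ValueError("samples must be integers >= 1")
    return x[x >= xmin].astype(np.int64)


def approx_alpha(samples, xmin: int = 1) -> float:
    """Closed-form approximation ``1 + n / sum(ln(x / (xmin - 0.5)))``.

    Exact for the continuous model; for the discrete model it is a good
    initialiser and a small-n oracle.
    """
    x = _tail(samples, xmin)
    s = float(np.sum(np.log(x / (xmin - 0.5))))
    if s <= 0:
        raise DegenerateFitError("all samples equal xmin")
    return 1.0 + x.size / s


def log_likelihood(samples, alpha: float, xmin: int = 1) -> float:
    """Discrete power-law log-likelihood of the tail sample at ``alpha``."""
    x = _tail(samples, xmin)
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    return float(
        -alpha * np.sum(np.log(x))
        - x.size * np.log(special.zeta(alpha, xmin))
    )


def mle_alpha_discrete(samples, xmin: int = 1) -> tuple[float, float]:
    """Maximum-likelihood exponent of the zeta-normalised discrete model.

    Returns ``(alpha, sigma)`` with ``sigma = (alpha - 1) / sqrt(n_tail)``.
    The likelihood is unimodal in alpha; the optimum is found by bounded
    scalar minimisation seeded near the closed-form approximation.
    """
    x = _tail(samples, xmin)
    if x.size < 2:
        raise ValueError("need at least two samples >= xmin")
    if np.all(x == x[0]):
        raise DegenerateFitError("all tail samples identical")
    sum_log = float(np.sum(np.log(x)))

    def nll(alpha: float) -> float:
        return alpha * sum_log + x.size * np.log(special.zeta(alpha, xmin))

    res = optimize.minimize_scalar(
        nll,
        bounds=(1.0 + 1e-9, ALPHA_MAX),
        method="bounded",
        options={"xatol": 1e-10},
    )
    alpha = float(res.x)
    sigma = (alpha - 1.0) / np.sqrt(x.size)
    return alpha, float(sigma)


def _fitted_cdf(xs: np.ndarray, alpha: float, xmin: int) -> np.ndarray:
    """P(X <= x) of the discrete power law, vectorised over integer xs."""
    z = special.zeta(alpha, xmin)
    return 1.0 - special.zeta(alpha, xs + 1.0) / z


def ks_distance(samples, alpha: float, xmin: int = 1) -> float:
    """Max |empirical CDF - fitted CDF| over the observed tail support.

    For a discrete step/step comparison the supremum occurs at an observed
    value or immediately before the next one; both are checked.
    """
    x = _tail(samples, xmin)
    if x.size == 0:
        raise ValueError("no samples >= xmin")
    vals, counts = np.unique(x, return_counts=True)
    ecdf = np.cumsum(counts) / x.size
    model = _fitted_cdf(vals.astype(float), alpha, xmin)
    d_at = np.max(np.abs(ecdf - model))
    # just below each observed value: empirical CDF is the previous step
    model_before = _fitted_cdf(vals.astype(float) - 1.0, alpha, xmin)
    ecdf_prev = np.concatenate(([0.0], ecdf[:-1]))
    d_before = np.max(np.abs(ecdf_prev - model_before))
    return float(max(d_at, d_before))


def fit_sizes(samples, xmin: int = 1) -> PowerLawFit:
    """Fit alpha at a fixed xmin and bundle sigma/D/n_tail."""
    x = _tail(samples, xmin)
    alpha, sigma = mle_alpha_discrete(x, xmin)
    return PowerLawFit(
        alpha=alpha,
        xmin=int(xmin),
        sigma=sigma,
        D=ks_distance(x, alpha, xmin),
        n_tail=int(x.size),
    )


def select_xmin(
    samples, xmin_max: int | None = None, min_tail: int = 10
) -> PowerLawFit:
    """Scan candidate xmin values and keep the fit minimising the KS D.

    Candidates are the distinct observed values (optionally capped at
    ``xmin_max``) whose tail retains at least ``min_tail`` samples.
    """
    x = _tail(np.asarray(samples), 1)
    distinct = np.unique(x)
    if distinct.size < 10:
        raise ValueError("need at least 10 distinct values to scan xmin")
    best: PowerLawFit | None = None
    for cand in distinct:
        if xmin_max is not None and cand > xmin_max:
            break
        tail = x[x >= cand]
        if tail.size < min_tail or np.unique(tail).size < 2:
            break
        fit = fit_sizes(tail, int(cand))
        if best is None or fit.D < best.D:
            best = fit
    assert best is not None
    return best
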