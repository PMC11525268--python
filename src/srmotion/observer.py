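"""Threshold stochastic-resonance observer for 2IFC motion detection.

The observer reduces each stimulus interval to a scalar "motion evidence"
draw.  The target interval yields ``X_t ~ N(mu, sigma²)`` and the
all-random interval ``X_n ~ N(0, sigma²)``, where

* ``mu = gain_a · coherence · N / (N + n_sat)`` — signal pooling that
  saturates with dot numerosity ``N`` (more dots help, with diminishing
  returns), and
* ``sigma² = sigma_int² + ext_b² · N`` — internal (neural) noise plus
  correspondence noise that accumulates as the sum of independent per-dot
  matching errors, hence SD growing like √N.

Evidence passes through a hard detection threshold, ``T(x) = x`` if
``x > theta`` else ``0``; the observer picks the interval with the larger
rectified evidence and guesses on ties.  Because a sub-threshold signal
(``mu < theta``) is invisible without noise but is pushed over the
threshold by an intermediate amount of it, accuracy as a function of total
noise is an inverted U — the classical threshold stochastic-resonance
mechanism.  Raising ``sigma_int`` moves the optimum toward *less* external
noise: part of the noise budget is already spent internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import ndtr

_SQRT2PI = math.sqrt(2.0 * math.pi)

__all__ = [
    "ObserverParams",
    "PsychometricPoint",
    "evidence_moments",
    "p_correct_2ifc",
    "accuracy_curve",
    "sr_peak",
    "coherence_threshold_analytic",
    "simulate_trial",
    "simulate_trials",
]


@dataclass(frozen=True)
class ObserverParams:
    """Per-participant observer parameters (evidence units are arbitrary).

    theta
        detection threshold on the evidence scale (> 0).
    sigma_int
        internal-noise SD; the age-linked quantity.
    gain_a
        asymptotic pooling gain: ``mu -> gain_a · coherence`` as N grows.
    n_sat
        dot count at which pooling reaches half its asymptote.
    ext_b
        external-noise coefficient; evidence SD contributed per √dot.
    lapse
        trial-independent lapse rate, capped at 0.1.
    """

    theta: float = 1.0
    sigma_int: float = 0.3
    gain_a: float = 6.0
    n_sat: float = 15.0
    ext_b: float = 0.035
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.sigma_int < 0 or self.ext_b < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.gain_a <= 0 or self.n_sat <= 0:
            raise ValueError("gain_a and n_sat must be > 0")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")


@dataclass(frozen=True)
class PsychometricPoint:
    coherence: float
    n_dots: int
    p_correct: float


def evidence_moments(
    params: ObserverParams, coherence: float, n_dots: int
) -> tuple[float, float]:
    """Mean and SD of the target-interval evidence at one stimulus condition."""
    if n_dots < 1:
        raise ValueError("n_dots must be >= 1")
    mu = params.gain_a * coherence * n_dots / (n_dots + params.n_sat)
    sigma = math.sqrt(params.sigma_int**2 + params.ext_b**2 * n_dots)
    return mu, sigma


def p_correct_2ifc(mu: float, sigma: float, theta: float, lapse: float = 0.0) -> float:
    """Probability of a correct 2IFC choice under the rectified-max rule.

    Decomposes over the three regimes of the rectifier:

    * only the target crosses threshold         -> correct,
    * both cross                                -> correct iff X_t > X_n,
    * neither crosses (tie at zero)             -> unbiased guess,

    with the middle term evaluated by adaptive quadrature (abs. tol 1e-6).
    The lapse mixes in an unconditional coin flip.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    q_t = ndtr(-(theta - mu) / sigma)  # P(X_t > theta)
    q_n = ndtr(-theta / sigma)  # P(X_n > theta)
    # target above threshold, non-target below
    p = q_t * (1.0 - q_n)
    # both below: guess
    p += 0.5 * (1.0 - q_t) * (1.0 - q_n)
    # both above: P(X_t > X_n > theta)
    z_lo = (theta - mu) / sigma
    cdf_theta = ndtr(theta / sigma)

    def integrand(z: float) -> float:
        x = mu + sigma * z
        return math.exp(-0.5 * z * z) / _SQRT2PI * (ndtr(x / sigma) - cdf_theta)

    both, _ = integrate.quad(integrand, z_lo, np.inf, epsabs=1e-6, epsrel=1e-8)
    p += both
    return (1.0 - lapse) * p + 0.5 * lapse


def accuracy_curve(
    params: ObserverParams, coherence: float, levels: list[int]
) -> list[PsychometricPoint]:
    """Expected accuracy at each dot-numerosity level (deterministic)."""
    if not levels:
        raise ValueError("levels must be non-empty")
    pts = []
    for n in levels:
        mu, sigma = evidence_moments(params, coherence, n)
        pts.append(
            PsychometricPoint(coherence, n, p_correct_2ifc(mu, sigma, params.theta, params.lapse))
        )
    return pts


def sr_peak(params: ObserverParams, coherence: float, grid: list[int]) -> int:
    """Grid level with maximal expected accuracy; ties go to the smaller level."""
    if not grid:
        raise ValueError("grid must be non-empty")
    if list(grid) != sorted(grid):
        raise ValueError("grid must be sorted ascending")
    curve = accuracy_curve(params, coherence, list(grid))
    p = np.array([pt.p_correct for pt in curve])
    return int(grid[int(np.argmax(p))])


def coherence_threshold_analytic(
    params: ObserverParams, n_dots: int, target_p: float, tol: float = 1e-4
) -> float:
    """Coherence at which expected 2IFC accuracy equals ``target_p``.

    Bisection on coherence in [0, 1].  Returns ``nan`` ("unattainable")
    when even full coherence does not reach the target.
    """
    if not 0.5 < target_p < 1.0:
        raise ValueError("target_p must be in (0.5, 1)")

    def p_at(c: float) -> float:
        mu, sigma = evidence_moments(params, c, n_dots)
        return p_correct_2ifc(mu, sigma, params.theta, params.lapse)

    if p_at(1.0) < target_p:
        return float("nan")
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if p_at(mid) < target_p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_trials(
    params: ObserverParams,
    coherence: float,
    n_dots: int,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised Monte-Carlo 2IFC trials; returns a boolean correctness array."""
    mu, sigma = evidence_moments(params, coherence, n_dots)
    x_t = rng.normal(mu, sigma, size=n_trials)
    x_n = rng.normal(0.0, sigma, size=n_trials)
    t_t = np.where(x_t > params.theta, x_t, 0.0)
    t_n = np.where(x_n > params.theta, x_n, 0.0)
    correct = t_t > t_n
    ties = t_t == t_n
    correct[ties] = rng.random(int(ties.sum())) < 0.5
    lapsed = rng.random(n_trials) < params.lapse
    correct[lapsed] = rng.random(int(lapsed.sum())) < 0.5
    return correct


def simulate_trial(
    params: ObserverParams,
    coherence: float,
    n_dots: int,
    seed: int | np.random.Generator,
) -> bool:
    """One seeded stochastic 2IFC trial (the sampling twin of p_correct_2ifc)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return bool(simulate_trials(params, coherence, n_dots, 1, rng)[0])
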