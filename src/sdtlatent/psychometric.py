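"""The m-AFC psychometric function in d' units.

Signal detection theory models an m-alternative forced-choice trial by
postulating one internal response per response alternative.  The correct
alternative draws its internal response from N(d', 1) and each of the m-1
incorrect alternatives from N(0, 1); the alternative with the largest
internal response is chosen.  Probability correct is therefore

    p(C) = \\int phi(x - d') [Phi(x)]^(m-1) dx

where phi and Phi are the standard normal density and CDF.  ``pc_from_dprime``
evaluates this integral, ``dprime_from_pc`` inverts it, and
``choice_probability`` generalizes the integrand (point-mass signal density,
logistic CDF) — the generalization contains the dichotomous Rasch model as a
special case via the sifting property of the Dirac delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, ndtr

__all__ = [
    "InternalResponseModel",
    "PsychometricPoint",
    "pc_from_dprime",
    "dprime_from_pc",
    "choice_probability",
]

# Gauss-Hermite rule, centered at d' at evaluation time.  Order 64 evaluates
# the integral to ~1e-12 absolute error over d' in [-6, 6], m up to 8.
_GH_ORDER = 64
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(_GH_ORDER)
_SQRT2 = np.sqrt(2.0)
_INV_SQRT_PI = 1.0 / np.sqrt(np.pi)


@dataclass(frozen=True)
class InternalResponseModel:
    """Equal-variance Gaussian internal-response model for an m-AFC trial.

    The incorrect-alternative mean is fixed at 0 and the common SD at 1:
    d' is in pooled-SD units and the axis origin is arbitrary, so both can
    be normalized away without loss of generality.
    """

    mean_correct: float
    n_alternatives: int
    mean_incorrect: float = field(default=0.0, init=False)
    sd: float = field(default=1.0, init=False)

    def __post_init__(self) -> None:
        if self.n_alternatives < 2:
            raise ValueError(f"n_alternatives must be >= 2, got {self.n_alternatives}")
        if not np.isfinite(self.mean_correct):
            raise ValueError("mean_correct must be finite")

    @property
    def dprime(self) -> float:
        return self.mean_correct

    def p_correct(self) -> float:
        return pc_from_dprime(self.mean_correct, self.n_alternatives)


@dataclass(frozen=True)
class PsychometricPoint:
    """One point (d', m, p_correct) on the m-AFC psychometric function."""

    dprime: float
    m: int
    p_correct: float

    @classmethod
    def at(cls, dprime: float, m: int) -> "PsychometricPoint":
        return cls(dprime=dprime, m=m, p_correct=float(pc_from_dprime(dprime, m)))


def _check_m(m: int) -> int:
    if int(m) != m or m < 2:
        raise ValueError(f"m must be an integer >= 2, got {m!r}")
    return int(m)


def pc_from_dprime(dprime, m: int):
    """Probability correct on an m-AFC trial at separation ``dprime``.

    Evaluates ``int phi(x - d') Phi(x)^(m-1) dx`` by Gauss-Hermite quadrature
    centered at d'.  Vectorized over ``dprime``; strictly increasing in d' and
    strictly decreasing in m at fixed finite d'.

    Parameters
    ----------
    dprime : float or array_like
        Person-minus-item separation theta - b, in d' units.
    m : int
        Number of response alternatives, >= 2.

    Returns
    -------
    float or ndarray in (0, 1); chance = 1/m at dprime = 0.
    """
    m = _check_m(m)
    d = np.asarray(dprime, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("dprime must be finite")
    # substitute x = d' + sqrt(2) t against weight exp(-t^2)
    nodes = d[..., np.newaxis] + _SQRT2 * _GH_X
    pc = _INV_SQRT_PI * (ndtr(nodes) ** (m - 1)) @ _GH_W
    if np.isscalar(dprime) or np.ndim(dprime) == 0:
        return float(pc)
    return pc


def dprime_from_pc(p: float, m: int) -> float:
    """Inverse psychometric function: the d' at which p(C) equals ``p``.

    Uses monotone bracketing (initial bracket [-10, 10], doubled until it
    straddles ``p``) and Brent root refinement to |residual in p| < 1e-10.

    Raises
    ------
    ValueError
        If ``p`` is not strictly inside (0, 1) — degenerate observed scores
        must be adjusted by the caller before inversion.
    """
    m = _check_m(m)
    p = float(p)
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    lo, hi = -10.0, 10.0
    while pc_from_dprime(lo, m) > p:
        lo *= 2.0
        if lo < -1e6:  # pragma: no cover - unreachable for double-precision p
            raise ValueError(f"failed to bracket p={p}")
    while pc_from_dprime(hi, m) < p:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover
            raise ValueError(f"failed to bracket p={p}")
    return float(brentq(lambda d: pc_from_dprime(d, m) - p, lo, hi, xtol=1e-12, rtol=8.9e-16))


def choice_probability(dprime, m: int, signal_density: str = "normal",
                       noise_cdf: str = "normal"):
    """Generalized m-AFC choice probability ``int f(x - d') F(x)^(m-1) dx``.

    ``signal_density`` selects f (the correct-choice internal-response
    density): "normal" (standard SDT) or "point_mass" (Dirac delta at d').
    ``noise_cdf`` selects F: "normal" or "logistic".  With a point-mass
    density the integral collapses to F(d')^(m-1) by the sifting property;
    at m = 2 with the logistic CDF this is exactly the dichotomous Rasch
    model probability 1/(1 + e^{-d'}).
    """
    m = _check_m(m)
    d = np.asarray(dprime, dtype=float)
    if noise_cdf == "normal":
        F = ndtr
    elif noise_cdf == "logistic":
        F = expit
    else:
        raise ValueError(f"unknown noise_cdf {noise_cdf!r}")
    if signal_density == "point_mass":
        out = F(d) ** (m - 1)
    elif signal_density == "normal":
        nodes = d[..., np.newaxis] + _SQRT2 * _GH_X
        out = _INV_SQRT_PI * (F(nodes) ** (m - 1)) @ _GH_W
    else:
        raise ValueError(f"unknown signal_density {signal_density!r}")
    if np.isscalar(dprime) or np.ndim(dprime) == 0:
        return float(out)
    return out
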