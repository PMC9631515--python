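"""Prior specifications for Bayesian parameter estimation.

All positive parameters carry log-normal priors characterised by their
median and coefficient of variation (CV); estimation works on the log
scale, where these priors are Gaussian.  The mixture-split parameter RH of
the log-normal GA function lives in (0, 1) and is handled on a logit scale
with a Gaussian prior whose width is solved numerically so that the
natural-scale CV matches the configured value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ParamPrior",
    "default_gom_priors",
    "default_omm_priors",
    "lognormal_sigma_from_cv",
    "lognormal_cv_from_sigma",
    "logitnormal_moments",
    "logitnormal_cv",
    "logitnormal_sigma_from_cv",
]

# Gauss-Hermite rule used for logit-normal moments (probabilists' change of
# variables is applied explicitly below).
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(80)
_GH_WEIGHTS = _GH_WEIGHTS / math.sqrt(2.0 * math.pi)


def lognormal_sigma_from_cv(cv: float) -> float:
    """Log-scale SD of a log-normal with the given CV."""
    if not (cv > 0.0):
        raise ValueError("CV must be positive")
    return math.sqrt(math.log1p(cv * cv))


def lognormal_cv_from_sigma(sigma: float) -> float:
    return math.sqrt(math.expm1(sigma * sigma))


def _expit(x):
    out = np.empty_like(np.asarray(x, dtype=float))
    x = np.asarray(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def logitnormal_moments(mu: float, sigma: float):
    """Mean and SD on (0, 1) of expit(N(mu, sigma^2)), by quadrature."""
    x = _expit(mu + sigma * _GH_NODES)
    mean = float(np.sum(_GH_WEIGHTS * x))
    var = float(np.sum(_GH_WEIGHTS * (x - mean) ** 2))
    return mean, math.sqrt(max(var, 0.0))


def logitnormal_cv(mu: float, sigma: float) -> float:
    mean, sd = logitnormal_moments(mu, sigma)
    return sd / mean


def logitnormal_sigma_from_cv(median: float, cv: float) -> float:
    """Solve the logit-scale SD whose natural-scale CV matches ``cv``.

    The logit-normal CV is bounded above (for median 0.5 it approaches 1 as
    the distribution piles onto {0, 1}); an unattainable CV raises.
    """
    if not (0.0 < median < 1.0):
        raise ValueError("median must lie in (0, 1)")
    mu = math.log(median / (1.0 - median))
    f = lambda s: logitnormal_cv(mu, s) - cv
    hi = 60.0
    if f(hi) < 0.0:
        raise ValueError(f"CV {cv} is not attainable for a logit-normal with median {median}")
    return brentq(f, 1e-8, hi, xtol=1e-12)


@dataclass(frozen=True)
class ParamPrior:
    """Median/CV prior on one parameter, Gaussian on a transformed scale."""

    median: float
    cv: float
    transform: str = "log"  # "log" for positive parameters, "logit" for (0,1)

    def __post_init__(self) -> None:
        if not (self.cv > 0.0):
            raise ValueError("prior CV must be positive")
        if self.transform == "log":
            if not (self.median > 0.0):
                raise ValueError("log-normal prior median must be positive")
        elif self.transform == "logit":
            if not (0.0 < self.median < 1.0):
                raise ValueError("logit-scale prior median must lie in (0, 1)")
        else:
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def mu(self) -> float:
        """Gaussian mean on the transformed scale (maps back to the median)."""
        if self.transform == "log":
            return math.log(self.median)
        return math.log(self.median / (1.0 - self.median))

    @property
    def sigma(self) -> float:
        """Gaussian SD on the transformed scale matching the natural CV."""
        if self.transform == "log":
            return lognormal_sigma_from_cv(self.cv)
        return logitnormal_sigma_from_cv(self.median, self.cv)

    def to_natural(self, x: float) -> float:
        if self.transform == "log":
            return math.exp(x)
        return float(_expit(np.asarray([x]))[0])

    def from_natural(self, value: float) -> float:
        if self.transform == "log":
            return math.log(value)
        return math.log(value / (1.0 - value))

    def cv_from_sigma(self, sigma: float, mu: float | None = None) -> float:
        """Natural-scale CV implied by a transformed-scale Gaussian SD."""
        if self.transform == "log":
            return lognormal_cv_from_sigma(sigma)
        return logitnormal_cv(self.mu if mu is None else mu, sigma)


def default_gom_priors() -> Dict[str, ParamPrior]:
    """Default priors for the glucose-only model's nine free parameters.

    The sensitivity surrogate SG gets a wide prior (CV 50 %) while the GA
    coupling beta is held narrow (CV 10 %): the two covary strongly, and
    widening both degrades the precision of SG, the parameter that carries
    the insulin-sensitivity information.
    """
    return {
        "p1": ParamPrior(0.02, 0.50),     # min^-1
        "p2": ParamPrior(0.02, 0.50),     # min^-1
        "sg": ParamPrior(5e-4, 0.50),     # min^-1 per mg/dL
        "beta": ParamPrior(30.0, 0.10),   # min
        "T1": ParamPrior(30.0, 0.50),     # min
        "T2": ParamPrior(90.0, 0.50),     # min
        "W1": ParamPrior(0.5, 0.50),
        "W2": ParamPrior(0.5, 0.50),
        "RH": ParamPrior(0.5, 0.50, transform="logit"),
    }


def default_omm_priors(A: float, n_free_heights: int = 6) -> Dict[str, ParamPrior]:
    """Default priors for the oral minimal model.

    Free GA heights are centred on the flat profile whose trapezoidal AUC
    over the standard breakpoints equals ``A`` (the seventh height is not
    estimated; it is solved from the AUC constraint).
    """
    flat = A / 235.0  # AUC of a flat 7-breakpoint profile at height h is 235 h
    priors: Dict[str, ParamPrior] = {
        "p1": ParamPrior(0.02, 0.50),
        "p2": ParamPrior(0.02, 0.50),
        "si": ParamPrior(1e-3, 0.50),     # min^-1 per mU/L
    }
    for i in range(1, n_free_heights + 1):
        priors[f"h{i}"] = ParamPrior(flat, 0.50)
    return priors
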