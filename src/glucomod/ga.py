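"""Meal-related glucose appearance (GA) input functions.

Two parameterisations of the rate at which meal-derived glucose enters
plasma (mg/kg/min) are provided:

* :class:`RaLN` — a two-component mixture of modified log-normal densities,
  fully differentiable, with a fixed total area under the curve ``A``
  (mg/kg).  Used by the glucose-only model.
* :class:`RaPL` — a piecewise-linear curve anchored at the origin with seven
  breakpoints at adjustable heights and the same fixed-AUC constraint,
  realised by solving the last height from the first six.  Used by the
  oral minimal model.

Both expose ``rate(t)`` (scalar, minutes after meal consumption) and
``rate_grid(t)`` (vectorised) and can be evaluated beyond the nominal
240-min response window, which is how the absorption tail of a previous
meal persists into the next response (:class:`PersistingGA`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "f_ln",
    "f_ln_grid",
    "ra_ln",
    "ra_pl",
    "RaLN",
    "RaPL",
    "solve_last_height",
    "PersistingGA",
    "InfeasibleAUCError",
]

_DEFAULT_BREAK_TIMES = (10.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0)


class InfeasibleAUCError(ValueError):
    """The fixed-AUC constraint forces a negative piecewise-linear height."""


def _check_shape(T: float, W: float) -> None:
    if not (T > 0.0):
        raise ValueError(f"log-normal time parameter T must be > 0, got {T}")
    if not (W > 0.0):
        raise ValueError(f"log-normal width parameter W must be > 0, got {W}")


def f_ln(t: float, T: float, W: float) -> float:
    """Modified log-normal density (min^-1), zero at ``t = 0``.

    The density is parameterised so that its mode falls exactly at ``t = T``
    and it integrates to one over ``[0, inf)``; ``W`` controls the width.
    """
    _check_shape(T, W)
    if t < 0.0:
        raise ValueError(f"time must be >= 0, got {t}")
    r = t / T
    if r == 0.0:  # includes exact zero and subnormal underflow
        return 0.0
    u = math.log(r) - W / 2.0
    # log-space evaluation guards against float underflow at extreme t
    logv = -u * u / W - math.log(t) - 0.5 * math.log(math.pi * W)
    return math.exp(logv) if logv > -745.0 else 0.0


def f_ln_grid(t: np.ndarray, T: float, W: float) -> np.ndarray:
    """Vectorised :func:`f_ln` over an array of times (minutes)."""
    _check_shape(T, W)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("times must be >= 0")
    out = np.zeros_like(t)
    pos = (t / T) > 0.0
    tp = t[pos]
    u = np.log(tp / T) - W / 2.0
    out[pos] = np.exp(-u * u / W) / (tp * math.sqrt(math.pi * W))
    return out


@dataclass(frozen=True)
class RaLN:
    """Two-component log-normal GA function with total AUC ``A`` (mg/kg).

    ``RH`` in (0, 1) splits the AUC between an early component (peak time
    ``T1`` min, width ``W1``) and a late component (``T2``, ``W2``).
    """

    A: float
    RH: float
    T1: float
    W1: float
    T2: float
    W2: float

    def __post_init__(self) -> None:
        if not (self.A > 0.0):
            raise ValueError(f"AUC A must be > 0, got {self.A}")
        if not (0.0 < self.RH < 1.0):
            raise ValueError(f"RH must lie in (0, 1), got {self.RH}")
        _check_shape(self.T1, self.W1)
        _check_shape(self.T2, self.W2)

    def rate(self, t: float) -> float:
        """GA rate (mg/kg/min) at ``t`` minutes after meal consumption."""
        return self.A * (
            (1.0 - self.RH) * f_ln(t, self.T1, self.W1)
            + self.RH * f_ln(t, self.T2, self.W2)
        )

    def rate_grid(self, t: np.ndarray) -> np.ndarray:
        return self.A * (
            (1.0 - self.RH) * f_ln_grid(t, self.T1, self.W1)
            + self.RH * f_ln_grid(t, self.T2, self.W2)
        )


def ra_ln(t: float, p: "RaLN") -> float:
    """GA rate (mg/kg/min) of a log-normal input at ``t`` minutes."""
    return p.rate(t)


def ra_pl(t: float, p: "RaPL") -> float:
    """GA rate (mg/kg/min) of a piecewise-linear input at ``t`` minutes."""
    return p.rate(t)


def solve_last_height(
    first_six: Sequence[float],
    break_times: Sequence[float] = _DEFAULT_BREAK_TIMES,
    A: float = 0.0,
) -> float:
    """Solve the seventh breakpoint height from the trapezoidal AUC constraint.

    The piecewise-linear curve runs through ``(0, 0)`` and the seven
    breakpoints; its trapezoidal AUC must equal ``A`` exactly.  Raises
    :class:`InfeasibleAUCError` when the implied height is negative, which
    during estimation marks a proposal as invalid.
    """
    bt = _validated_break_times(break_times)
    h = [float(x) for x in first_six]
    if len(h) != 6:
        raise ValueError("expected exactly six free heights")
    ts = np.concatenate(([0.0], bt))
    hs = np.concatenate(([0.0], h, [0.0]))
    dts = np.diff(ts)
    # AUC = sum dt_i*(h_{i-1}+h_i)/2; the last height enters with dt_7/2.
    partial = float(np.sum(dts * (hs[:-1] + hs[1:]) / 2.0))
    coeff = dts[-1] / 2.0
    h7 = (float(A) - partial) / coeff
    if h7 < 0.0:
        if h7 > -1e-12 * max(1.0, abs(A)):
            return 0.0
        raise InfeasibleAUCError(
            f"AUC constraint A={A} implies a negative seventh height ({h7:.4g})"
        )
    return h7


def _validated_break_times(break_times: Sequence[float]) -> np.ndarray:
    bt = np.asarray(break_times, dtype=float)
    if bt.ndim != 1 or bt.size != 7:
        raise ValueError("break_times must contain exactly seven values")
    if bt[0] <= 0.0 or np.any(np.diff(bt) <= 0.0):
        raise ValueError("break_times must be strictly increasing and > 0")
    return bt


@dataclass(frozen=True)
class RaPL:
    """Piecewise-linear GA function through (0, 0) and seven breakpoints.

    The heights are GA rates (mg/kg/min); the trapezoidal AUC over the
    breakpoints equals ``A``.  Beyond the last breakpoint the curve decays
    linearly from the final height to zero over ``tail_decay`` minutes (the
    rule used when this meal's absorption persists into the next response).
    """

    A: float
    heights: tuple
    break_times: tuple = _DEFAULT_BREAK_TIMES
    tail_decay: float = 60.0

    def __post_init__(self) -> None:
        bt = _validated_break_times(self.break_times)
        hs = np.asarray(self.heights, dtype=float)
        if hs.size != 7:
            raise ValueError("heights must contain exactly seven values")
        if np.any(hs < 0.0):
            raise ValueError("heights must be >= 0")
        if self.tail_decay <= 0.0:
            raise ValueError("tail_decay must be > 0")
        ts = np.concatenate(([0.0], bt))
        full = np.concatenate(([0.0], hs))
        auc = float(np.trapezoid(full, ts))
        if not math.isclose(auc, self.A, rel_tol=1e-6, abs_tol=1e-9):
            raise ValueError(
                f"trapezoidal AUC {auc:.6g} does not match the fixed AUC {self.A:.6g}"
            )
        object.__setattr__(self, "break_times", tuple(bt))
        object.__setattr__(self, "heights", tuple(hs))

    @classmethod
    def from_free_heights(
        cls,
        first_six: Sequence[float],
        A: float,
        break_times: Sequence[float] = _DEFAULT_BREAK_TIMES,
        tail_decay: float = 60.0,
    ) -> "RaPL":
        """Build from six free heights, solving the seventh from the AUC."""
        h7 = solve_last_height(first_six, break_times, A)
        return cls(
            A=float(A),
            heights=tuple(list(map(float, first_six)) + [h7]),
            break_times=tuple(float(t) for t in break_times),
            tail_decay=float(tail_decay),
        )

    @property
    def knots(self) -> np.ndarray:
        """Non-smooth points of the curve, for ODE mesh protection."""
        return np.concatenate(
            ([0.0], self.break_times, [self.break_times[-1] + self.tail_decay])
        )

    def rate(self, t: float) -> float:
        return float(self.rate_grid(np.asarray([t]))[0])

    def rate_grid(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        t_end = self.break_times[-1]
        xs = np.concatenate(
            ([0.0], self.break_times, [t_end + self.tail_decay])
        )
        ys = np.concatenate(([0.0], self.heights, [0.0]))
        out = np.interp(t, xs, ys, left=0.0, right=0.0)
        out[t < 0.0] = 0.0
        return out


@dataclass(frozen=True)
class PersistingGA:
    """Residual absorption from previously consumed meals.

    Each contribution pairs a time offset (minutes elapsed between the
    earlier meal and the start of the current response) with that meal's GA
    function; the persisting rate at local time ``t`` is the sum of the
    earlier functions evaluated at ``t + offset``.  The first meal of a day
    carries no persisting GA (:meth:`none`).
    """

    contributions: tuple = field(default_factory=tuple)

    @classmethod
    def none(cls) -> "PersistingGA":
        return cls(contributions=())

    @classmethod
    def from_previous(cls, offsets_and_gas) -> "PersistingGA":
        return cls(contributions=tuple((float(off), ga) for off, ga in offsets_and_gas))

    def rate(self, t: float) -> float:
        return sum(ga.rate(t + off) for off, ga in self.contributions)

    def rate_grid(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for off, ga in self.contributions:
            out += ga.rate_grid(t + off)
        return out

    def knots(self, t_max: float) -> np.ndarray:
        """Local times where a contributing RaPL tail has a kink."""
        pts = []
        for off, ga in self.contributions:
            if hasattr(ga, "knots"):
                local = np.asarray(ga.knots) - off
                pts.extend(local[(local > 0.0) & (local < t_max)])
        return np.asarray(sorted(set(pts)))
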