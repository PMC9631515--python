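"""Forward models of postprandial glucose dynamics.

Two two-state ODE models share the structure

    dG/dt = -G X - p1 (G - Gb) + [Ra(t) + Rap(t)] / V
    dX/dt = -p2 (X - S * drive(t))

where ``G`` is plasma glucose (mg/dL), ``X`` the glucose-lowering action in
a remote compartment (min^-1), ``Ra`` the meal-related glucose appearance,
``Rap`` persisting appearance from an earlier meal, and ``V`` the glucose
distribution volume (dL/kg).

* Oral minimal model (OMM): the drive is the measured supra-basal insulin
  ``I(t) - Ib`` and ``S = SI`` is insulin sensitivity (min^-1 per mU/L);
  the GA input is piecewise linear (:class:`glucomod.ga.RaPL`).
* Glucose-only model (GOM): the drive is a surrogate built from glucose
  itself, ``Z(t) = Zpos(G) + beta * RaLN(t) / V``, where ``Zpos`` is a
  sigmoid-gated supra-basal glucose excursion; ``S = SG`` (min^-1 per
  mg/dL) replaces insulin sensitivity and the GA input is the log-normal
  mixture (:class:`glucomod.ga.RaLN`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .ga import PersistingGA, RaLN, RaPL

__all__ = [
    "GomParams",
    "OmmParams",
    "z_pos",
    "z_var",
    "gom_rhs",
    "omm_rhs",
    "simulate",
    "SimResult",
    "IntegrationError",
    "InsulinInterpolant",
    "DEFAULT_ALPHA",
    "DEFAULT_V",
]

#: Shape of the sigmoid gate in Zpos (dL/mg); fixed, not estimated, because
#: it is practically unidentifiable from single-meal glucose data.
DEFAULT_ALPHA = 0.1

#: Glucose distribution volume (dL/kg); the standard minimal-model value,
#: fixed rather than estimated.
DEFAULT_V = 1.45


class IntegrationError(RuntimeError):
    """Adaptive ODE integration failed; carries the failure time."""

    def __init__(self, message: str, t: float):
        super().__init__(message)
        self.t = t


def _positive(name: str, value: float) -> None:
    if not (value > 0.0):
        raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class GomParams:
    """Full parameter vector of the glucose-only model."""

    p1: float      # glucose effectiveness, min^-1
    p2: float      # action decay rate, min^-1
    sg: float      # sensitivity surrogate, min^-1 per mg/dL
    beta: float    # coupling of GA into the drive Z, min
    gb: float      # basal glucose, mg/dL
    g0: float      # initial glucose, mg/dL
    x0: float      # initial action, min^-1
    ga: RaLN
    alpha: float = DEFAULT_ALPHA  # Zpos gate shape, dL/mg
    v: float = DEFAULT_V          # distribution volume, dL/kg

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "sg", "beta", "gb", "g0", "alpha", "v"):
            _positive(name, getattr(self, name))
        if self.x0 < 0.0:
            raise ValueError(f"x0 must be >= 0, got {self.x0}")


@dataclass(frozen=True)
class OmmParams:
    """Full parameter vector of the oral minimal model."""

    p1: float      # glucose effectiveness, min^-1
    p2: float      # insulin-action decay rate, min^-1
    si: float      # insulin sensitivity, min^-1 per mU/L
    gb: float      # basal glucose, mg/dL
    ib: float      # basal insulin, mU/L
    g0: float      # initial glucose, mg/dL
    x0: float      # initial insulin action, min^-1
    ga: RaPL
    v: float = DEFAULT_V

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "si", "gb", "ib", "g0", "v"):
            _positive(name, getattr(self, name))
        if self.x0 < 0.0:
            raise ValueError(f"x0 must be >= 0, got {self.x0}")


def _sigmoid(x):
    """Numerically stable logistic function, scalar or array."""
    if np.isscalar(x):
        if x >= 0.0:
            return 1.0 / (1.0 + math.exp(-x))
        e = math.exp(x)
        return e / (1.0 + e)
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0.0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def z_pos(g, gb: float, alpha: float = DEFAULT_ALPHA):
    """Sigmoid-gated supra-basal glucose excursion (mg/dL).

    Behaves like ``g - gb`` well above basal and saturates towards zero
    below basal; it is not hard-clipped, so slightly negative values occur
    for sub-basal glucose.  ``alpha`` (dL/mg) sets the transition sharpness.
    """
    _positive("alpha", alpha)
    d = g - gb
    return d * _sigmoid(alpha * d)


def z_var(g, gb: float, raln_t, params: GomParams):
    """The GOM drive Z(t) = Zpos(G) + beta * RaLN(t) / V (mg/dL)."""
    return z_pos(g, gb, params.alpha) + params.beta * raln_t / params.v


def gom_rhs(state, t: float, params: GomParams, rap: Optional[PersistingGA] = None):
    """Right-hand side of the glucose-only model at one time point."""
    g, x = float(state[0]), float(state[1])
    raln_t = params.ga.rate(t)
    rap_t = rap.rate(t) if rap is not None else 0.0
    z = z_pos(g, params.gb, params.alpha) + params.beta * raln_t / params.v
    dg = -g * x - params.p1 * (g - params.gb) + (raln_t + rap_t) / params.v
    dx = -params.p2 * (x - params.sg * z)
    return dg, dx


def omm_rhs(
    state,
    t: float,
    params: OmmParams,
    insulin: Callable[[float], float],
    rap: Optional[PersistingGA] = None,
):
    """Right-hand side of the oral minimal model at one time point."""
    g, x = float(state[0]), float(state[1])
    ra_t = params.ga.rate(t)
    rap_t = rap.rate(t) if rap is not None else 0.0
    dg = -g * x - params.p1 * (g - params.gb) + (ra_t + rap_t) / params.v
    dx = -params.p2 * (x - params.si * (insulin(t) - params.ib))
    return dg, dx


class InsulinInterpolant:
    """Piecewise-linear insulin input I(t) (mU/L), constant beyond the ends."""

    def __init__(self, times, values):
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0.0):
            raise ValueError("insulin times must be strictly increasing, n >= 2")
        if t.size != v.size:
            raise ValueError("insulin times and values must have equal length")
        self.times = t
        self.values = v

    def __call__(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))

    def grid(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)


@dataclass
class SimResult:
    """A simulated meal response sampled on the requested time grid."""

    t: np.ndarray       # minutes after meal consumption
    glucose: np.ndarray  # G, mg/dL
    action: np.ndarray   # X, min^-1
    gx: np.ndarray       # insulin-action product G*X, mg/dL/min
    drive: np.ndarray    # Z (GOM) or I - Ib (OMM), the input to dX/dt
    y: np.ndarray        # S * drive: SG*Z (GOM) or SI*(I-Ib) (OMM), min^-1
    ga_rate: np.ndarray  # current-meal GA rate at t, mg/kg/min
    model: str = "gom"


def _gom_fast_rhs(params: GomParams, rap: Optional[PersistingGA]):
    """Closure-based scalar RHS for speed inside the adaptive solver."""
    p1, p2, sg, beta = params.p1, params.p2, params.sg, params.beta
    gb, alpha, v = params.gb, params.alpha, params.v
    ga = params.ga
    A, RH, T1, W1, T2, W2 = ga.A, ga.RH, ga.T1, ga.W1, ga.T2, ga.W2
    c1 = A * (1.0 - RH) / math.sqrt(math.pi * W1)
    c2 = A * RH / math.sqrt(math.pi * W2)
    rap_rate = rap.rate if rap is not None else None
    exp, log = math.exp, math.log

    def rhs(t, y):
        g = y[0]
        x = y[1]
        if t > 0.0:
            u1 = log(t / T1) - W1 / 2.0
            u2 = log(t / T2) - W2 / 2.0
            raln = (c1 * exp(-u1 * u1 / W1) + c2 * exp(-u2 * u2 / W2)) / t
        else:
            raln = 0.0
        rap_t = rap_rate(t) if rap_rate is not None else 0.0
        d = g - gb
        ax = alpha * d
        if ax >= 0.0:
            sig = 1.0 / (1.0 + exp(-ax))
        else:
            e = exp(ax)
            sig = e / (1.0 + e)
        z = d * sig + beta * raln / v
        dg = -g * x - p1 * d + (raln + rap_t) / v
        dx = -p2 * (x - sg * z)
        return (dg, dx)

    return rhs


def _omm_fast_rhs(params: OmmParams, insulin, rap: Optional[PersistingGA]):
    p1, p2, si = params.p1, params.p2, params.si
    gb, ib, v = params.gb, params.ib, params.v
    ga_rate = params.ga.rate
    rap_rate = rap.rate if rap is not None else None

    def rhs(t, y):
        g = y[0]
        x = y[1]
        ra = ga_rate(t)
        rap_t = rap_rate(t) if rap_rate is not None else 0.0
        dg = -g * x - p1 * (g - gb) + (ra + rap_t) / v
        dx = -p2 * (x - si * (insulin(t) - ib))
        return (dg, dx)

    return rhs


def _segment_boundaries(t0: float, t1: float, knots) -> np.ndarray:
    pts = [t0, t1]
    for k in np.atleast_1d(np.asarray(knots, dtype=float)):
        if t0 < k < t1:
            pts.append(float(k))
    return np.unique(np.asarray(pts))


def simulate(
    model: str,
    params,
    t_grid,
    rap: Optional[PersistingGA] = None,
    insulin: Optional[Callable[[float], float]] = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    ga_override=None,
    max_rhs_evals: int = 100_000,
) -> SimResult:
    """Integrate a meal response and sample it on ``t_grid`` (minutes).

    Uses adaptive Runge-Kutta (RK45) with the non-smooth points of any
    piecewise-linear GA input inserted as segment boundaries so the error
    control is not defeated by kinks.  ``ga_override`` substitutes a
    different GA object (anything with ``rate``/``rate_grid``) for the one
    stored in ``params``, which is occasionally useful for model-comparison
    experiments.

    Raises :class:`IntegrationError` if the solver cannot complete.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1 or np.any(np.diff(t_grid) <= 0.0):
        raise ValueError("t_grid must be one-dimensional and strictly increasing")
    if t_grid[0] < 0.0:
        raise ValueError("t_grid must start at or after the meal (t >= 0)")

    if ga_override is not None:
        params = _with_ga(params, ga_override)

    if model == "gom":
        rhs = _gom_fast_rhs(params, rap)
        knots = []
    elif model == "omm":
        if insulin is None:
            raise ValueError("the oral minimal model requires an insulin input")
        rhs = _omm_fast_rhs(params, insulin, rap)
        knots = list(getattr(params.ga, "knots", np.asarray([])))
    else:
        raise ValueError(f"unknown model {model!r}; expected 'gom' or 'omm'")
    if rap is not None:
        knots.extend(rap.knots(t_grid[-1] + 1.0))

    # evaluation budget: pathological parameter regions can make the
    # adaptive solver crawl; exceeding the budget is treated exactly like
    # a solver failure so callers (the estimator) can reject the proposal
    n_evals = [0]
    inner = rhs

    def rhs(t, y):  # noqa: F811 - deliberate wrap
        n_evals[0] += 1
        if n_evals[0] > max_rhs_evals:
            raise IntegrationError(
                f"integration exceeded {max_rhs_evals} RHS evaluations", t=float(t)
            )
        return inner(t, y)

    t0, t1 = 0.0, float(t_grid[-1])
    y = np.array([params.g0, params.x0], dtype=float)
    ts_out = []
    ys_out = []
    if t_grid[0] == 0.0:
        ts_out.append(0.0)
        ys_out.append(y.copy())

    if t1 > t0:
        bounds = _segment_boundaries(t0, t1, knots)
        for a, b in zip(bounds[:-1], bounds[1:]):
            eval_mask = (t_grid > a) & (t_grid <= b)
            t_eval = np.unique(np.concatenate((t_grid[eval_mask], [b])))
            sol = solve_ivp(
                rhs, (a, b), y, method="RK45", rtol=rtol, atol=atol,
                t_eval=t_eval, dense_output=False,
            )
            if not sol.success:
                raise IntegrationError(
                    f"ODE integration failed near t = {sol.t[-1] if sol.t.size else a:.2f} min: "
                    f"{sol.message}", t=float(sol.t[-1] if sol.t.size else a),
                )
            for tt, yy in zip(sol.t, sol.y.T):
                if tt in t_grid[eval_mask]:
                    ts_out.append(float(tt))
                    ys_out.append(yy.copy())
            y = sol.y[:, -1].copy()

    ts = np.asarray(ts_out)
    if ts.size != t_grid.size or not np.allclose(ts, t_grid):
        raise IntegrationError("solver did not produce all requested samples", t=t1)
    Y = np.asarray(ys_out).T
    g, x = Y[0], Y[1]
    ga_rate = params.ga.rate_grid(t_grid)
    if model == "gom":
        drive = z_pos(g, params.gb, params.alpha) + params.beta * ga_rate / params.v
        y_series = params.sg * drive
    else:
        ins = np.asarray([insulin(tt) for tt in t_grid])
        drive = ins - params.ib
        y_series = params.si * drive
    return SimResult(
        t=t_grid, glucose=g, action=x, gx=g * x, drive=drive,
        y=y_series, ga_rate=ga_rate, model=model,
    )


def _with_ga(params, ga):
    from dataclasses import replace

    return replace(params, ga=ga)
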