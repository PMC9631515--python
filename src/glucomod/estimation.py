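"""Bayesian parameter estimation for the GOM and OMM.

One set of parameters is estimated from every meal response.  The scheme
is a variational-Laplace approximation: the posterior mode on the
transformed (log / logit) scale is located by damped Gauss-Newton
(trust-region nonlinear least squares over the stacked data and prior
residuals) with multiple restarts drawn from the prior, and the posterior
is approximated as Gaussian with covariance from the Gauss-Newton
curvature at the mode.  Posterior medians and CVs are then read off the
implied log-normal (or logit-normal) marginals.

Consecutive meals of a day are chained: the initial glucose and action
states of meal ``k+1`` are taken from the posterior-median trajectory of
meal ``k`` evaluated at the next meal time, the previous meals' fitted GA
functions persist as ``Rap``, and the basal glucose ``Gb`` — the average
of the -15, 0, 2 and 5 min samples of the first meal — is held constant
throughout the day.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .data import DataError, MealResponseData, ObservationModel, RESPONSE_DURATION_MIN
from .ga import InfeasibleAUCError, PersistingGA, RaLN, RaPL
from .models import (
    DEFAULT_ALPHA,
    DEFAULT_V,
    GomParams,
    InsulinInterpolant,
    IntegrationError,
    OmmParams,
    SimResult,
    simulate,
)
from .priors import ParamPrior, default_gom_priors, default_omm_priors

__all__ = [
    "compute_gb",
    "log_joint",
    "fit_meal",
    "chain_day",
    "PosteriorResult",
    "EstimationError",
    "ParameterMap",
]

logger = logging.getLogger(__name__)

_GB_SAMPLE_TIMES = (-15.0, 0.0, 2.0, 5.0)

GOM_PARAM_NAMES = ("p1", "p2", "sg", "beta", "T1", "T2", "W1", "W2", "RH")


class EstimationError(RuntimeError):
    """Parameter estimation failed after all restarts."""


def compute_gb(first_meal: MealResponseData) -> float:
    """Basal glucose: the mean of the -15, 0, 2 and 5 min samples.

    Computed once from the first meal of the day and held constant for all
    meals.  Raises :class:`DataError` if any of the four samples is absent.
    """
    values = []
    for t in _GB_SAMPLE_TIMES:
        try:
            values.append(first_meal.value_at(t))
        except DataError as exc:
            raise DataError(
                f"basal glucose needs the sample at t = {t:g} min of the first meal"
            ) from exc
    return float(np.mean(values))


@dataclass(frozen=True)
class ParameterMap:
    """Bijection between the estimation vector and a full parameter set.

    The estimation vector holds the free parameters on their transformed
    scales, in a fixed order; everything else (alpha, V, Gb, initial
    conditions, the meal's GA AUC) is a constant of the fit.
    """

    model: str
    names: tuple
    priors: Dict[str, ParamPrior]
    gb: float
    g0: float
    x0: float
    A: float
    ib: float = 0.0
    alpha: float = DEFAULT_ALPHA
    v: float = DEFAULT_V
    break_times: tuple = (10.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0)
    tail_decay: float = 60.0

    @classmethod
    def for_gom(cls, priors, gb, g0, x0, A, alpha=DEFAULT_ALPHA, v=DEFAULT_V):
        return cls(model="gom", names=GOM_PARAM_NAMES, priors=priors,
                   gb=gb, g0=g0, x0=x0, A=A, alpha=alpha, v=v)

    @classmethod
    def for_omm(cls, priors, gb, ib, g0, x0, A, v=DEFAULT_V,
                break_times=(10.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0),
                tail_decay=60.0):
        names = ("p1", "p2", "si") + tuple(f"h{i}" for i in range(1, 7))
        return cls(model="omm", names=names, priors=priors, gb=gb, g0=g0,
                   x0=x0, A=A, ib=ib, v=v, break_times=tuple(break_times),
                   tail_decay=tail_decay)

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def prior_mu(self) -> np.ndarray:
        return np.array([self.priors[n].mu for n in self.names])

    @property
    def prior_sigma(self) -> np.ndarray:
        return np.array([self.priors[n].sigma for n in self.names])

    def to_natural(self, theta: np.ndarray) -> Dict[str, float]:
        return {n: self.priors[n].to_natural(x) for n, x in zip(self.names, theta)}

    def from_natural(self, values: Dict[str, float]) -> np.ndarray:
        return np.array([self.priors[n].from_natural(values[n]) for n in self.names])

    def build_params(self, theta: np.ndarray):
        """Materialise a full GomParams/OmmParams from an estimation vector.

        Raises :class:`InfeasibleAUCError` for OMM proposals whose implied
        seventh GA height is negative.
        """
        nat = self.to_natural(theta)
        if self.model == "gom":
            ga = RaLN(A=self.A, RH=nat["RH"], T1=nat["T1"], W1=nat["W1"],
                      T2=nat["T2"], W2=nat["W2"])
            return GomParams(p1=nat["p1"], p2=nat["p2"], sg=nat["sg"],
                             beta=nat["beta"], gb=self.gb, g0=self.g0,
                             x0=self.x0, ga=ga, alpha=self.alpha, v=self.v)
        ga = RaPL.from_free_heights(
            [nat[f"h{i}"] for i in range(1, 7)], A=self.A,
            break_times=self.break_times, tail_decay=self.tail_decay,
        )
        return OmmParams(p1=nat["p1"], p2=nat["p2"], si=nat["si"],
                         gb=self.gb, ib=self.ib, g0=self.g0, x0=self.x0,
                         ga=ga, v=self.v)


def _simulate_theta(pmap, theta, t_fit, rap, insulin, rtol):
    params = pmap.build_params(theta)
    # tight evaluation budget: a proposal too stiff to integrate cheaply
    # is rejected rather than allowed to stall the optimiser
    return simulate(pmap.model, params, t_fit, rap=rap, insulin=insulin,
                    rtol=rtol, max_rhs_evals=20_000)


def log_joint(
    theta: np.ndarray,
    data: MealResponseData,
    pmap: ParameterMap,
    obs: ObservationModel,
    rap: Optional[PersistingGA] = None,
    insulin=None,
    rtol: float = 1e-6,
) -> float:
    """Unnormalised log posterior on the transformed parameter scale.

    Gaussian log-likelihood of the observed glucose against the simulated
    trajectory under the known measurement SDs, plus independent Gaussian
    log-priors on the transformed scale.  Returns ``-inf`` when the
    proposal is infeasible or the simulation fails, so samplers and
    optimisers reject it.
    """
    theta = np.asarray(theta, dtype=float)
    t_fit = data.fit_times
    sd = np.asarray(obs.sd, dtype=float)
    if sd.size != t_fit.size:
        raise ValueError("observation model must give one SD per fitted sample")
    try:
        sim = _simulate_theta(pmap, theta, t_fit, rap, insulin, rtol)
    except (InfeasibleAUCError, IntegrationError, ValueError, OverflowError):
        return -np.inf
    resid = (data.fit_glucose - sim.glucose) / sd
    loglik = -0.5 * float(resid @ resid) - float(np.sum(np.log(sd * math.sqrt(2.0 * math.pi))))
    mu, sig = pmap.prior_mu, pmap.prior_sigma
    zp = (theta - mu) / sig
    logprior = -0.5 * float(zp @ zp) - float(np.sum(np.log(sig * math.sqrt(2.0 * math.pi))))
    return loglik + logprior


@dataclass
class PosteriorResult:
    """Gaussian posterior approximation for one meal response.

    ``medians``/``cvs`` are on the natural parameter scale; ``mode`` and
    ``cov`` live on the transformed (log / logit) estimation scale, where
    the approximation is Gaussian.
    """

    model: str
    param_map: ParameterMap
    mode: np.ndarray
    cov: np.ndarray
    medians: Dict[str, float]
    cvs: Dict[str, float]
    free_energy: float
    fitted: SimResult
    weighted_residuals: np.ndarray
    data: MealResponseData
    obs: ObservationModel
    rap: Optional[PersistingGA]
    insulin: Optional[InsulinInterpolant]
    n_starts: int
    n_converged: int
    best_start: int
    degenerate_cov: bool = False

    @property
    def params(self):
        """Full parameter object at the posterior median."""
        return self.param_map.build_params(self.mode)

    def interval(self, name: str, level: float = 0.95):
        """Equal-tailed credible interval on the natural scale."""
        i = self.param_map.names.index(name)
        z = float(-_norm_ppf((1.0 - level) / 2.0))
        s = math.sqrt(max(self.cov[i, i], 0.0))
        lo = self.param_map.priors[name].to_natural(self.mode[i] - z * s)
        hi = self.param_map.priors[name].to_natural(self.mode[i] + z * s)
        return lo, hi

    def summary(self) -> Dict[str, Dict[str, float]]:
        return {
            n: {"median": self.medians[n], "cv": self.cvs[n]}
            for n in self.param_map.names
        }


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


def _posterior_from_mode(pmap, theta, cov):
    medians, cvs = {}, {}
    for i, name in enumerate(pmap.names):
        prior = pmap.priors[name]
        medians[name] = prior.to_natural(theta[i])
        sigma = math.sqrt(max(cov[i, i], 0.0))
        cvs[name] = prior.cv_from_sigma(sigma, mu=theta[i]) if sigma > 0 else 0.0
    return medians, cvs


def fit_meal(
    data: MealResponseData,
    priors: Optional[Dict[str, ParamPrior]] = None,
    obs: Optional[ObservationModel] = None,
    model: str = "gom",
    rap: Optional[PersistingGA] = None,
    init: Optional[Dict[str, float]] = None,
    n_starts: int = 5,
    seed: int = 0,
    include_likelihood: bool = True,
    rtol: float = 1e-6,
    alpha: float = DEFAULT_ALPHA,
    v: float = DEFAULT_V,
    gb: Optional[float] = None,
    noise_cv: float = 0.02,
) -> PosteriorResult:
    """Fit one meal response, returning the Gaussian posterior approximation.

    Parameters
    ----------
    data
        The sampled response; must include insulin when ``model="omm"``.
    priors
        Median/CV priors per free parameter; defaults to the module
        defaults for the chosen model.
    obs
        Known per-sample glucose measurement SDs; defaults to
        ``noise_cv`` x measured value.
    rap
        Persisting GA from earlier meals (``None`` for the first meal).
    init
        Initial conditions ``{"G0": ..., "X0": ...}``; defaults to the
        glucose observed at t = 0 and zero action.
    include_likelihood
        With ``False`` only the prior term is optimised — a diagnostic
        mode in which the posterior must reproduce the prior.

    The optimisation is deterministic given ``seed``: restart 0 starts at
    the prior medians, the remaining ``n_starts - 1`` at draws from the
    prior.  The restart with the lowest cost (highest free energy) wins.
    """
    if model not in ("gom", "omm"):
        raise ValueError(f"unknown model {model!r}")
    if model == "omm" and data.insulin is None:
        raise DataError(
            "the oral minimal model needs insulin data; this response has none "
            "(fit the glucose-only model instead)"
        )

    t_fit = data.fit_times
    g_fit = data.fit_glucose
    if obs is None:
        obs = ObservationModel.from_cv(g_fit, cv=noise_cv)
    sd = np.asarray(obs.sd, dtype=float)
    if sd.size != t_fit.size:
        raise ValueError("observation model must give one SD per fitted sample")

    if gb is None:
        gb = compute_gb(data) if -15.0 in data.times else float(g_fit[0])
    g0 = float(init["G0"]) if init and "G0" in init else float(g_fit[0])
    x0 = float(init["X0"]) if init and "X0" in init else 0.0

    insulin = None
    ib = 0.0
    if model == "omm":
        insulin = InsulinInterpolant(data.times, data.insulin)
        # basal insulin: mean of the same pre/early samples used for Gb,
        # falling back to the first sample when -15 min is absent
        mask = np.isin(data.times, _GB_SAMPLE_TIMES)
        ib = float(np.mean(data.insulin[mask])) if mask.any() else float(data.insulin[0])

    if priors is None:
        priors = default_gom_priors() if model == "gom" else default_omm_priors(data.meal.A)

    if model == "gom":
        pmap = ParameterMap.for_gom(priors, gb=gb, g0=g0, x0=x0, A=data.meal.A,
                                    alpha=alpha, v=v)
    else:
        pmap = ParameterMap.for_omm(priors, gb=gb, ib=ib, g0=g0, x0=x0, A=data.meal.A, v=v)

    mu, sig = pmap.prior_mu, pmap.prior_sigma
    n_data = t_fit.size

    def residuals(theta):
        prior_part = (theta - mu) / sig
        if not include_likelihood:
            return prior_part
        try:
            sim = _simulate_theta(pmap, theta, t_fit, rap, insulin, rtol)
            data_part = (g_fit - sim.glucose) / sd
        except (InfeasibleAUCError, IntegrationError, ValueError, OverflowError):
            data_part = np.full(n_data, 1e6)
        return np.concatenate((data_part, prior_part))

    rng = np.random.default_rng(seed)
    starts = [mu.copy()]
    for _ in range(max(0, n_starts - 1)):
        starts.append(mu + sig * rng.standard_normal(pmap.n))

    best = None
    best_cost = np.inf
    best_idx = -1
    n_converged = 0
    for k, x0_start in enumerate(starts):
        try:
            sol = least_squares(
                residuals, x0_start, method="trf", x_scale=sig,
                ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=400,
            )
        except Exception as exc:  # noqa: BLE001 - restart-level robustness
            logger.warning("restart %d raised %s", k, exc)
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        n_converged += 1
        if sol.cost < best_cost:
            best, best_cost, best_idx = sol, sol.cost, k
    if best is None:
        raise EstimationError(
            f"no restart converged for {data.subject_id} meal {data.meal_index}"
        )

    theta_hat = best.x

    # posterior curvature: central-difference Hessian of the negative log
    # joint on the transformed scale, with the Gauss-Newton curvature
    # J^T J as a fallback when the exact Hessian is not positive definite
    # (the two coincide for zero residuals and for the prior-only mode)
    def negloglp(theta):
        r = residuals(theta)
        return 0.5 * float(r @ r)

    H = _central_hessian(negloglp, theta_hat, 0.05 * sig)
    H_gn = best.jac.T @ best.jac
    degenerate = False
    if not _is_pos_def(H):
        H = H_gn
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0.0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        degenerate = True
        cov = np.linalg.pinv(H_gn)
        logger.warning("degenerate posterior curvature for %s meal %d",
                       data.subject_id, data.meal_index)
    cov = 0.5 * (cov + cov.T)

    lp = log_joint(theta_hat, data, pmap, obs, rap=rap, insulin=insulin, rtol=rtol) \
        if include_likelihood else _prior_only_logp(theta_hat, mu, sig)
    sign, logdet = np.linalg.slogdet(H)
    free_energy = lp + 0.5 * pmap.n * math.log(2.0 * math.pi) - 0.5 * (logdet if sign > 0 else np.inf)

    medians, cvs = _posterior_from_mode(pmap, theta_hat, cov)
    fitted = _simulate_theta(pmap, theta_hat, t_fit, rap, insulin, rtol)
    wres = (g_fit - fitted.glucose) / sd

    return PosteriorResult(
        model=model, param_map=pmap, mode=theta_hat, cov=cov,
        medians=medians, cvs=cvs, free_energy=float(free_energy),
        fitted=fitted, weighted_residuals=wres, data=data, obs=obs,
        rap=rap, insulin=insulin, n_starts=len(starts),
        n_converged=n_converged, best_start=best_idx,
        degenerate_cov=degenerate,
    )


def _central_hessian(f, x, steps):
    """Symmetric central-difference Hessian with per-coordinate steps."""
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        hi = steps[i]
        ei = np.zeros(n); ei[i] = hi
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (hi * hi)
        for j in range(i + 1, n):
            hj = steps[j]
            ej = np.zeros(n); ej[j] = hj
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * hi * hj)
    return H


def _is_pos_def(H):
    if not np.all(np.isfinite(H)):
        return False
    try:
        np.linalg.cholesky(H)
        return True
    except np.linalg.LinAlgError:
        return False


def _prior_only_logp(theta, mu, sig):
    z = (theta - mu) / sig
    return -0.5 * float(z @ z) - float(np.sum(np.log(sig * math.sqrt(2.0 * math.pi))))


def chain_day(
    meals: Sequence[MealResponseData],
    priors: Optional[Dict[str, ParamPrior]] = None,
    model: str = "gom",
    noise_cv: float = 0.02,
    meal_spacing: float = RESPONSE_DURATION_MIN,
    **fit_kwargs,
) -> List[Optional[PosteriorResult]]:
    """Fit the consecutive meals of one day with state carry-over.

    Meal 1 starts from the observed glucose at t = 0 with zero action and
    no persisting GA.  Each later meal inherits ``G0`` and ``X0`` from the
    previous fit's posterior-median trajectory at the meal time, and the
    fitted GA functions of all earlier meals persist as ``Rap``.  Basal
    glucose is computed once from the first meal and held fixed.

    A failed fit is recorded as ``None``; later meals fall back to
    observed initial conditions and whatever persisting GA is available.
    """
    meals = list(meals)
    if not meals:
        raise ValueError("need at least one meal response")
    gb = compute_gb(meals[0]) if -15.0 in meals[0].times else float(meals[0].fit_glucose[0])

    results: List[Optional[PosteriorResult]] = []
    fitted_gas: List[Optional[object]] = []
    init = None
    for k, meal in enumerate(meals):
        offsets = [(meal_spacing * (k - j), fitted_gas[j])
                   for j in range(k) if fitted_gas[j] is not None]
        rap = PersistingGA.from_previous(offsets) if offsets else PersistingGA.none()
        obs = ObservationModel.from_cv(meal.fit_glucose, cv=noise_cv)
        try:
            res = fit_meal(meal, priors=priors, obs=obs, model=model, rap=rap,
                           init=init, gb=gb, **fit_kwargs)
        except (EstimationError, DataError) as exc:
            logger.warning("meal %d fit failed: %s", k + 1, exc)
            results.append(None)
            fitted_gas.append(None)
            init = None  # next meal falls back to observed G0, X0 = 0
            continue
        results.append(res)
        fitted_gas.append(res.params.ga)
        # carry the posterior-median state to the next meal time
        sim = simulate(model, res.params, np.asarray([0.0, meal_spacing]),
                       rap=rap, insulin=res.insulin)
        # X can transiently dip just below zero when Z goes sub-basal;
        # the next meal's initial action is clamped to the admissible range
        init = {"G0": float(sim.glucose[-1]), "X0": max(0.0, float(sim.action[-1]))}
    return results
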