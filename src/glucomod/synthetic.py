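"""Synthetic cohorts of meal days for testing and parameter recovery.

The generator emulates the structure of a controlled meal-study day in
subjects with normal glucose tolerance: three identical meals eaten four
hours apart, blood sampled on a fixed schedule after each meal (plus one
fasting sample 15 min before breakfast), additive Gaussian glucose
measurement noise of known SD, and insulin profiles consistent with a
13 % assay CV.  True parameters are drawn from log-normal population
distributions centred on the estimation defaults, glucose is simulated
from the glucose-only model with inter-meal carry-over, and the truth is
kept alongside the data so recovery can be scored.

The insulin synthesiser (a lagged, scaled positive glucose excursion) is
an internal device to give the oral minimal model a plausible input; it
is not itself a physiological model of insulin secretion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .data import (
    FASTING_SAMPLE_MIN,
    MEAL_SCHEDULE_MIN,
    MealResponseData,
    MealSpec,
    ObservationModel,
    RESPONSE_DURATION_MIN,
)
from .estimation import EstimationError, PosteriorResult, fit_meal
from .ga import PersistingGA, RaLN, RaPL, solve_last_height, InfeasibleAUCError
from .models import DEFAULT_ALPHA, DEFAULT_V, GomParams, OmmParams, simulate, z_pos
from .priors import (
    ParamPrior,
    default_gom_priors,
    logitnormal_sigma_from_cv,
    lognormal_sigma_from_cv,
)
from .validation import ProfileBand, ci_profile, overlap_share, rmse

__all__ = [
    "CohortConfig",
    "SyntheticSubject",
    "SyntheticDay",
    "draw_subject",
    "synth_insulin",
    "make_day",
    "generate_cohort",
    "recovery_experiment",
    "RecoveryReport",
    "UnphysiologicalTrajectoryError",
]

logger = logging.getLogger(__name__)

#: Carbohydrate dose per meal (g per kg body weight) by meal type and sex.
CHO_DOSE = {
    "STAND": {"male": 1.2, "female": 1.1},
    "HCHO": {"male": 2.0, "female": 1.8},
}

#: Body weight (kg): mean and spread by sex, typical of a young NGT cohort.
BODY_WEIGHT = {"male": (76.0, 5.0), "female": (59.0, 4.0)}


class UnphysiologicalTrajectoryError(RuntimeError):
    """A simulated day left the plausible glucose range (0, 500) mg/dL."""


@dataclass(frozen=True)
class CohortConfig:
    """Population and protocol settings for the synthetic generator.

    True parameters are log-normal around the estimation priors' medians
    with population CV ``pop_cv`` (``sg_pop_cv`` for the sensitivity
    surrogate, wider to create real heterogeneity).  The insulin
    synthesiser maps the lagged positive glucose excursion to supra-basal
    insulin with gain ``insulin_gain`` (mU/L per mg/dL) and lag
    ``insulin_tau`` (min) around a basal level ``ib`` (mU/L).
    """

    meal_type: str = "STAND"
    pop_cv: float = 0.30
    sg_pop_cv: float = 0.50
    # beta varies with the estimator's narrow prior: it is a unit-conversion
    # factor, not a subject-level trait, and a population wider than that
    # prior would make the SG posteriors systematically miscalibrated
    beta_pop_cv: float = 0.10
    gb_mean: float = 90.0     # mg/dL
    gb_sd: float = 5.0        # mg/dL
    p_female: float = 0.4
    bioavailability: float = 0.9
    noise_cv: float = 0.02
    insulin_gain: float = 0.6   # mU/L per mg/dL
    insulin_tau: float = 15.0   # min
    ib: float = 8.0             # mU/L
    insulin_cv: float = 0.13
    alpha: float = DEFAULT_ALPHA
    v: float = DEFAULT_V
    n_meals: int = 3


@dataclass(frozen=True)
class SyntheticSubject:
    """A simulated study participant with known true parameters."""

    subject_id: str
    sex: str
    body_weight: float
    meal_type: str
    true_gom: GomParams
    true_omm: OmmParams
    meals: tuple  # MealSpec per meal, identical composition 240 min apart
    config: CohortConfig


@dataclass
class SyntheticDay:
    """One simulated meal day: sampled responses plus the dense truth."""

    subject: SyntheticSubject
    meals: List[MealResponseData]
    t_dense: np.ndarray        # minutes since day start
    glucose_dense: np.ndarray  # noise-free G(t), mg/dL
    insulin_dense: np.ndarray  # noise-free synthetic I(t), mU/L
    noise_cv: float
    seed: int


def _pop_priors(config: CohortConfig) -> Dict[str, ParamPrior]:
    base = default_gom_priors()
    out = {}
    for name, prior in base.items():
        if name == "sg":
            cv = config.sg_pop_cv
        elif name == "beta":
            cv = config.beta_pop_cv
        else:
            cv = config.pop_cv
        out[name] = replace(prior, cv=cv)
    return out


def draw_subject(
    seed: int,
    meal_type: str = "STAND",
    config: Optional[CohortConfig] = None,
    subject_id: Optional[str] = None,
) -> SyntheticSubject:
    """Draw one subject reproducibly from the population distributions."""
    if meal_type not in CHO_DOSE:
        raise ValueError(f"unknown meal type {meal_type!r}; expected STAND or HCHO")
    config = config or CohortConfig(meal_type=meal_type)
    if config.meal_type != meal_type:
        config = replace(config, meal_type=meal_type)
    rng = np.random.default_rng(seed)

    sex = "female" if rng.random() < config.p_female else "male"
    w_mean, w_sd = BODY_WEIGHT[sex]
    weight = float(np.clip(rng.normal(w_mean, w_sd), 40.0, 120.0))
    gb = float(np.clip(rng.normal(config.gb_mean, config.gb_sd), 60.0, 110.0))

    dose = CHO_DOSE[meal_type][sex]
    meals = tuple(
        MealSpec(t_meal=RESPONSE_DURATION_MIN * m, cho_dose=dose,
                 bioavailability=config.bioavailability)
        for m in range(config.n_meals)
    )
    A = meals[0].A

    pop = _pop_priors(config)
    nat: Dict[str, float] = {}
    for name, prior in pop.items():
        z = rng.standard_normal()
        nat[name] = prior.to_natural(prior.mu + prior.sigma * z)
    # keep the late GA component later than the early one
    if nat["T2"] <= nat["T1"]:
        nat["T1"], nat["T2"] = nat["T2"], nat["T1"]

    ga = RaLN(A=A, RH=nat["RH"], T1=nat["T1"], W1=nat["W1"], T2=nat["T2"], W2=nat["W2"])
    true_gom = GomParams(
        p1=nat["p1"], p2=nat["p2"], sg=nat["sg"], beta=nat["beta"],
        gb=gb, g0=gb, x0=0.0, ga=ga, alpha=config.alpha, v=config.v,
    )
    true_omm = _paired_omm(true_gom, config)
    return SyntheticSubject(
        subject_id=subject_id or f"S{seed}",
        sex=sex, body_weight=weight, meal_type=meal_type,
        true_gom=true_gom, true_omm=true_omm, meals=meals, config=config,
    )


def _paired_omm(gom: GomParams, config: CohortConfig) -> OmmParams:
    """A consistent OMM truth: SI scaled from SG through the insulin gain,
    and a piecewise-linear GA tracing the log-normal one at the breakpoints."""
    bt = (10.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0)
    first_six = [gom.ga.rate(t) for t in bt[:6]]
    try:
        h7 = solve_last_height(first_six, bt, gom.ga.A)
        ga = RaPL(A=gom.ga.A, heights=tuple(first_six + [h7]), break_times=bt)
    except InfeasibleAUCError:
        flat = gom.ga.A / 235.0
        ga = RaPL.from_free_heights([flat] * 6, A=gom.ga.A, break_times=bt)
    return OmmParams(
        p1=gom.p1, p2=gom.p2, si=gom.sg / config.insulin_gain,
        gb=gom.gb, ib=config.ib, g0=gom.g0, x0=gom.x0, ga=ga, v=gom.v,
    )


def synth_insulin(
    t_dense: np.ndarray,
    glucose_dense: np.ndarray,
    gb: float,
    seed: int = 0,
    gain: float = 0.6,
    tau: float = 15.0,
    ib: float = 8.0,
    cv: float = 0.13,
    sample_times: Optional[np.ndarray] = None,
):
    """Synthesise an insulin profile from a dense glucose trajectory.

    The noise-free profile is ``I(t) = Ib + gain * y(t)`` where ``y`` is the
    positive supra-basal glucose excursion passed through a first-order lag
    of time constant ``tau`` (an exponential integrator on the dense grid;
    ``tau = 0`` means no lag).  Samples, if requested, are perturbed with
    multiplicative Gaussian noise of coefficient of variation ``cv``.

    Returns ``(insulin_dense, insulin_samples)``; the second element is
    ``None`` when no sample times are given.
    """
    t = np.asarray(t_dense, dtype=float)
    g = np.asarray(glucose_dense, dtype=float)
    u = np.maximum(g - gb, 0.0)
    if tau <= 1e-9:
        y = u.copy()
    else:
        y = np.zeros_like(u)
        for i in range(1, t.size):
            dt = t[i] - t[i - 1]
            decay = math.exp(-dt / tau)
            u_mid = 0.5 * (u[i - 1] + u[i])
            y[i] = y[i - 1] * decay + u_mid * (1.0 - decay)
    dense = ib + gain * y
    if sample_times is None:
        return dense, None
    rng = np.random.default_rng(seed)
    st = np.asarray(sample_times, dtype=float)
    clean = np.interp(st, t, dense)
    noisy = clean * (1.0 + cv * rng.standard_normal(st.size)) if cv > 0 else clean
    return dense, np.maximum(noisy, 0.5)


def make_day(
    subject: SyntheticSubject,
    schedule: Sequence[float] = MEAL_SCHEDULE_MIN,
    noise_cv: float = 0.02,
    seed: int = 0,
    dense_step: float = 1.0,
) -> SyntheticDay:
    """Simulate one full day and sample it at the study schedule.

    The glucose-only model is integrated meal by meal; the state is
    carried across meal boundaries and each earlier meal's GA function
    persists into later responses.  Shared time points (a meal's 240-min
    sample doubles as the next meal's 0-min sample) are drawn once.
    Raises :class:`UnphysiologicalTrajectoryError` if any sampled or dense
    glucose value leaves (0, 500) mg/dL.
    """
    config = subject.config
    params = subject.true_gom
    n_meals = len(subject.meals)
    rng = np.random.default_rng(seed)

    t_local = np.arange(0.0, RESPONSE_DURATION_MIN + dense_step / 2, dense_step)
    t_all: List[np.ndarray] = []
    g_all: List[np.ndarray] = []
    g0, x0 = params.g0, params.x0
    for m in range(n_meals):
        offsets = [(RESPONSE_DURATION_MIN * (m - j), subject.true_gom.ga) for j in range(m)]
        rap = PersistingGA.from_previous(offsets) if offsets else PersistingGA.none()
        seg_params = replace(params, g0=g0, x0=x0)
        sim = simulate("gom", seg_params, t_local, rap=rap)
        t_abs = t_local + RESPONSE_DURATION_MIN * m
        if m > 0:  # drop the duplicated boundary point
            t_abs, g_seg = t_abs[1:], sim.glucose[1:]
        else:
            g_seg = sim.glucose
        t_all.append(t_abs)
        g_all.append(g_seg)
        # X dips marginally below zero after sub-basal excursions; the next
        # segment's initial action is clamped to the admissible range
        g0, x0 = float(sim.glucose[-1]), max(0.0, float(sim.action[-1]))

    t_dense = np.concatenate(([FASTING_SAMPLE_MIN], *t_all))
    g_dense = np.concatenate(([params.gb], *g_all))
    if np.any(g_dense <= 0.0) or np.any(g_dense >= 500.0):
        raise UnphysiologicalTrajectoryError(
            f"{subject.subject_id}: dense glucose left (0, 500) mg/dL"
        )

    # one blood draw per unique absolute time
    abs_times = [FASTING_SAMPLE_MIN]
    for m in range(n_meals):
        for rel in schedule:
            t_abs = RESPONSE_DURATION_MIN * m + rel
            if t_abs not in abs_times:
                abs_times.append(t_abs)
    abs_times = np.asarray(sorted(abs_times))
    clean = np.interp(abs_times, t_dense, g_dense)
    noise = rng.standard_normal(abs_times.size) if noise_cv > 0 else np.zeros(abs_times.size)
    measured = clean + noise_cv * clean * noise
    if np.any(measured <= 0.0) or np.any(measured >= 500.0):
        raise UnphysiologicalTrajectoryError(
            f"{subject.subject_id}: sampled glucose left (0, 500) mg/dL"
        )
    glucose_by_time = dict(zip(abs_times, measured))

    insulin_dense, insulin_samples = synth_insulin(
        t_dense, g_dense, params.gb, seed=seed + 1,
        gain=config.insulin_gain, tau=config.insulin_tau, ib=config.ib,
        cv=config.insulin_cv, sample_times=abs_times,
    )
    insulin_by_time = dict(zip(abs_times, insulin_samples))

    meals: List[MealResponseData] = []
    for m in range(n_meals):
        rel_times = list(schedule)
        if m == 0:
            rel_times = [FASTING_SAMPLE_MIN] + rel_times
        rel_times = np.asarray(sorted(rel_times))
        t_abs = rel_times + RESPONSE_DURATION_MIN * m
        meals.append(
            MealResponseData(
                times=rel_times,
                glucose=np.asarray([glucose_by_time[t] for t in t_abs]),
                insulin=np.asarray([insulin_by_time[t] for t in t_abs]),
                meal=subject.meals[m],
                subject_id=subject.subject_id,
                meal_index=m + 1,
            )
        )
    return SyntheticDay(
        subject=subject, meals=meals, t_dense=t_dense,
        glucose_dense=g_dense, insulin_dense=insulin_dense,
        noise_cv=noise_cv, seed=seed,
    )


def generate_cohort(
    n_subjects: int,
    seed: int = 1,
    meal_type: str = "STAND",
    noise_cv: float = 0.02,
    config: Optional[CohortConfig] = None,
    max_redraws: int = 20,
) -> List[SyntheticDay]:
    """Generate ``n_subjects`` valid meal days, resampling rejected draws.

    Draws whose simulated glucose leaves the plausible range are rejected
    and redrawn with a shifted sub-seed; every rejection is logged.
    """
    days: List[SyntheticDay] = []
    attempt = 0
    i = 0
    while len(days) < n_subjects:
        sub_seed = seed + 1000 * (i + 1) + attempt
        try:
            subject = draw_subject(sub_seed, meal_type=meal_type, config=config,
                                   subject_id=f"S{i + 1:02d}")
            days.append(make_day(subject, noise_cv=noise_cv, seed=sub_seed + 500))
            i += 1
            attempt = 0
        except UnphysiologicalTrajectoryError as exc:
            attempt += 1
            logger.warning("rejected draw (attempt %d): %s", attempt, exc)
            if attempt > max_redraws:
                raise
    return days


@dataclass
class RecoveryReport:
    """Scores from fitting the generator's output back with the estimator."""

    rows: List[Dict[str, float]] = field(default_factory=list)
    n_failed: int = 0
    param_names: tuple = ()

    @property
    def sg_true(self) -> np.ndarray:
        return np.asarray([r["true_sg"] for r in self.rows])

    @property
    def sg_est(self) -> np.ndarray:
        return np.asarray([r["est_sg"] for r in self.rows])

    @property
    def sg_pearson_r(self) -> float:
        r, _ = stats.pearsonr(self.sg_true, self.sg_est)
        return float(r)

    @property
    def sg_coverage(self) -> float:
        """Fraction of responses whose 95 % interval covers the true SG."""
        return float(np.mean([r["sg_covered"] for r in self.rows]))

    def median_abs_rel_bias(self) -> Dict[str, float]:
        out = {}
        for name in self.param_names:
            rel = [abs(r[f"est_{name}"] / r[f"true_{name}"] - 1.0) for r in self.rows]
            out[name] = float(np.median(rel))
        return out

    def mean_rmse(self) -> float:
        return float(np.mean([r["rmse"] for r in self.rows]))

    def mean_ol_true_ga(self) -> float:
        return float(np.mean([r["ol_true_ga"] for r in self.rows]))

    def summary(self) -> Dict[str, object]:
        return {
            "n_fitted": len(self.rows),
            "n_failed": self.n_failed,
            "sg_pearson_r": self.sg_pearson_r,
            "sg_coverage": self.sg_coverage,
            "mean_rmse_mgdl": self.mean_rmse(),
            "mean_ol_true_ga": self.mean_ol_true_ga(),
            "median_abs_rel_bias": self.median_abs_rel_bias(),
        }


def recovery_experiment(
    n_subjects: int = 20,
    seed: int = 1,
    meal_type: str = "STAND",
    noise_cv: float = 0.02,
    config: Optional[CohortConfig] = None,
    priors: Optional[Dict[str, ParamPrior]] = None,
    meals_per_subject: int = 1,
    n_starts: int = 5,
    n_band_draws: int = 300,
) -> RecoveryReport:
    """Generate a cohort, refit it, and score parameter recovery.

    For each subject the first ``meals_per_subject`` responses are fitted
    with the glucose-only model under the default priors, and the
    estimates are compared with the generating truth: Pearson correlation
    of true versus estimated SG, 95 %-interval coverage, per-parameter
    relative bias, fit RMSE, and the overlap share between the fitted GA
    band and the true GA curve.  Individual fit failures are logged,
    counted and excluded.
    """
    if n_subjects < 5:
        raise ValueError("a recovery experiment needs at least five subjects")
    days = generate_cohort(n_subjects, seed=seed, meal_type=meal_type,
                           noise_cv=noise_cv, config=config)
    report = RecoveryReport(param_names=("p1", "p2", "sg", "beta", "T1", "T2", "W1", "W2", "RH"))
    for idx, day in enumerate(days):
        truth = day.subject.true_gom
        true_nat = {
            "p1": truth.p1, "p2": truth.p2, "sg": truth.sg, "beta": truth.beta,
            "T1": truth.ga.T1, "T2": truth.ga.T2, "W1": truth.ga.W1,
            "W2": truth.ga.W2, "RH": truth.ga.RH,
        }
        for meal in day.meals[:meals_per_subject]:
            try:
                fit = fit_meal(meal, priors=priors, model="gom",
                               noise_cv=noise_cv if noise_cv > 0 else 0.02,
                               n_starts=n_starts, seed=seed + 37 * idx + meal.meal_index)
            except EstimationError as exc:
                logger.warning("fit failed for %s meal %d: %s",
                               day.subject.subject_id, meal.meal_index, exc)
                report.n_failed += 1
                continue
            lo, hi = fit.interval("sg", 0.95)
            band = ci_profile(fit, "raln", n_draws=n_band_draws,
                              seed=seed + 1000 + idx)
            true_curve = truth.ga.rate_grid(band.t)
            true_band = ProfileBand(t=band.t, median=true_curve,
                                    lower=true_curve.copy(), upper=true_curve.copy(),
                                    units="mg/kg/min")
            row = {
                "subject_id": day.subject.subject_id,
                "meal_index": meal.meal_index,
                "rmse": rmse(fit, meal),
                "sg_covered": float(lo <= truth.sg <= hi),
                "sg_cv": fit.cvs["sg"],
                "ol_true_ga": overlap_share(band, true_band),
            }
            for name, tv in true_nat.items():
                row[f"true_{name}"] = tv
                row[f"est_{name}"] = fit.medians[name]
            report.rows.append(row)
    return report
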