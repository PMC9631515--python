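"""Cross-model validation: residual diagnostics, RMSE, sensitivity
agreement and confidence-band overlap statistics.

The glucose-only model is validated against the insulin-based oral
minimal model fitted to the same responses, on four axes: (1) weighted
residuals and RMSE of the glucose fit, (2) agreement of the sensitivity
parameters SG and SI, (3) overlap of the 95 % confidence bands of the two
GA profiles, and (4) overlap of the bands of the insulin-action drives
Y_OMM = SI (I - Ib) and Y_GOM = SG Z.  Band overlap is summarised as the
share of the 240-min response during which the bands intersect (the OL
value), computed on a 1-min grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .data import MealResponseData, ObservationModel, RESPONSE_DURATION_MIN
from .estimation import PosteriorResult
from .models import simulate, z_pos

__all__ = [
    "ProfileBand",
    "weighted_residuals",
    "rmse",
    "ci_profile",
    "overlap_share",
    "compare_sensitivity",
    "y_profiles",
    "ComparisonReport",
    "INSULIN_ASSAY_CV",
]

logger = logging.getLogger(__name__)

#: Reported coefficient of variation of the insulin assay, used to
#: propagate insulin measurement error into the Y_OMM band.
INSULIN_ASSAY_CV = 0.13

_GRID = np.arange(0.0, RESPONSE_DURATION_MIN + 1.0)  # 1-min grid, endpoints inclusive


@dataclass
class ProfileBand:
    """A time-gridded curve with a pointwise credible band.

    ``units`` is mg/kg/min for GA profiles and min^-1 for the
    insulin-action drives.
    """

    t: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("median", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if any(getattr(self, k).size != n for k in ("median", "lower", "upper")):
            raise ValueError("band curves must share the time grid")
        tol = 1e-9 * (1.0 + np.abs(self.median))
        if np.any(self.lower > self.median + tol) or np.any(self.median > self.upper + tol):
            raise ValueError("band must satisfy lower <= median <= upper pointwise")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def weighted_residuals(
    fit: PosteriorResult, data: MealResponseData, obs: Optional[ObservationModel] = None
) -> np.ndarray:
    """(observed - model) / SD at the sample times; model above data is negative."""
    if obs is None:
        obs = fit.obs
    return (data.fit_glucose - fit.fitted.glucose) / np.asarray(obs.sd, dtype=float)


def rmse(fit: PosteriorResult, data: MealResponseData) -> float:
    """Root mean squared residual of the glucose fit, mg/dL (unweighted)."""
    r = data.fit_glucose - fit.fitted.glucose
    return float(np.sqrt(np.mean(r * r)))


def _draw_thetas(posterior: PosteriorResult, n_draws: int, rng) -> Tuple[np.ndarray, bool]:
    cov = posterior.cov
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return posterior.mode[None, :], True
    z = rng.standard_normal((n_draws, cov.shape[0]))
    return posterior.mode[None, :] + z @ chol.T, False


def ci_profile(
    posterior: PosteriorResult,
    curve: str,
    level: float = 0.95,
    n_draws: int = 2000,
    seed: int = 0,
    t_grid: Optional[np.ndarray] = None,
    insulin_cv: float = INSULIN_ASSAY_CV,
) -> ProfileBand:
    """Pointwise credible band of a fitted time profile.

    ``curve`` is one of ``"raln"``/``"rapl"`` (the GA profile of the
    respective model), ``"y_gom"`` (SG Z(t) along re-simulated posterior
    draws) or ``"y_omm"`` (SI (I(t) - Ib) with the insulin samples
    perturbed per draw by independent Gaussian noise of CV ``insulin_cv``).
    Draws come from the Gaussian posterior on the transformed scale; a
    degenerate covariance collapses the band onto the median curve with a
    warning.
    """
    if t_grid is None:
        t_grid = _GRID
    t_grid = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    thetas, degenerate = _draw_thetas(posterior, n_draws, rng)
    if degenerate:
        logger.warning("degenerate posterior covariance: returning a median-only band")

    pmap = posterior.param_map
    units = "mg/kg/min" if curve in ("raln", "rapl") else "1/min"
    curves = np.empty((thetas.shape[0], t_grid.size))
    n_bad = 0
    for i, theta in enumerate(thetas):
        try:
            params = pmap.build_params(theta)
            if curve in ("raln", "rapl"):
                curves[i] = params.ga.rate_grid(t_grid)
            elif curve == "y_gom":
                sim = simulate("gom", params, t_grid, rap=posterior.rap)
                curves[i] = sim.y
            elif curve == "y_omm":
                if posterior.insulin is None:
                    raise ValueError("y_omm requires insulin data")
                ins_t = posterior.insulin.times
                ins_v = posterior.insulin.values
                noisy = ins_v * (1.0 + insulin_cv * rng.standard_normal(ins_v.size))
                grid_i = np.interp(t_grid, ins_t, noisy)
                curves[i] = params.si * (grid_i - pmap.ib)
            else:
                raise ValueError(f"unknown curve {curve!r}")
        except ValueError:
            if curve in ("y_omm",) and posterior.insulin is None:
                raise
            curves[i] = np.nan
            n_bad += 1
    if n_bad:
        logger.warning("%d/%d posterior draws were infeasible and dropped",
                       n_bad, thetas.shape[0])
    valid = curves[~np.isnan(curves).any(axis=1)]
    if valid.shape[0] == 0:
        raise ValueError("no feasible posterior draws for the requested curve")
    if degenerate or valid.shape[0] == 1:
        med = valid[0]
        return ProfileBand(t=t_grid, median=med, lower=med.copy(), upper=med.copy(), units=units)
    q = (1.0 - level) / 2.0
    lower, med, upper = np.quantile(valid, [q, 0.5, 1.0 - q], axis=0)
    return ProfileBand(t=t_grid, median=med, lower=lower, upper=upper, units=units)


def overlap_share(band_a: ProfileBand, band_b: ProfileBand) -> float:
    """Share of the response during which two 95 % bands intersect (OL).

    Evaluated on the bands' common 1-min grid, endpoints inclusive: the
    fraction of grid points where the vertical intervals overlap.
    """
    if band_a.t.size != band_b.t.size or not np.allclose(band_a.t, band_b.t):
        raise ValueError("bands must share the same time grid")
    hit = (band_a.lower <= band_b.upper) & (band_b.lower <= band_a.upper)
    return float(np.mean(hit))


def compare_sensitivity(
    sg_values: Sequence[float],
    si_values: Sequence[float],
    sg_cvs: Optional[Sequence[float]] = None,
    si_cvs: Optional[Sequence[float]] = None,
    groups: Optional[Sequence[str]] = None,
) -> Dict[str, object]:
    """Correlation and linear regression between paired SG and SI estimates.

    Returns the Pearson correlation of the posterior medians, the ordinary
    least-squares line, optional per-group summaries, and — when posterior
    CVs are supplied — the one-sigma log-normal ranges for plotting.
    """
    sg = np.asarray(sg_values, dtype=float)
    si = np.asarray(si_values, dtype=float)
    if sg.size != si.size:
        raise ValueError("SG and SI estimates must be paired")
    if sg.size < 3:
        raise ValueError("need at least three pairs for a correlation analysis")
    r, p = stats.pearsonr(sg, si)
    reg = stats.linregress(sg, si)
    out: Dict[str, object] = {
        "n": int(sg.size),
        "pearson_r": float(r),
        "p_value": float(p),
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
    }
    for label, vals, cvs in (("sg", sg, sg_cvs), ("si", si, si_cvs)):
        if cvs is not None:
            cvs = np.asarray(cvs, dtype=float)
            sigma = np.sqrt(np.log1p(cvs * cvs))
            out[f"{label}_one_sigma"] = np.stack(
                (vals * np.exp(-sigma), vals * np.exp(sigma)), axis=1
            )
    if groups is not None:
        groups = np.asarray(groups)
        by_group = {}
        for g in np.unique(groups):
            m = groups == g
            by_group[str(g)] = {
                "n": int(m.sum()),
                "sg_median": float(np.median(sg[m])),
                "si_median": float(np.median(si[m])),
            }
            if m.sum() >= 3:
                rg, pg = stats.pearsonr(sg[m], si[m])
                by_group[str(g)]["pearson_r"] = float(rg)
                by_group[str(g)]["p_value"] = float(pg)
        out["groups"] = by_group
    return out


def y_profiles(
    fit_gom: PosteriorResult,
    fit_omm: Optional[PosteriorResult],
    n_draws: int = 2000,
    seed: int = 0,
    t_grid: Optional[np.ndarray] = None,
) -> Tuple[ProfileBand, Optional[ProfileBand]]:
    """Bands of the insulin-action drives Y_GOM = SG Z and Y_OMM = SI (I - Ib).

    Both quantities enter dX/dt at the same position, so comparing them
    probes whether the glucose-only surrogate carries insulin-dynamics
    information.  Without an OMM fit (no insulin data) the second band is
    ``None``.
    """
    band_gom = ci_profile(fit_gom, "y_gom", n_draws=n_draws, seed=seed, t_grid=t_grid)
    band_omm = None
    if fit_omm is not None:
        if fit_omm.insulin is None:
            logger.warning("OMM fit has no insulin interpolant; Y_OMM unavailable")
        else:
            band_omm = ci_profile(fit_omm, "y_omm", n_draws=n_draws, seed=seed + 1,
                                  t_grid=t_grid)
    return band_gom, band_omm


@dataclass
class ComparisonReport:
    """Per-response GOM-vs-OMM comparison across a collection of fits."""

    rows: list = field(default_factory=list)

    def add_response(
        self,
        subject_id: str,
        meal_index: int,
        fit_gom: PosteriorResult,
        fit_omm: Optional[PosteriorResult] = None,
        n_draws: int = 500,
        seed: int = 0,
    ) -> Dict[str, object]:
        row: Dict[str, object] = {
            "subject_id": subject_id,
            "meal_index": meal_index,
            "rmse_gom": rmse(fit_gom, fit_gom.data),
            "sg_median": fit_gom.medians["sg"],
            "sg_cv": fit_gom.cvs["sg"],
            "mean_weighted_residual_gom": float(np.mean(fit_gom.weighted_residuals)),
        }
        if fit_omm is not None:
            row["rmse_omm"] = rmse(fit_omm, fit_omm.data)
            row["si_median"] = fit_omm.medians["si"]
            row["si_cv"] = fit_omm.cvs["si"]
            row["mean_weighted_residual_omm"] = float(np.mean(fit_omm.weighted_residuals))
            band_ln = ci_profile(fit_gom, "raln", n_draws=n_draws, seed=seed)
            band_pl = ci_profile(fit_omm, "rapl", n_draws=n_draws, seed=seed + 1)
            row["ol_ga"] = overlap_share(band_ln, band_pl)
            yg, yo = y_profiles(fit_gom, fit_omm, n_draws=n_draws, seed=seed + 2)
            if yo is not None:
                row["ol_y"] = overlap_share(yg, yo)
        self.rows.append(row)
        return row

    def sensitivity_comparison(self) -> Dict[str, object]:
        paired = [r for r in self.rows if "si_median" in r]
        if len(paired) < 3:
            raise ValueError("need at least three paired GOM/OMM responses")
        return compare_sensitivity(
            [r["sg_median"] for r in paired],
            [r["si_median"] for r in paired],
            sg_cvs=[r["sg_cv"] for r in paired],
            si_cvs=[r["si_cv"] for r in paired],
        )

    def rmse_comparison(self) -> Dict[str, float]:
        paired = [r for r in self.rows if "rmse_omm" in r]
        gom = np.asarray([r["rmse_gom"] for r in paired])
        omm = np.asarray([r["rmse_omm"] for r in paired])
        out = {
            "rmse_gom_mean": float(np.mean(gom)),
            "rmse_gom_sd": float(np.std(gom, ddof=1)) if gom.size > 1 else 0.0,
            "rmse_omm_mean": float(np.mean(omm)),
            "rmse_omm_sd": float(np.std(omm, ddof=1)) if omm.size > 1 else 0.0,
        }
        if gom.size > 1:
            t, p = stats.ttest_rel(gom, omm)
            out["paired_t_p_value"] = float(p)
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)
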