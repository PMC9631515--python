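"""Reading and writing meal-response datasets, configuration and results.

The on-disk dataset is a long-format, comma-separated UTF-8 table with a
"." decimal and one row per blood sample:

    subject_id, meal_type, meal_index, time_min, glucose_mgdl,
    insulin_muL (optional), body_weight_kg, cho_g_per_kg

``time_min`` is relative to the meal; -15 is allowed for meal 1 (the
fasting sample).  Configuration is a flat YAML document mapping parameter
names to ``{median, cv}`` plus the model constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .data import DataError, MealResponseData, MealSpec, RESPONSE_DURATION_MIN
from .estimation import PosteriorResult
from .priors import ParamPrior

__all__ = [
    "read_dataset",
    "write_dataset",
    "SubjectRecord",
    "load_config",
    "save_config",
    "posterior_to_dict",
    "save_posteriors",
]

REQUIRED_COLUMNS = (
    "subject_id", "meal_type", "meal_index", "time_min",
    "glucose_mgdl", "body_weight_kg", "cho_g_per_kg",
)
OPTIONAL_COLUMNS = ("insulin_muL",)


@dataclass
class SubjectRecord:
    """All meal responses of one subject, grouped and time-sorted."""

    subject_id: str
    meal_type: str
    body_weight: float
    meals: List[MealResponseData] = field(default_factory=list)

    @property
    def has_insulin(self) -> bool:
        return all(m.insulin is not None for m in self.meals)


def read_dataset(path) -> Dict[str, SubjectRecord]:
    """Read a dataset table into per-subject, per-meal structures.

    Malformed numeric rows are reported with their line numbers; missing
    required columns raise a schema error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path.name}: missing required columns {missing}")
    has_insulin = "insulin_muL" in df.columns

    numeric_cols = ["meal_index", "time_min", "glucose_mgdl",
                    "body_weight_kg", "cho_g_per_kg"]
    if has_insulin:
        numeric_cols.append("insulin_muL")
    bad_lines: List[int] = []
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        # line numbers in the file: header is line 1
        bad_lines.extend((df.index[bad] + 2).tolist())
        df[col] = converted
    if bad_lines:
        raise DataError(
            f"{path.name}: non-numeric values at line(s) {sorted(set(bad_lines))}"
        )

    subjects: Dict[str, SubjectRecord] = {}
    for (sid, meal_idx), grp in df.groupby(["subject_id", "meal_index"], sort=True):
        grp = grp.sort_values("time_min")
        meal_type = str(grp["meal_type"].iloc[0])
        weight = float(grp["body_weight_kg"].iloc[0])
        dose = float(grp["cho_g_per_kg"].iloc[0])
        meal_idx = int(meal_idx)
        spec = MealSpec(t_meal=RESPONSE_DURATION_MIN * (meal_idx - 1), cho_dose=dose)
        insulin = None
        if has_insulin and grp["insulin_muL"].notna().all():
            insulin = grp["insulin_muL"].to_numpy(dtype=float)
        response = MealResponseData(
            times=grp["time_min"].to_numpy(dtype=float),
            glucose=grp["glucose_mgdl"].to_numpy(dtype=float),
            insulin=insulin,
            meal=spec,
            subject_id=str(sid),
            meal_index=meal_idx,
        )
        rec = subjects.setdefault(
            str(sid), SubjectRecord(subject_id=str(sid), meal_type=meal_type,
                                    body_weight=weight)
        )
        rec.meals.append(response)
    for rec in subjects.values():
        rec.meals.sort(key=lambda m: m.meal_index)
    return subjects


def write_dataset(days, path) -> None:
    """Write synthetic meal days (:class:`glucomod.synthetic.SyntheticDay`)
    in the dataset dialect, deterministically ordered."""
    rows = []
    for day in days:
        sub = day.subject
        for meal in day.meals:
            for i, t in enumerate(meal.times):
                row = {
                    "subject_id": sub.subject_id,
                    "meal_type": sub.meal_type,
                    "meal_index": meal.meal_index,
                    "time_min": float(t),
                    "glucose_mgdl": round(float(meal.glucose[i]), 6),
                    "body_weight_kg": round(float(sub.body_weight), 3),
                    "cho_g_per_kg": float(meal.meal.cho_dose),
                }
                if meal.insulin is not None:
                    row["insulin_muL"] = round(float(meal.insulin[i]), 6)
                rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)


def truth_sidecar(days) -> Dict[str, Dict[str, float]]:
    """True generating parameters per subject, for recovery scoring."""
    out = {}
    for day in days:
        p = day.subject.true_gom
        out[day.subject.subject_id] = {
            "p1": p.p1, "p2": p.p2, "sg": p.sg, "beta": p.beta,
            "gb": p.gb, "T1": p.ga.T1, "T2": p.ga.T2,
            "W1": p.ga.W1, "W2": p.ga.W2, "RH": p.ga.RH, "A": p.ga.A,
            "si": day.subject.true_omm.si,
        }
    return out


def load_config(path) -> Dict[str, object]:
    """Load a flat YAML config: priors (name -> {median, cv}) + constants."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out: Dict[str, object] = {"priors": {}, "constants": dict(raw.get("constants", {}))}
    for name, spec in (raw.get("priors") or {}).items():
        transform = "logit" if name == "RH" else spec.get("transform", "log")
        out["priors"][name] = ParamPrior(
            median=float(spec["median"]), cv=float(spec["cv"]), transform=transform
        )
    return out


def save_config(priors: Dict[str, ParamPrior], constants: Dict[str, float], path) -> None:
    doc = {
        "priors": {
            name: {"median": p.median, "cv": p.cv, "transform": p.transform}
            for name, p in priors.items()
        },
        "constants": dict(constants),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def posterior_to_dict(result: PosteriorResult) -> Dict[str, object]:
    """Serialise one meal's posterior as a plain JSON-ready mapping."""
    return {
        "model": result.model,
        "subject_id": result.data.subject_id,
        "meal_index": result.data.meal_index,
        "parameters": result.summary(),
        "covariance_transformed_scale": result.cov.tolist(),
        "free_energy": result.free_energy,
        "diagnostics": {
            "n_starts": result.n_starts,
            "n_converged": result.n_converged,
            "best_start": result.best_start,
            "degenerate_cov": result.degenerate_cov,
            "rmse_mgdl": float(np.sqrt(np.mean(
                (result.data.fit_glucose - result.fitted.glucose) ** 2
            ))),
        },
        "constants": {
            "gb": result.param_map.gb, "g0": result.param_map.g0,
            "x0": result.param_map.x0, "A": result.param_map.A,
            "alpha": result.param_map.alpha, "v": result.param_map.v,
            "ib": result.param_map.ib,
        },
    }


def save_posteriors(results, path) -> None:
    """Write a list of per-meal posteriors (``None`` for failed fits)."""
    payload = [posterior_to_dict(r) if r is not None else None for r in results]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
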