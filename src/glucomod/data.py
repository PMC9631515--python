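"""Containers for meal specifications and sampled meal-response data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MealSpec",
    "MealResponseData",
    "ObservationModel",
    "MEAL_SCHEDULE_MIN",
    "FASTING_SAMPLE_MIN",
    "RESPONSE_DURATION_MIN",
    "DataError",
]

#: Blood-sampling schedule relative to each meal (minutes): dense early
#: sampling, then every 15 min to 120 min and every 30 min to 240 min.
MEAL_SCHEDULE_MIN = (
    0.0, 2.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0,
    75.0, 90.0, 105.0, 120.0, 150.0, 180.0, 210.0, 240.0,
)

#: One extra fasting sample before the first meal of the day.
FASTING_SAMPLE_MIN = -15.0

#: Nominal duration of a single meal response (minutes); meals are eaten
#: this far apart, so each response window abuts the next meal.
RESPONSE_DURATION_MIN = 240.0


class DataError(ValueError):
    """Input data violate a structural requirement."""


@dataclass(frozen=True)
class MealSpec:
    """When a meal is eaten and how much glucose it delivers to plasma.

    ``A`` is the fixed AUC (mg/kg) of the meal's GA function, derived from
    the carbohydrate content: ``A = bioavailability * cho_dose * 1000``.
    """

    t_meal: float            # minutes since day start
    cho_dose: float          # g carbohydrate per kg body weight
    bioavailability: float = 0.9

    def __post_init__(self) -> None:
        if self.t_meal < 0.0:
            raise ValueError(f"t_meal must be >= 0, got {self.t_meal}")
        if not (self.cho_dose > 0.0):
            raise ValueError(f"cho_dose must be > 0, got {self.cho_dose}")
        if not (0.0 < self.bioavailability <= 1.0):
            raise ValueError(
                f"bioavailability must lie in (0, 1], got {self.bioavailability}"
            )

    @property
    def A(self) -> float:
        """Total GA area under the curve, mg glucose per kg body weight."""
        return self.bioavailability * self.cho_dose * 1000.0


@dataclass
class MealResponseData:
    """Sampled glucose (and optionally insulin) response to one meal.

    Times are minutes relative to meal consumption; the fasting sample at
    -15 min may be present for the first meal of a day.  Insulin is
    optional — without it only the glucose-only model can be fitted.
    """

    times: np.ndarray
    glucose: np.ndarray
    meal: MealSpec
    insulin: Optional[np.ndarray] = None
    subject_id: str = "subject"
    meal_index: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.glucose.size:
            raise DataError("times and glucose must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0.0):
            raise DataError("sample times must be strictly increasing")
        if np.any(self.glucose <= 0.0):
            raise DataError("glucose concentrations must be positive")
        if self.insulin is not None:
            self.insulin = np.asarray(self.insulin, dtype=float)
            if self.insulin.size != self.times.size:
                raise DataError("insulin must align with the sample times")
            if np.any(self.insulin <= 0.0):
                raise DataError("insulin concentrations must be positive")
        if self.meal_index < 1:
            raise DataError("meal_index starts at 1")
        fit = self.fit_mask
        if not fit.any() or self.times[fit][0] != 0.0 or self.times[fit][-1] < RESPONSE_DURATION_MIN:
            raise DataError("the sampling schedule must cover [0, 240] min")

    @property
    def fit_mask(self) -> np.ndarray:
        """Samples inside the fitting window [0, 240] (excludes -15 min)."""
        return (self.times >= 0.0) & (self.times <= RESPONSE_DURATION_MIN)

    @property
    def fit_times(self) -> np.ndarray:
        return self.times[self.fit_mask]

    @property
    def fit_glucose(self) -> np.ndarray:
        return self.glucose[self.fit_mask]

    def value_at(self, t: float) -> float:
        idx = np.flatnonzero(self.times == t)
        if idx.size == 0:
            raise DataError(f"no sample at t = {t} min")
        return float(self.glucose[idx[0]])


@dataclass
class ObservationModel:
    """Additive zero-mean Gaussian glucose measurement error of known SD.

    The per-sample SD (mg/dL) is either given directly or derived as a
    fixed coefficient of variation of the measured value.
    """

    sd: np.ndarray

    def __post_init__(self) -> None:
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd <= 0.0):
            raise ValueError("measurement SDs must be positive")

    @classmethod
    def from_cv(cls, values, cv: float = 0.02) -> "ObservationModel":
        if not (cv > 0.0):
            raise ValueError("noise CV must be positive")
        return cls(sd=cv * np.asarray(values, dtype=float))
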