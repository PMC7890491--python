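"""Daily hydroclimatic forcing: stochastic rainfall and Thornthwaite PET.

All forcing depths are centimetres of water per day.  Rainfall is generated
as a marked Poisson process aggregated to daily totals: the number of storm
events on a day is Poisson(lambda_freq) and each event carries an
exponentially distributed depth with mean ``alpha`` cm, so the daily total is
a compound-Poisson (Gamma-marked) variable with mean ``alpha * lambda`` and
variance ``2 * alpha^2 * lambda``.  Potential evapotranspiration comes either
from a fixed constant rate or from Thornthwaite's monthly temperature method
spread uniformly over each month's days.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ForcingSeries",
    "generate_rainfall",
    "constant_pet",
    "thornthwaite_monthly_pet",
    "thornthwaite_pet",
    "generate_forcing",
    "read_forcing",
    "write_forcing",
]

MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass
class ForcingSeries:
    """Daily rainfall and PET depths (cm/day) over the simulation horizon."""

    rain: np.ndarray
    pet: np.ndarray

    def __post_init__(self) -> None:
        self.rain = np.asarray(self.rain, dtype=float)
        self.pet = np.asarray(self.pet, dtype=float)
        if self.rain.shape != self.pet.shape or self.rain.ndim != 1:
            raise ValueError("rain and pet must be 1-d arrays of equal length")
        if np.any(self.rain < 0):
            raise ValueError("rain depths must be non-negative")
        if np.any(self.pet < 0):
            raise ValueError("pet depths must be non-negative")

    def __len__(self) -> int:
        return len(self.rain)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": np.arange(len(self)), "rain_cm": self.rain, "pet_cm": self.pet}
        )


def generate_rainfall(
    alpha: float,
    lambda_freq: float,
    T: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Daily rainfall depths (cm) from a marked Poisson storm process.

    Parameters
    ----------
    alpha : float
        Mean storm depth, cm.  Must be positive.
    lambda_freq : float
        Mean storm arrival frequency, 1/day.  Storm counts per day are
        Poisson(lambda_freq); values above 1/day are meaningful (several
        storms in a day).
    T : int
        Number of days.
    seed : int, Generator, optional
        Seed or generator; the output is reproducible for a given seed.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if lambda_freq < 0:
        raise ValueError("lambda_freq must be >= 0")
    if T < 0:
        raise ValueError("T must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = rng.poisson(lambda_freq, size=T)
    depths = np.zeros(T)
    events = counts > 0
    # sum of k iid Exp(alpha) marks is Gamma(k, alpha)
    if events.any():
        depths[events] = rng.standard_gamma(counts[events]) * alpha
    return depths


def constant_pet(rate: float, T: int) -> np.ndarray:
    """A fixed PET series of ``rate`` cm/day for T days."""
    if rate < 0:
        raise ValueError("pet rate must be >= 0")
    return np.full(int(T), float(rate))


def _day_length_hours(latitude_deg: float, day_of_year: np.ndarray) -> np.ndarray:
    """Daylight duration (h) from the standard sunset-hour-angle formula."""
    phi = np.deg2rad(latitude_deg)
    decl = np.deg2rad(23.45) * np.sin(2 * np.pi * (284 + day_of_year) / 365.0)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_omega)


def thornthwaite_monthly_pet(
    monthly_mean_temp: np.ndarray,
    latitude: float | None = None,
    *,
    day_length_hours: np.ndarray | None = None,
    days_in_month: np.ndarray | None = None,
) -> np.ndarray:
    """Monthly potential evapotranspiration (mm/month) by Thornthwaite's method.

    ``PET_m = 16 (L_m / 12) (N_m / 30) (10 T_m / I)^a`` for months with
    ``T_m > 0`` (else zero), where ``I = sum (T_m / 5)^1.514`` over months
    with positive temperature and ``a`` is the standard cubic in ``I``.
    ``L_m`` is mean daylight hours (computed from latitude at mid-month
    unless supplied) and ``N_m`` the number of days in the month.

    An all-freezing year gives ``I = 0`` and an all-zero PET series.
    """
    temp = np.asarray(monthly_mean_temp, dtype=float)
    if temp.shape != (12,):
        raise ValueError("monthly_mean_temp must have 12 entries")
    if days_in_month is None:
        days_in_month = MONTH_DAYS
    days_in_month = np.asarray(days_in_month, dtype=float)
    if day_length_hours is None:
        if latitude is None:
            raise ValueError("provide latitude or day_length_hours")
        if abs(latitude) > 66.5:
            raise ValueError("latitude must be within +/-66.5 degrees")
        mid = np.cumsum(days_in_month) - days_in_month / 2.0
        day_length_hours = _day_length_hours(latitude, mid)
    L = np.asarray(day_length_hours, dtype=float)

    warm = temp > 0.0
    I = float(np.sum((temp[warm] / 5.0) ** 1.514)) if warm.any() else 0.0
    if I == 0.0:
        return np.zeros(12)
    a = 6.75e-7 * I**3 - 7.71e-5 * I**2 + 1.792e-2 * I + 0.49239
    pet = np.zeros(12)
    pet[warm] = 16.0 * (L[warm] / 12.0) * (days_in_month[warm] / 30.0) * (
        10.0 * temp[warm] / I
    ) ** a
    return pet


def thornthwaite_pet(
    monthly_mean_temp: np.ndarray,
    latitude: float,
    n_years: int = 1,
) -> np.ndarray:
    """Daily PET (cm/day) from monthly Thornthwaite estimates.

    Monthly totals are spread uniformly over each (non-leap) month's days and
    the 365-day annual cycle is tiled over ``n_years``.
    """
    monthly_mm = thornthwaite_monthly_pet(monthly_mean_temp, latitude)
    daily = np.repeat(monthly_mm / MONTH_DAYS / 10.0, MONTH_DAYS)  # mm -> cm
    return np.tile(daily, int(n_years))


def generate_forcing(
    alpha: float,
    lambda_freq: float,
    T: int,
    pet: float | np.ndarray = 0.50,
    seed: int | np.random.Generator | None = None,
) -> ForcingSeries:
    """Convenience constructor: stochastic rainfall plus a PET series.

    ``pet`` may be a constant rate (cm/day) or a precomputed daily series.
    """
    rain = generate_rainfall(alpha, lambda_freq, T, seed=seed)
    if np.isscalar(pet):
        pet_arr = constant_pet(float(pet), T)
    else:
        pet_arr = np.asarray(pet, dtype=float)
        if len(pet_arr) < T:
            raise ValueError("pet series shorter than T")
        pet_arr = pet_arr[:T]
    return ForcingSeries(rain=rain, pet=pet_arr)


def write_forcing(series: ForcingSeries, path: str | Path, start_date: str = "2000-01-01") -> None:
    frame = series.to_frame()
    frame.insert(0, "date", pd.date_range(start_date, periods=len(series), freq="D"))
    frame.drop(columns="day").to_csv(path, index=False, float_format="%.10g")


def read_forcing(path: str | Path) -> ForcingSeries:
    """Read a daily forcing table with columns ``date, rain_cm[, pet_cm]``.

    The series must be gap-free and strictly daily; negative depths,
    duplicate dates and calendar gaps are rejected with the first offending
    row (1-based data rows).
    """
    frame = pd.read_csv(path, comment="#")
    if "date" not in frame.columns or "rain_cm" not in frame.columns:
        raise ValueError(f"{path}: requires columns date, rain_cm")
    dates = pd.to_datetime(frame["date"])
    if dates.duplicated().any():
        row = int(np.flatnonzero(dates.duplicated().to_numpy())[0]) + 1
        raise ValueError(f"{path}: duplicate date {frame['date'].iloc[row - 1]} at data row {row}")
    deltas = dates.diff().dropna()
    bad = deltas != pd.Timedelta(days=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(
            f"{path}: non-daily step before data row {row} "
            f"(gap after {frame['date'].iloc[row - 2]})"
        )
    rain = frame["rain_cm"].to_numpy(dtype=float)
    if (rain < 0).any():
        row = int(np.flatnonzero(rain < 0)[0]) + 1
        raise ValueError(f"{path}: negative rain_cm at data row {row}")
    if "pet_cm" in frame.columns:
        pet = frame["pet_cm"].to_numpy(dtype=float)
        if (pet < 0).any():
            row = int(np.flatnonzero(pet < 0)[0]) + 1
            raise ValueError(f"{path}: negative pet_cm at data row {row}")
    else:
        pet = np.zeros_like(rain)
    return ForcingSeries(rain=rain, pet=pet)
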