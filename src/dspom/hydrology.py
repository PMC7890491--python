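"""Per-wetland daily water balance: stage, wetted area and depth-zone areas.

Each wetland is an independent depression with a power-law bathymetry

    A(h) = A_max * min(1, h / h_max)^(2/p)
    V(h) = A_max * h_max * (h / h_max)^(2/p + 1) / (2/p + 1)

driven by daily fluxes: rainfall over the wetted area plus its upland
contributing area, evapotranspiration over the wetted area, and a linear
groundwater leakage proportional to the wetted area.  Stage is capped at
``h_max``; excess volume leaves the system as spill (wetlands are
geographically isolated: no inter-wetland surface routing).

Volume is carried as the simulation state so the balance closes exactly;
stage and area are derived for reporting.  A depth-zonation splits the
wetted area into concentric shallow (< 0.3 m), intermediate (0.3-0.8 m) and
deep (> 0.8 m) annuli; at a local depth of exactly 0.8 m the deep zone has
zero area (deep means strictly greater than 80 cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import Wetland, Wetlandscape
from .forcing import ForcingSeries

__all__ = [
    "HydroParams",
    "HydroStateSeries",
    "stage_to_area",
    "stage_to_volume",
    "volume_to_stage",
    "zone_areas",
    "step_water_balance",
    "simulate_hydrology",
    "SHALLOW_MAX_DEPTH",
    "DEEP_MIN_DEPTH",
]

SHALLOW_MAX_DEPTH = 0.3  # m
DEEP_MIN_DEPTH = 0.8  # m

CM = 0.01  # cm -> m


@dataclass(frozen=True)
class HydroParams:
    """Water-balance coefficients.

    k_leak : groundwater exchange rate over the wetted area, cm/day
        (positive = loss to shallow groundwater).
    pet_coeff : dimensionless multiplier on PET over the wetted area.
    """

    k_leak: float = 0.1
    pet_coeff: float = 1.0

    def __post_init__(self) -> None:
        if self.pet_coeff < 0:
            raise ValueError("pet_coeff must be >= 0")


def stage_to_area(w: Wetland, h) -> np.ndarray | float:
    """Wetted area (m^2) at stage ``h`` (m); vectorised over h."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("stage must be >= 0")
    frac = np.minimum(1.0, h / w.h_max)
    out = w.A_max * frac ** (2.0 / w.p)
    return float(out) if out.ndim == 0 else out


def stage_to_volume(w: Wetland, h) -> np.ndarray | float:
    """Stored volume (m^3) at stage ``h``; the antiderivative of the area."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h > w.h_max):
        raise ValueError("stage must lie in [0, h_max]")
    expo = 2.0 / w.p + 1.0
    out = w.A_max * w.h_max * (h / w.h_max) ** expo / expo
    return float(out) if out.ndim == 0 else out


def volume_to_stage(w: Wetland, v) -> np.ndarray | float:
    """Inverse of :func:`stage_to_volume` on [0, V(h_max)]."""
    v = np.asarray(v, dtype=float)
    expo = 2.0 / w.p + 1.0
    v_max = w.A_max * w.h_max / expo
    if np.any(v < 0) or np.any(v > v_max * (1 + 1e-12)):
        raise ValueError("volume outside [0, V(h_max)]")
    out = w.h_max * np.minimum(1.0, v * expo / (w.A_max * w.h_max)) ** (1.0 / expo)
    return float(out) if out.ndim == 0 else out


def zone_areas(w: Wetland, h: float) -> tuple[float, float, float]:
    """Concentric (shallow, intermediate, deep) wetted areas at stage ``h``.

    The area with local water depth exceeding ``d`` is the wetted area at the
    lowered stage ``h - d``, so the three annuli telescope exactly to the
    total wetted area.
    """
    if h < 0 or h > w.h_max:
        raise ValueError("stage must lie in [0, h_max]")
    a_total = stage_to_area(w, h)
    a_gt_shallow = stage_to_area(w, h - SHALLOW_MAX_DEPTH) if h > SHALLOW_MAX_DEPTH else 0.0
    a_deep = stage_to_area(w, h - DEEP_MIN_DEPTH) if h > DEEP_MIN_DEPTH else 0.0
    return a_total - a_gt_shallow, a_gt_shallow - a_deep, a_deep


def step_water_balance(
    w: Wetland,
    h_t: float,
    rain_t: float,
    pet_t: float,
    params: HydroParams,
) -> tuple[float, float]:
    """Advance one wetland one day; returns ``(h_next, spill_m3)``.

    Fluxes (rain and PET in cm/day) are converted to m^3 through the current
    wetted area (rain additionally over ``ca_ratio * A_max`` of contributing
    upland).  The updated volume is floored at zero and capped at full pool;
    the excess above full pool is reported as spill.
    """
    if rain_t < 0 or pet_t < 0:
        raise ValueError("forcing depths must be >= 0")
    a = stage_to_area(w, h_t)
    v = stage_to_volume(w, min(h_t, w.h_max))
    inflow = rain_t * CM * (a + w.ca_ratio * w.A_max)
    losses = (params.pet_coeff * pet_t + params.k_leak) * CM * a
    v_raw = v + inflow - losses
    expo = 2.0 / w.p + 1.0
    v_max = w.A_max * w.h_max / expo
    spill = max(0.0, v_raw - v_max)
    v_new = min(max(v_raw, 0.0), v_max)
    return volume_to_stage(w, v_new), spill


@dataclass
class HydroStateSeries:
    """Daily hydrologic state of every wetland plus a mass-balance ledger.

    Arrays are (T, n): stage ``h`` (m), wetted area ``A`` (m^2), equivalent
    radius ``r`` (m) and the three depth-zone areas.  States are recorded at
    the end of each forcing day.  The ledger totals (m^3, summed over the
    horizon per wetland) satisfy, exactly up to float addition,

        v_final - v0 = inflow - et - leak - spill + deficit

    where ``deficit`` is the part of the demanded losses unmet because the
    wetland dried out.
    """

    wetland_ids: list[str]
    h: np.ndarray
    A: np.ndarray
    r: np.ndarray
    A_shallow: np.ndarray
    A_int: np.ndarray
    A_deep: np.ndarray
    v0: np.ndarray = field(default=None)
    v_final: np.ndarray = field(default=None)
    inflow: np.ndarray = field(default=None)
    et: np.ndarray = field(default=None)
    leak: np.ndarray = field(default=None)
    spill: np.ndarray = field(default=None)
    deficit: np.ndarray = field(default=None)

    @property
    def n_days(self) -> int:
        return self.h.shape[0]

    @property
    def n_wetlands(self) -> int:
        return self.h.shape[1]

    def mass_balance_error(self) -> float:
        """Relative closure error of the landscape-total volume balance."""
        lhs = float(np.sum(self.v_final - self.v0))
        rhs = float(
            np.sum(self.inflow - self.et - self.leak - self.spill + self.deficit)
        )
        scale = max(float(np.sum(self.inflow)), float(np.sum(self.v0)), 1e-300)
        return abs(lhs - rhs) / scale

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (day, wetland_id, h, A, zone areas)."""
        T, n = self.h.shape
        return pd.DataFrame(
            {
                "day": np.repeat(np.arange(T), n),
                "wetland_id": np.tile(np.asarray(self.wetland_ids, dtype=object), T),
                "h": self.h.ravel(),
                "A": self.A.ravel(),
                "A_shallow": self.A_shallow.ravel(),
                "A_int": self.A_int.ravel(),
                "A_deep": self.A_deep.ravel(),
            }
        )


def _area_from_volume(v, a_max, h_max, expo):
    """Vectorised wetted area from stored volume (power-law bathymetry)."""
    v_max = a_max * h_max / expo
    frac = np.clip(v / v_max, 0.0, 1.0)
    # A = A_max * (h/h_max)^(2/p) and (h/h_max) = (V/V_max)^(1/expo)
    return a_max * frac ** ((expo - 1.0) / expo)


def _zone_areas_vec(h, a_max, h_max, p):
    two_over_p = 2.0 / p
    def area_at(stage):
        frac = np.clip(stage / h_max, 0.0, 1.0)
        return a_max * frac**two_over_p
    a_total = area_at(h)
    a_gt_shallow = np.where(h > SHALLOW_MAX_DEPTH, area_at(h - SHALLOW_MAX_DEPTH), 0.0)
    a_deep = np.where(h > DEEP_MIN_DEPTH, area_at(h - DEEP_MIN_DEPTH), 0.0)
    return a_total - a_gt_shallow, a_gt_shallow - a_deep, a_deep


def simulate_hydrology(
    landscape: Wetlandscape,
    forcing: ForcingSeries,
    params: HydroParams = HydroParams(),
    h0: float | np.ndarray | str = "full",
) -> HydroStateSeries:
    """Run the daily water balance for every wetland independently.

    ``h0`` sets the initial stage: ``"full"`` (default, all wetlands at
    ``h_max``), a scalar fraction of ``h_max`` in [0, 1], or an explicit
    per-wetland stage array (m).  End-of-day states are recorded for each of
    the ``len(forcing)`` days; the initial state is not part of the series.
    """
    n = len(landscape)
    T = len(forcing)
    a_max = landscape.a_max
    h_max = landscape.h_max
    p = landscape.p
    ca = landscape.ca_ratio
    expo = 2.0 / p + 1.0
    v_max = a_max * h_max / expo

    if isinstance(h0, str):
        if h0 != "full":
            raise ValueError(f"unknown h0 rule {h0!r}")
        h_init = h_max.copy()
    elif np.isscalar(h0):
        if not 0 <= h0 <= 1:
            raise ValueError("scalar h0 is a fraction of h_max in [0, 1]")
        h_init = float(h0) * h_max
    else:
        h_init = np.asarray(h0, dtype=float)
        if h_init.shape != (n,):
            raise ValueError("h0 array must have one stage per wetland")
        if np.any(h_init < 0) or np.any(h_init > h_max):
            raise ValueError("h0 stages must lie in [0, h_max]")

    v = a_max * h_max * (h_init / np.where(h_max > 0, h_max, 1.0)) ** expo / expo
    v = np.where(a_max > 0, v, 0.0)
    v0 = v.copy()

    h = np.empty((T, n))
    A = np.empty((T, n))
    tot_in = np.zeros(n)
    tot_et = np.zeros(n)
    tot_leak = np.zeros(n)
    tot_spill = np.zeros(n)
    tot_deficit = np.zeros(n)

    rain_m = forcing.rain * CM
    pet_m = forcing.pet * CM * params.pet_coeff
    leak_m = params.k_leak * CM

    for t in range(T):
        a = _area_from_volume(v, a_max, h_max, expo)
        inflow = rain_m[t] * (a + ca * a_max)
        et = pet_m[t] * a
        leak = leak_m * a
        v_raw = v + inflow - et - leak
        deficit = np.maximum(0.0, -v_raw)
        spill = np.maximum(0.0, v_raw - v_max)
        v = v_raw + deficit - spill
        tot_in += inflow
        tot_et += et
        tot_leak += leak
        tot_spill += spill
        tot_deficit += deficit
        h[t] = h_max * np.clip(v * expo / (a_max * h_max), 0.0, 1.0) ** (1.0 / expo)
        A[t] = _area_from_volume(v, a_max, h_max, expo)

    a_sh, a_int, a_dp = _zone_areas_vec(h, a_max, h_max, p)
    return HydroStateSeries(
        wetland_ids=landscape.ids,
        h=h,
        A=A,
        r=np.sqrt(A / np.pi),
        A_shallow=a_sh,
        A_int=a_int,
        A_deep=a_dp,
        v0=v0,
        v_final=v,
        inflow=tot_in,
        et=tot_et,
        leak=tot_leak,
        spill=tot_spill,
        deficit=tot_deficit,
    )
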