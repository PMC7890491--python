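"""Stochastic patch occupancy Markov chain and metapopulation capacity.

The occupancy state of an n-patch landscape is a binary vector p(t).  Each
day, an unoccupied patch i is colonised with probability
``1 - exp(-C_i dt)`` where the colonisation rate sums contributions from
occupied neighbours through an exponential dispersal kernel,

    C_i(t) = c * sum_{j != i} exp(-d_ij(t) / D) S_j(t) p_j(t),

and an occupied patch goes locally extinct with probability
``1 - exp(-E_i dt)`` with the extinction rate inversely proportional to
suitability, ``E_i(t) = e / S_i(t)`` (an unsuitable patch, S = 0, loses its
population with certainty at the next step and cannot be colonised).  All
events in a day are evaluated synchronously from the state at time t.

The landscape matrix ``M`` with ``m_ij = exp(-d_ij / D) S_i S_j`` (zero
diagonal) summarises habitat amount and configuration; its leading
eigenvalue, the metapopulation capacity ``lambda_max``, enters the
mean-field persistence criterion ``lambda_max > e / c``.  The dynamic
engine recomputes S, d and lambda_max every day from the hydrologic state;
the static engine freezes them at their time means.  Both run the identical
chain code with the identical random-number stream, so under time-constant
hydrology they produce identical trajectories realisation by realisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .landscape import Wetlandscape
from .hydrology import HydroStateSeries
from .geometry import centre_distances, gap_matrix

__all__ = [
    "SpeciesTraits",
    "OccupancyEnsemble",
    "CapacitySeries",
    "colonization_rate",
    "extinction_rate",
    "event_probability",
    "landscape_matrix",
    "metapopulation_capacity",
    "persistence_condition",
    "step_occupancy",
    "suitability_from_hydro",
    "run_dspom",
    "run_static_spom",
]


@dataclass(frozen=True)
class SpeciesTraits:
    """Fixed traits of the focal species.

    e : extinction coefficient (1/day per unit suitability)
    c : colonization coefficient (1/day per unit suitability)
    D : dispersal distance (m), the e-folding scale of the kernel and the
        connection threshold of the dispersal network.
    """

    e: float
    c: float
    D: float

    def __post_init__(self) -> None:
        if self.e < 0 or self.c < 0:
            raise ValueError("e and c must be >= 0")
        if not self.D > 0:
            raise ValueError("D must be > 0")


@dataclass
class OccupancyEnsemble:
    """Monte-Carlo realisations of the occupancy chain plus summaries.

    p : (realizations, days, patches) boolean occupancy states.
    omega : per-day fraction of occupied patches, averaged over realisations.
    sigma_omega : per-day std over realisations of the occupied fraction.
    f_S : fraction of realisations with at least one occupied patch on the
        final day (the surviving metapopulations).
    """

    p: np.ndarray
    omega: np.ndarray
    sigma_omega: np.ndarray
    f_S: float

    @classmethod
    def from_states(cls, p: np.ndarray) -> "OccupancyEnsemble":
        frac = p.mean(axis=2)  # (R, T)
        return cls(
            p=p,
            omega=frac.mean(axis=0),
            sigma_omega=frac.std(axis=0),
            f_S=float(p[:, -1, :].any(axis=1).mean()) if p.shape[1] else float("nan"),
        )

    @property
    def n_realizations(self) -> int:
        return self.p.shape[0]

    def extinction_days(self) -> np.ndarray:
        """First day with no occupied patch per realisation (NaN if never)."""
        empty = ~self.p.any(axis=2)  # (R, T)
        out = np.full(self.p.shape[0], np.nan)
        any_empty = empty.any(axis=1)
        out[any_empty] = np.argmax(empty[any_empty], axis=1)
        return out


@dataclass
class CapacitySeries:
    """Per-day metapopulation capacity lambda_max (deterministic)."""

    lambda_max: np.ndarray

    def __len__(self) -> int:
        return len(self.lambda_max)


# -- elementary rates -------------------------------------------------------

def colonization_rate(
    i: int,
    p: np.ndarray,
    S: np.ndarray,
    d_row: np.ndarray,
    traits: SpeciesTraits,
) -> float:
    """Colonisation rate (1/day) of patch i given the current occupancy."""
    p = np.asarray(p, dtype=float)
    mask = np.ones(len(p), dtype=bool)
    mask[i] = False
    return float(
        traits.c * np.sum(np.exp(-d_row[mask] / traits.D) * S[mask] * p[mask])
    )


def extinction_rate(S_i: float, traits: SpeciesTraits) -> float:
    """Extinction rate ``e / S_i`` (1/day); infinite for S_i = 0."""
    if S_i < 0:
        raise ValueError("suitability must be >= 0")
    if S_i == 0.0:
        return float("inf")
    return traits.e / S_i


def event_probability(rate: float, dt: float = 1.0) -> float:
    """Probability ``1 - exp(-rate * dt)`` of at least one event in dt days."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if np.isinf(rate):
        return 1.0
    return float(-np.expm1(-rate * dt))


# -- capacity ---------------------------------------------------------------

def landscape_matrix(S: np.ndarray, d: np.ndarray, D: float) -> np.ndarray:
    """Landscape matrix ``m_ij = exp(-d_ij / D) S_i S_j``, zero diagonal."""
    S = np.asarray(S, dtype=float)
    d = np.asarray(d, dtype=float)
    if d.shape != (len(S), len(S)):
        raise ValueError("gap matrix shape inconsistent with suitabilities")
    M = np.exp(-d / D) * np.outer(S, S)
    np.fill_diagonal(M, 0.0)
    return M


def metapopulation_capacity(M: np.ndarray, sym_tol: float = 1e-8) -> float:
    """Leading eigenvalue of the (symmetric, non-negative) landscape matrix."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    if M.size == 0:
        return 0.0
    scale = max(float(np.abs(M).max()), 1.0)
    if float(np.abs(M - M.T).max()) > sym_tol * scale:
        raise ValueError("M must be symmetric")
    return float(np.linalg.eigvalsh(M)[-1])


def persistence_condition(lambda_max: float, traits: SpeciesTraits) -> bool | None:
    """Mean-field persistence criterion ``lambda_max > e / c``.

    Returns None (indeterminate) when both rates vanish: the chain is frozen
    and neither persists nor collapses.  Near the threshold, individual
    stochastic realisations may still go extinct.
    """
    if traits.c == 0.0:
        return None if traits.e == 0.0 else False
    return bool(lambda_max > traits.e / traits.c)


# -- chain stepping ---------------------------------------------------------

def step_occupancy(
    p_t: np.ndarray,
    S_t: np.ndarray,
    d_t: np.ndarray,
    traits: SpeciesTraits,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance the chain one step (synchronous update from the state at t).

    ``p_t`` may be a single occupancy vector (n,) or a stack of independent
    realisations (R, n) advanced with one uniform draw per patch each.
    """
    kernel = np.exp(-np.asarray(d_t, dtype=float) / traits.D)
    np.fill_diagonal(kernel, 0.0)
    return _step_with_kernel(np.atleast_2d(p_t).astype(bool), np.asarray(S_t, float),
                             kernel, traits, dt, rng).reshape(np.shape(p_t))


def _step_with_kernel(p, S, kernel, traits, dt, rng):
    """Vectorised synchronous update; p is (R, n) boolean."""
    C = traits.c * (p * S) @ kernel  # kernel symmetric, zero diagonal
    p_col = -np.expm1(-C * dt)
    with np.errstate(divide="ignore"):
        E = np.where(S > 0, traits.e / np.where(S > 0, S, 1.0), np.inf)
    p_ext = np.where(np.isinf(E), 1.0, -np.expm1(-E * dt))
    u = rng.random(p.shape)
    survive = p & (u >= p_ext)
    colonise = (~p) & (u < p_col) & (S > 0)
    return survive | colonise


def suitability_from_hydro(
    hydro: HydroStateSeries,
    rule: str | Callable[[HydroStateSeries], np.ndarray] = "area",
    reference_area: float | None = None,
) -> np.ndarray:
    """Per-day, per-patch suitability S_i(t) from the hydrologic state.

    The default rule takes suitability proportional to wetted area,
    normalised by a reference area so that S is dimensionless and of order
    one (the reference defaults to the landscape mean full-pool area,
    estimated as the per-wetland maximum simulated area).  Zone rules
    (``"shallow"``, ``"intermediate"``, ``"deep"``) use the corresponding
    depth-zone area series instead, with the same reference.
    """
    if callable(rule):
        return np.asarray(rule(hydro), dtype=float)
    series = {
        "area": hydro.A,
        "shallow": hydro.A_shallow,
        "intermediate": hydro.A_int,
        "deep": hydro.A_deep,
    }.get(rule)
    if series is None:
        raise ValueError(f"unknown suitability rule {rule!r}")
    if reference_area is None:
        reference_area = float(np.mean(hydro.A.max(axis=0)))
    if reference_area <= 0:
        raise ValueError("reference_area must be > 0")
    return series / reference_area


def _initial_occupancy(n, n_realizations, p0, S0, rng):
    if isinstance(p0, str):
        if p0 != "all":
            raise ValueError(f"unknown p0 rule {p0!r}")
        base = S0 > 0
        return np.broadcast_to(base, (n_realizations, n)).copy()
    if np.isscalar(p0):
        if not 0 <= p0 <= 1:
            raise ValueError("scalar p0 is an occupancy probability in [0, 1]")
        return (rng.random((n_realizations, n)) < p0) & (S0 > 0)
    arr = np.asarray(p0, dtype=bool)
    if arr.shape != (n,):
        raise ValueError("p0 array must have one state per patch")
    return np.broadcast_to(arr, (n_realizations, n)).copy()


def _run_chain(S_series, gap_provider, traits, n_realizations, dt, p0, seed):
    """Shared engine: identical rng consumption for static and dynamic runs.

    ``S_series`` is (T, n); ``gap_provider(t)`` returns the day-t gap matrix.
    One capacity eigenvalue is computed per day (it is deterministic, a
    function of the hydrologic state only, unaffected by chain stochasticity).
    """
    T, n = S_series.shape
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    rng = np.random.default_rng(seed)
    p = _initial_occupancy(n, n_realizations, p0, S_series[0], rng)
    states = np.empty((n_realizations, T, n), dtype=bool)
    lam = np.empty(T)
    for t in range(T):
        S_t = S_series[t]
        d_t = gap_provider(t)
        kernel = np.exp(-d_t / traits.D)
        np.fill_diagonal(kernel, 0.0)
        lam[t] = metapopulation_capacity(kernel * np.outer(S_t, S_t))
        p = _step_with_kernel(p, S_t, kernel, traits, dt, rng)
        states[:, t, :] = p
        if not p.any():
            states[:, t:, :] = False  # global extinction is absorbing
            lam[t + 1 :] = [
                metapopulation_capacity(
                    landscape_matrix(S_series[s], gap_provider(s), traits.D)
                )
                for s in range(t + 1, T)
            ]
            break
    return OccupancyEnsemble.from_states(states), CapacitySeries(lambda_max=lam)


def run_dspom(
    landscape: Wetlandscape,
    hydro: HydroStateSeries,
    traits: SpeciesTraits,
    n_realizations: int = 100,
    dt: float = 1.0,
    p0: str | float | np.ndarray = "all",
    suitability: str | Callable = "area",
    reference_area: float | None = None,
    seed: int | None = None,
) -> tuple[OccupancyEnsemble, CapacitySeries]:
    """Run the dynamic chain: S_i(t) and d_ij(t) re-derived every day.

    Suitability follows ``suitability_from_hydro``; gap matrices are rebuilt
    from each day's wetted areas.  ``lambda_max(t)`` is recorded once per
    day.  Identical seeds give identical ensembles.
    """
    S_series = suitability_from_hydro(hydro, suitability, reference_area)
    centres = centre_distances(landscape)
    A = hydro.A

    def gaps(t: int) -> np.ndarray:
        return gap_matrix(centres, A[t])

    return _run_chain(S_series, gaps, traits, n_realizations, dt, p0, seed)


def run_static_spom(
    landscape: Wetlandscape,
    hydro: HydroStateSeries,
    traits: SpeciesTraits,
    n_realizations: int = 100,
    dt: float = 1.0,
    p0: str | float | np.ndarray = "all",
    suitability: str | Callable = "area",
    reference_area: float | None = None,
    seed: int | None = None,
) -> tuple[OccupancyEnsemble, CapacitySeries]:
    """Run the static chain: areas frozen at their simulated time means.

    Suitability is the time mean of the dynamic suitability and gaps are
    computed from the time-mean wetted areas, then the identical chain
    mechanics run for the same horizon.  The capacity series is constant by
    construction.
    """
    S_dyn = suitability_from_hydro(hydro, suitability, reference_area)
    T = S_dyn.shape[0]
    S_static = np.broadcast_to(S_dyn.mean(axis=0), S_dyn.shape)
    centres = centre_distances(landscape)
    gap_static = gap_matrix(centres, hydro.A.mean(axis=0))

    def gaps(t: int) -> np.ndarray:
        return gap_static

    return _run_chain(S_static, gaps, traits, n_realizations, dt, p0, seed)
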