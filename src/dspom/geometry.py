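"""Time-varying inter-patch gap geometry and landscape-level statistics.

Patches are equivalent circles, so the gap between patches i and j is the
perimeter-to-perimeter separation

    d_ij = max(0, ||x_i - x_j|| - r_i - r_j),   r = sqrt(A / pi),

which grows as wetlands contract.  Dry patches (A = 0) keep their centre
coordinates and enter the matrix with r = 0; their dynamical irrelevance is
handled by zero suitability in the occupancy chain, which keeps all matrices
time-constant in shape.

Landscape statistics per day: A* (total wetted area normalised by the
landscape full-pool total), NND (mean nearest-neighbour gap among wet
patches) and r_CV (spatial CV of areas over spatial CV of gaps).  Days on
which a statistic is undefined (fewer than two wet patches) are reported as
NaN, never silently zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .landscape import Wetlandscape
from .hydrology import HydroStateSeries

__all__ = [
    "gap_distance",
    "centre_distances",
    "gap_matrix",
    "nnd",
    "a_star",
    "r_cv",
    "landscape_stats",
]


def gap_distance(x_i, x_j, A_i: float, A_j: float) -> float:
    """Perimeter-to-perimeter gap (m) between two equivalent-circle patches."""
    if A_i < 0 or A_j < 0:
        raise ValueError("areas must be >= 0")
    centre = float(np.hypot(x_i[0] - x_j[0], x_i[1] - x_j[1]))
    return max(0.0, centre - np.sqrt(A_i / np.pi) - np.sqrt(A_j / np.pi))


def centre_distances(landscape: Wetlandscape) -> np.ndarray:
    """Symmetric centre-to-centre Euclidean distance matrix (m)."""
    n = len(landscape)
    if n == 0:
        return np.zeros((0, 0))
    return squareform(pdist(landscape.xy))


def gap_matrix(
    landscape_or_centres: Wetlandscape | np.ndarray, areas: np.ndarray
) -> np.ndarray:
    """Symmetric gap-distance matrix for one day's areas.

    Accepts either a landscape (centre distances computed internally) or a
    precomputed centre-distance matrix, which callers stepping through many
    days should cache.
    """
    if isinstance(landscape_or_centres, Wetlandscape):
        centres = centre_distances(landscape_or_centres)
    else:
        centres = np.asarray(landscape_or_centres, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if np.any(areas < 0):
        raise ValueError("areas must be >= 0")
    radii = np.sqrt(areas / np.pi)
    gaps = np.maximum(0.0, centres - (radii[:, None] + radii[None, :]))
    np.fill_diagonal(gaps, 0.0)
    return gaps


def nnd(gaps: np.ndarray, wet: np.ndarray | None = None) -> float:
    """Mean nearest-neighbour gap (m) among wet patches; NaN if fewer than 2.

    ``wet`` is a boolean mask restricting the average to currently wet
    patches (the default considers every patch wet).
    """
    gaps = np.asarray(gaps, dtype=float)
    n = gaps.shape[0]
    if wet is None:
        wet = np.ones(n, dtype=bool)
    idx = np.flatnonzero(wet)
    if len(idx) < 2:
        return float("nan")
    sub = gaps[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(np.mean(np.min(sub, axis=1)))


def a_star(areas: np.ndarray, total_a_max: float) -> float:
    """Normalised total wetted area ``sum(A_i) / A_T,MAX`` in [0, 1]."""
    if total_a_max <= 0:
        raise ValueError("total_a_max must be > 0")
    return float(np.sum(areas) / total_a_max)


def _spatial_cv(values: np.ndarray) -> float:
    mean = float(np.mean(values))
    if mean == 0.0:
        return float("nan")
    return float(np.std(values) / mean)


def r_cv(areas: np.ndarray, gaps: np.ndarray, wet: np.ndarray | None = None) -> float:
    """Ratio of the spatial CV of wet-patch areas to that of their gaps.

    Both CVs are taken over the cross-section at a single time: areas over
    wet patches, gaps over the off-diagonal pairs of wet patches.  NaN when
    fewer than two patches are wet or the gap CV vanishes; identically zero
    areas across wet patches give r_CV = 0.
    """
    areas = np.asarray(areas, dtype=float)
    n = len(areas)
    if wet is None:
        wet = areas > 0
    idx = np.flatnonzero(wet)
    if len(idx) < 2:
        return float("nan")
    a_sub = areas[idx]
    g_sub = gaps[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)]
    cv_a = _spatial_cv(a_sub)
    cv_d = _spatial_cv(g_sub)
    if cv_a == 0.0:
        return 0.0
    if not np.isfinite(cv_d) or cv_d == 0.0:
        return float("nan")
    return cv_a / cv_d


def landscape_stats(
    landscape: Wetlandscape,
    hydro: HydroStateSeries,
    wet_only: bool = True,
) -> pd.DataFrame:
    """Per-day table of A*, NND and r_CV.

    ``wet_only=True`` (default) restricts NND and r_CV to currently wet
    patches; with ``wet_only=False`` every patch participates (dry patches
    with r = 0).
    """
    centres = centre_distances(landscape)
    total = landscape.total_a_max
    rows = []
    for t in range(hydro.n_days):
        areas = hydro.A[t]
        gaps = gap_matrix(centres, areas)
        wet = areas > 0 if wet_only else None
        rows.append(
            {
                "day": t,
                "A_star": a_star(areas, total),
                "NND": nnd(gaps, wet),
                "r_CV": r_cv(areas, gaps, wet),
            }
        )
    return pd.DataFrame(rows)
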