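"""Wetlandscape representation, synthetic generation and tabular I/O.

A wetlandscape is an ordered collection of depressional wetland patches in a
planar domain.  Each patch is described by its centre coordinates, the wetted
area and stage at full pool, a power-law bathymetry shape exponent, and the
ratio of its upland contributing area to its full-pool area.  Patches are
treated as equivalent circles of radius ``sqrt(A / pi)``: every downstream
quantity (perimeter-to-perimeter gap distances, wetted areas, depth-zone
areas) is computable from the circular approximation, which removes any need
for polygon/GIS machinery.

Two synthetic archetypes are provided, emulating contrasting real
wetlandscapes: a dense, heterogeneous prairie-pothole-like landscape
(~30 wetlands km^-2, strongly lognormal areas) and a sparse, homogeneous
playa-lake-like landscape (~1 wetland km^-2, weakly varying areas).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Wetland",
    "Wetlandscape",
    "generate_wetlandscape",
    "read_wetlandscape",
    "write_wetlandscape",
    "dense_archetype",
    "sparse_archetype",
]

_COLUMNS = ["id", "x", "y", "A_max", "h_max", "p", "ca_ratio"]


@dataclass(frozen=True)
class Wetland:
    """Static geometry of one habitat patch.

    Parameters
    ----------
    id : str
        Unique identifier within a landscape.
    x, y : float
        Planar centre coordinates in metres (origin at the domain corner).
    A_max : float
        Wetted area at full pool, m^2.  Must be positive.
    h_max : float
        Stage at full pool, m.  Must be positive.
    p : float
        Bathymetry shape exponent of the power-law stage-area relation
        ``A(h) = A_max (h / h_max)^(2/p)``.  ``p = 2`` is a cone-like basin.
    ca_ratio : float
        Upland contributing area divided by ``A_max`` (dimensionless, >= 0).
        Rain falling on the contributing area runs into the wetland.
    """

    id: str
    x: float
    y: float
    A_max: float
    h_max: float
    p: float
    ca_ratio: float = 0.0

    def __post_init__(self) -> None:
        if not self.A_max > 0:
            raise ValueError(f"wetland {self.id!r}: A_max must be > 0, got {self.A_max}")
        if not self.h_max > 0:
            raise ValueError(f"wetland {self.id!r}: h_max must be > 0, got {self.h_max}")
        if not self.p > 0:
            raise ValueError(f"wetland {self.id!r}: p must be > 0, got {self.p}")
        if self.ca_ratio < 0:
            raise ValueError(
                f"wetland {self.id!r}: ca_ratio must be >= 0, got {self.ca_ratio}"
            )

    @property
    def r_max(self) -> float:
        """Equivalent-circle radius at full pool, m."""
        return float(np.sqrt(self.A_max / np.pi))


@dataclass
class Wetlandscape:
    """An ordered collection of :class:`Wetland` in a rectangular domain."""

    wetlands: list[Wetland]
    domain_extent: tuple[float, float]

    def __post_init__(self) -> None:
        ids = [w.id for w in self.wetlands]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate wetland id {i!r}")
                seen.add(i)
        w_ext, h_ext = self.domain_extent
        if w_ext <= 0 or h_ext <= 0:
            raise ValueError("domain_extent must be positive")
        for w in self.wetlands:
            if not (0 <= w.x <= w_ext and 0 <= w.y <= h_ext):
                raise ValueError(
                    f"wetland {w.id!r} centre ({w.x}, {w.y}) outside domain {self.domain_extent}"
                )

    def __len__(self) -> int:
        return len(self.wetlands)

    def __iter__(self):
        return iter(self.wetlands)

    # -- array views used throughout the simulation code ------------------

    @property
    def ids(self) -> list[str]:
        return [w.id for w in self.wetlands]

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of centre coordinates, m."""
        return np.array([[w.x, w.y] for w in self.wetlands], dtype=float).reshape(-1, 2)

    @property
    def a_max(self) -> np.ndarray:
        return np.array([w.A_max for w in self.wetlands], dtype=float)

    @property
    def h_max(self) -> np.ndarray:
        return np.array([w.h_max for w in self.wetlands], dtype=float)

    @property
    def p(self) -> np.ndarray:
        return np.array([w.p for w in self.wetlands], dtype=float)

    @property
    def ca_ratio(self) -> np.ndarray:
        return np.array([w.ca_ratio for w in self.wetlands], dtype=float)

    @property
    def total_a_max(self) -> float:
        """A_T,MAX: summed full-pool area of the landscape, m^2."""
        return float(self.a_max.sum()) if self.wetlands else 0.0

    @property
    def density_per_km2(self) -> float:
        w, h = self.domain_extent
        return len(self) / (w * h / 1e6)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": w.id,
                    "x": w.x,
                    "y": w.y,
                    "A_max": w.A_max,
                    "h_max": w.h_max,
                    "p": w.p,
                    "ca_ratio": w.ca_ratio,
                }
                for w in self.wetlands
            ],
            columns=_COLUMNS,
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, domain_extent: tuple[float, float]
    ) -> "Wetlandscape":
        wetlands = [
            Wetland(
                id=str(row.id),
                x=float(row.x),
                y=float(row.y),
                A_max=float(row.A_max),
                h_max=float(row.h_max),
                p=float(row.p),
                ca_ratio=float(row.ca_ratio),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(wetlands=wetlands, domain_extent=domain_extent)


# -- synthetic archetypes ---------------------------------------------------

def dense_archetype() -> dict:
    """Generator parameters emulating a dense, heterogeneous wetlandscape.

    Target statistics: ~30 wetlands km^-2 with a landscape full-pool area of
    ~0.38 km^2 per km^2 (mean A_max ~ 1.27e4 m^2) and strong area
    heterogeneity, as in glacially formed prairie-pothole terrain.
    """
    return {
        "density_per_km2": 30.0,
        "area_law": {"kind": "lognormal", "mean": 38e6 / 3000, "cv": 1.5},
        "h_max_law": {"kind": "lognormal", "mean": 1.2, "cv": 0.4},
        "bathymetry_law": {"kind": "uniform", "low": 1.0, "high": 4.0},
        "ca_ratio": 2.0,
        "min_centre_separation": 30.0,
    }


def sparse_archetype() -> dict:
    """Generator parameters emulating a sparse, homogeneous wetlandscape.

    Target statistics: ~1 wetland km^-2 with a landscape full-pool area of
    ~0.05 km^2 per km^2 (mean A_max ~ 5e4 m^2) and weak heterogeneity, as in
    wind-carved playa-lake terrain.
    """
    return {
        "density_per_km2": 1.0,
        "area_law": {"kind": "lognormal", "mean": 5e6 / 100, "cv": 0.3},
        "h_max_law": {"kind": "lognormal", "mean": 1.0, "cv": 0.2},
        "bathymetry_law": {"kind": "uniform", "low": 1.8, "high": 2.2},
        "ca_ratio": 3.0,
        "min_centre_separation": 300.0,
    }


def _sample_law(law: Mapping | float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n values from a distribution descriptor.

    Accepts a plain number (fixed value), ``{"kind": "fixed", "value": v}``,
    ``{"kind": "lognormal", "mean": m, "cv": c}`` (moment-parameterised), or
    ``{"kind": "uniform", "low": a, "high": b}``.
    """
    if isinstance(law, (int, float)):
        return np.full(n, float(law))
    kind = law["kind"]
    if kind == "fixed":
        return np.full(n, float(law["value"]))
    if kind == "lognormal":
        mean, cv = float(law["mean"]), float(law["cv"])
        if mean <= 0:
            raise ValueError("lognormal law requires mean > 0")
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    if kind == "uniform":
        return rng.uniform(float(law["low"]), float(law["high"]), size=n)
    raise ValueError(f"unknown distribution kind {kind!r}")


def generate_wetlandscape(
    n_patches: int,
    extent: tuple[float, float] = (10_000.0, 10_000.0),
    area_law: Mapping | float | None = None,
    bathymetry_law: Mapping | float | None = None,
    h_max_law: Mapping | float | None = None,
    ca_ratio: Mapping | float = 2.0,
    min_centre_separation: float = 0.0,
    seed: int | None = None,
    max_attempts_per_patch: int = 1000,
) -> Wetlandscape:
    """Generate a synthetic wetlandscape by sequential rejection sampling.

    Centres are drawn uniformly in the domain and rejected when closer than
    ``min_centre_separation`` to an already placed centre (a hard-core point
    process).  Per-patch attributes are drawn independently from the supplied
    distribution laws.  The output is fully determined by ``seed``.

    Raises
    ------
    ValueError
        If the requested packing is infeasible, or placement fails after
        ``max_attempts_per_patch * n_patches`` rejections.
    """
    if n_patches < 0:
        raise ValueError("n_patches must be >= 0")
    w_ext, h_ext = float(extent[0]), float(extent[1])
    if w_ext <= 0 or h_ext <= 0:
        raise ValueError("extent must be positive")
    if n_patches * np.pi * (min_centre_separation / 2.0) ** 2 >= w_ext * h_ext:
        raise ValueError(
            "infeasible packing: n_patches * pi * (min_centre_separation/2)^2 "
            "exceeds the domain area"
        )
    if area_law is None:
        area_law = dense_archetype()["area_law"]
    if bathymetry_law is None:
        bathymetry_law = dense_archetype()["bathymetry_law"]
    if h_max_law is None:
        h_max_law = dense_archetype()["h_max_law"]

    rng = np.random.default_rng(seed)
    centres: list[tuple[float, float]] = []
    placed = np.empty((0, 2))
    attempts = 0
    budget = max(1, max_attempts_per_patch * max(n_patches, 1))
    while len(centres) < n_patches:
        if attempts >= budget:
            raise ValueError(
                f"could not place {n_patches} centres with "
                f"min_centre_separation={min_centre_separation} m in a "
                f"{w_ext} x {h_ext} m domain after {attempts} attempts"
            )
        attempts += 1
        cand = rng.uniform((0.0, 0.0), (w_ext, h_ext))
        if min_centre_separation > 0 and len(centres):
            d2 = np.sum((placed - cand) ** 2, axis=1)
            if np.any(d2 < min_centre_separation**2):
                continue
        centres.append((float(cand[0]), float(cand[1])))
        placed = np.vstack([placed, cand])

    a_max = _sample_law(area_law, n_patches, rng)
    h_max = _sample_law(h_max_law, n_patches, rng)
    p = _sample_law(bathymetry_law, n_patches, rng)
    ca = _sample_law(ca_ratio, n_patches, rng)

    width = len(str(max(n_patches - 1, 0)))
    wetlands = [
        Wetland(
            id=f"w{i:0{width}d}",
            x=centres[i][0],
            y=centres[i][1],
            A_max=float(a_max[i]),
            h_max=float(h_max[i]),
            p=float(p[i]),
            ca_ratio=float(ca[i]),
        )
        for i in range(n_patches)
    ]
    return Wetlandscape(wetlands=wetlands, domain_extent=(w_ext, h_ext))


def generate_archetype(
    archetype: str,
    extent: tuple[float, float] = (10_000.0, 10_000.0),
    seed: int | None = None,
    **overrides,
) -> Wetlandscape:
    """Generate a landscape from a named archetype (``dense`` or ``sparse``)."""
    params = {"dense": dense_archetype, "sparse": sparse_archetype}[archetype]()
    params.update(overrides)
    density = params.pop("density_per_km2")
    n = int(round(density * extent[0] * extent[1] / 1e6))
    return generate_wetlandscape(n_patches=n, extent=extent, seed=seed, **params)


# -- tabular I/O ------------------------------------------------------------

def write_wetlandscape(landscape: Wetlandscape, path: str | Path) -> None:
    """Write a landscape as a commented, comma-delimited UTF-8 table.

    Header comment lines (starting ``#``) record units and the domain extent
    so the file round-trips through :func:`read_wetlandscape`.
    """
    path = Path(path)
    w_ext, h_ext = landscape.domain_extent
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# wetlandscape table: x,y in m; A_max in m^2; h_max in m; "
                 "p, ca_ratio dimensionless\n")
        fh.write(f"# domain_extent_m: {w_ext!r} {h_ext!r}\n")
        landscape.to_frame().to_csv(fh, index=False, float_format="%.10g")


def read_wetlandscape(
    path: str | Path, domain_extent: tuple[float, float] | None = None
) -> Wetlandscape:
    """Read a landscape table written by :func:`write_wetlandscape`.

    The domain extent is taken from the ``# domain_extent_m`` header comment
    unless given explicitly; with neither present it defaults to the bounding
    box of the centres.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    extent = domain_extent
    for line in text.splitlines():
        if line.startswith("# domain_extent_m:") and extent is None:
            parts = line.split(":", 1)[1].split()
            extent = (float(parts[0]), float(parts[1]))
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    frame = pd.read_csv(io.StringIO(body))
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    frame["id"] = frame["id"].astype(str)
    dup = frame["id"][frame["id"].duplicated()]
    if len(dup):
        row = int(dup.index[0]) + 1  # 1-based data row
        raise ValueError(f"{path}: duplicate id {dup.iloc[0]!r} at data row {row}")
    for col, cond in [("A_max", frame["A_max"] <= 0), ("h_max", frame["h_max"] <= 0),
                      ("p", frame["p"] <= 0), ("ca_ratio", frame["ca_ratio"] < 0)]:
        if cond.any():
            row = int(np.flatnonzero(cond.to_numpy())[0]) + 1
            raise ValueError(
                f"{path}: invalid {col} at data row {row} "
                f"(violates {col} {'>= 0' if col == 'ca_ratio' else '> 0'})"
            )
    if extent is None:
        extent = (float(frame["x"].max()), float(frame["y"].max()))
    return Wetlandscape.from_frame(frame, domain_extent=extent)
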