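"""Migration-distance proxy for population genetic divergence.

Under the serial founder effect, worldwide genetic divergence decreases
approximately linearly with migration distance over the earth's surface from
a single origin in East Africa.  Migration distance therefore orders human
populations by decreasing genetic divergence, and that order — re-expressed
as an equally spaced Population Index — is the perturbation axis the 2D
correlation engine consumes.

Distances are estimated per population from weighted waypoint paths
(great-circle legs; optional pre-computed driving distances act as upper
bounds), the lower/upper bounds are widened symmetrically about their
midpoint until a straight line of distance against divergence rank threads
every interval, and the surviving populations are ranked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import linprog

EARTH_RADIUS_KM = 6371.0  # mean Earth radius

__all__ = [
    "EARTH_RADIUS_KM",
    "Waypoint",
    "PopulationRoute",
    "PopulationOrder",
    "BoundCalibration",
    "great_circle_distance",
    "path_distance",
    "admixture_distance",
    "calibrate_bounds",
    "order_populations",
    "load_route_config",
    "default_route_config",
    "RouteConfig",
]


@dataclass(frozen=True)
class Waypoint:
    name: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 < self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside (-180, 180]")


def great_circle_distance(a: Waypoint, b: Waypoint) -> float:
    """Haversine great-circle distance in km on a sphere of mean radius."""
    la1, lo1, la2, lo2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    h = (
        math.sin((la2 - la1) / 2.0) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def path_distance(path: Sequence[Waypoint]) -> float:
    """Sum of consecutive great-circle legs; a single waypoint has length 0."""
    if not path:
        raise ValueError("empty waypoint path")
    return sum(
        great_circle_distance(a, b) for a, b in zip(path[:-1], path[1:])
    )


def admixture_distance(components: Sequence[tuple[float, float]]) -> float:
    """Weighted mean of (distance_km, weight) components; weights sum to 1."""
    if not components:
        raise ValueError("no admixture components")
    total_w = sum(w for _, w in components)
    if any(w < 0 for _, w in components):
        raise ValueError("negative admixture weight")
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError(f"admixture weights sum to {total_w}, expected 1")
    return sum(d * w for d, w in components)


@dataclass
class PopulationRoute:
    """One population's migration-distance estimate.

    ``components`` holds (waypoint path, weight) pairs — weights reflect
    ethnic contributions to the local population.  ``lower_km`` is the
    admixture-weighted great-circle estimate; ``upper_km`` the corresponding
    driving-distance estimate where available (never shorter).
    """

    code: str
    components: list[tuple[list[Waypoint], float]] = field(default_factory=list)
    lower_km: float = 0.0
    upper_km: float = 0.0

    def __post_init__(self) -> None:
        if self.upper_km < self.lower_km:
            raise ValueError(
                f"{self.code}: upper bound {self.upper_km} < lower {self.lower_km}"
            )


@dataclass(frozen=True)
class PopulationOrder:
    """Populations ordered by increasing migration distance (decreasing
    genetic divergence), with equally spaced indices 1..np."""

    codes: tuple[str, ...]
    distances_km: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.codes) != len(self.distances_km):
            raise ValueError("codes/distances length mismatch")

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(range(1, len(self.codes) + 1))

    def index_of(self, code: str) -> int:
        return self.codes.index(code) + 1


@dataclass(frozen=True)
class BoundCalibration:
    scale_lower: float
    scale_upper: float
    intercept: float
    slope: float
    fitted_km: tuple[float, ...]
    codes: tuple[str, ...]


def _line_fits(lower: np.ndarray, upper: np.ndarray) -> Optional[tuple[float, float]]:
    """Chebyshev-style feasibility: is there a line y = a + b*rank with
    lower_i <= y_i <= upper_i for all i?  Returns (a, b) or None."""
    n = len(lower)
    rank = np.arange(1, n + 1, dtype=float)
    # variables: a, b.  Constraints: a + b*r <= upper; -(a + b*r) <= -lower.
    A = np.vstack([np.column_stack([np.ones(n), rank]),
                   -np.column_stack([np.ones(n), rank])])
    ub = np.concatenate([upper, -lower])
    res = linprog(c=[0.0, 0.0], A_ub=A, b_ub=ub, bounds=[(None, None)] * 2,
                  method="highs")
    if res.status == 0:
        return float(res.x[0]), float(res.x[1])
    return None


def calibrate_bounds(
    routes: Sequence[PopulationRoute],
    step: float = 0.01,
    max_widening: float = 3.0,
) -> BoundCalibration:
    """Widen per-population [lower, upper] intervals outward from their
    midpoints, in equal increments of ``step`` per side, until a straight
    line of distance against divergence rank passes through every interval.

    Populations are ranked by interval midpoint.  Returns the widening
    factors applied to each half-interval (equal by construction of the
    symmetric schedule), the fitted line, and per-population fitted
    distances.
    """
    if len(routes) < 2:
        raise ValueError("need at least 2 populations to calibrate")
    order = sorted(routes, key=lambda r: ((r.lower_km + r.upper_km) / 2.0, r.code))
    lo = np.array([r.lower_km for r in order])
    up = np.array([r.upper_km for r in order])
    mid = (lo + up) / 2.0
    half = (up - lo) / 2.0

    f = 1.0
    while f <= max_widening + 1e-12:
        fit = _line_fits(mid - f * half, mid + f * half)
        if fit is not None:
            a, b = fit
            rank = np.arange(1, len(order) + 1, dtype=float)
            fitted = a + b * rank
            return BoundCalibration(
                scale_lower=f,
                scale_upper=f,
                intercept=a,
                slope=b,
                fitted_km=tuple(fitted),
                codes=tuple(r.code for r in order),
            )
        f += step
    raise RuntimeError(
        f"no line fits within widening factor {max_widening}; "
        "check the route bounds"
    )


def order_populations(
    distances: Mapping[str, float],
    exclusions: set[str] | frozenset[str] = frozenset(),
    redundancies: set[str] | frozenset[str] = frozenset(),
) -> PopulationOrder:
    """Rank populations by increasing migration distance.

    ``exclusions`` removes codes whose distance ranking is not feasible
    (e.g. global or unspecified pools); ``redundancies`` removes codes whose
    migration distance duplicates a retained population.  Ties break
    alphabetically so the order is deterministic.
    """
    if any(d < 0 for d in distances.values()):
        raise ValueError("negative migration distance")
    kept = {
        c: d for c, d in distances.items()
        if c not in exclusions and c not in redundancies
    }
    if len(kept) < 2:
        raise ValueError("fewer than 2 populations remain after exclusion")
    ranked = sorted(kept.items(), key=lambda cd: (cd[1], cd[0]))
    return PopulationOrder(
        codes=tuple(c for c, _ in ranked),
        distances_km=tuple(d for _, d in ranked),
    )


# ---------------------------------------------------------------------------
# Route configuration
# ---------------------------------------------------------------------------

@dataclass
class RouteConfig:
    waypoints: dict[str, Waypoint]
    routes: list[PopulationRoute]
    exclusions: set[str]
    redundancies: set[str]

    def distances(self) -> dict[str, float]:
        return {r.code: (r.lower_km + r.upper_km) / 2.0 for r in self.routes}

    def population_order(self) -> PopulationOrder:
        return order_populations(
            self.distances(), self.exclusions, self.redundancies
        )

    def calibrate(self, step: float = 0.01, max_widening: float = 10.0) -> "BoundCalibration":
        """Calibrate bounds over the rankable routes only (exclusions and
        redundant codes dropped first)."""
        drop = self.exclusions | self.redundancies
        return calibrate_bounds(
            [r for r in self.routes if r.code not in drop],
            step=step,
            max_widening=max_widening,
        )


def load_route_config(path: str | Path) -> RouteConfig:
    """Parse a YAML route configuration.

    Schema::

        waypoints: {Name: [lat, lon], ...}
        routes:
          POP:
            components:
              - {path: [Name, ...], weight: 0.6, driving_km: 12345}  # optional
        exclusions: [GLO, OTH]
        redundancies: [TWC]
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    waypoints = {
        name: Waypoint(name, float(lat), float(lon))
        for name, (lat, lon) in raw.get("waypoints", {}).items()
    }
    routes = []
    for code, spec in raw.get("routes", {}).items():
        comps, lower_parts, upper_parts = [], [], []
        for comp in spec["components"]:
            try:
                wps = [waypoints[n] for n in comp["path"]]
            except KeyError as exc:
                raise ValueError(f"{code}: unknown waypoint {exc}") from exc
            w = float(comp.get("weight", 1.0))
            gc = path_distance(wps)
            drv = float(comp.get("driving_km", gc))
            if drv < gc:
                raise ValueError(
                    f"{code}: driving distance {drv} shorter than great-circle {gc:.0f}"
                )
            comps.append((wps, w))
            lower_parts.append((gc, w))
            upper_parts.append((drv, w))
        routes.append(
            PopulationRoute(
                code=code,
                components=comps,
                lower_km=admixture_distance(lower_parts),
                upper_km=admixture_distance(upper_parts),
            )
        )
    return RouteConfig(
        waypoints=waypoints,
        routes=routes,
        exclusions=set(raw.get("exclusions", [])),
        redundancies=set(raw.get("redundancies", [])),
    )


def default_route_config() -> RouteConfig:
    """The packaged approximate route table (waypoints from the published
    out-of-Africa pathway description; coordinates and weights are this
    package's approximation, not the original supplementary table)."""
    here = Path(__file__).parent / "data" / "default_routes.yaml"
    return load_route_config(here)
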