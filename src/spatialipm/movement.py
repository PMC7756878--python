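"""Inter-annual dispersal: heavy-tailed kernel, site fidelity, emigration.

Movements between years follow an axis-independent random walk with
Student-T steps of fixed 5 degrees of freedom (long tails) and a scale
``sigma_move`` specific to age (fledgling natal dispersal vs breeder
breeding dispersal) and habitat of origin.  Breeders additionally reuse
exactly the same territory site with probability ``Pstay_h`` (a Bernoulli
mixture: stay implies a zero step); fledglings never "stay".

Emigration is a derived quantity: the kernel mass landing outside the total
study area, times the probability of moving at all, estimated by Monte
Carlo.  The study area is a core region (intensive monitoring) nested in a
total region (where detection is possible at all); by default both are
axis-aligned rectangles of 40 and 60 km^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import box

__all__ = [
    "FLEDGLING",
    "BREEDER",
    "AGE_LABELS",
    "Location",
    "StudyArea",
    "MovementParams",
    "kernel_logdensity",
    "sample_next_location",
    "emigration_probability",
    "population_emigration_rate",
]

FLEDGLING = 0
BREEDER = 1
AGE_LABELS = ("fledgling", "breeder")


@dataclass
class Location:
    """Planar location in km (local study plane, x easting / y northing)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("location coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class StudyArea:
    """Core region nested inside the total region (km units).

    ``total_rect`` / ``core_rect`` are (xmin, xmax, ymin, ymax) when the
    regions are axis-aligned rectangles (the fast path used in fitting);
    arbitrary polygons are supported through the shapely geometries.
    """

    total: shapely.Geometry
    core: shapely.Geometry
    total_rect: tuple[float, float, float, float] | None = None
    core_rect: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.total.area <= 0 or self.core.area <= 0:
            raise ValueError("study-area regions must have positive area")
        if not self.total.covers(self.core):
            raise ValueError("core region must be contained in the total region")

    @classmethod
    def from_rects(cls, total_rect, core_rect) -> "StudyArea":
        """Build from two (xmin, xmax, ymin, ymax) rectangles."""
        tx0, tx1, ty0, ty1 = map(float, total_rect)
        cx0, cx1, cy0, cy1 = map(float, core_rect)
        return cls(
            total=box(tx0, ty0, tx1, ty1),
            core=box(cx0, cy0, cx1, cy1),
            total_rect=(tx0, tx1, ty0, ty1),
            core_rect=(cx0, cx1, cy0, cy1),
        )

    @classmethod
    def from_wkt(cls, total_wkt: str, core_wkt: str) -> "StudyArea":
        return cls(total=shapely.from_wkt(total_wkt), core=shapely.from_wkt(core_wkt))

    @classmethod
    def default(cls) -> "StudyArea":
        """Nested rectangles of 60 km^2 (total) and 40 km^2 (core).

        The total region is 10 x 6 km; the core is a concentric rectangle
        with the same aspect ratio scaled to 40 km^2.
        """
        w, h = 10.0, 6.0
        s = math.sqrt(40.0 / 60.0)
        cw, ch = w * s, h * s
        return cls.from_rects(
            (0.0, w, 0.0, h),
            ((w - cw) / 2, (w + cw) / 2, (h - ch) / 2, (h + ch) / 2),
        )

    def contains_total(self, x, y) -> np.ndarray:
        if self.total_rect is not None:
            x0, x1, y0, y1 = self.total_rect
            x, y = np.asarray(x), np.asarray(y)
            return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
        return shapely.contains_xy(self.total, np.asarray(x), np.asarray(y))

    def contains_core(self, x, y) -> np.ndarray:
        if self.core_rect is not None:
            x0, x1, y0, y1 = self.core_rect
            x, y = np.asarray(x), np.asarray(y)
            return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
        return shapely.contains_xy(self.core, np.asarray(x), np.asarray(y))


@dataclass
class MovementParams:
    """Dispersal-kernel scales, site fidelity and kernel degrees of freedom.

    sigma_move
        2x2 array of kernel scales (km) indexed [age, habitat] with age in
        (fledgling, breeder) and habitat in (Short, Tall).
    p_stay
        Per-habitat probability that a *breeder* reuses its territory site;
        fixed at 0 for fledglings by model structure.
    df
        Student-T degrees of freedom, fixed at 5 across ages and habitats.
    """

    sigma_move: np.ndarray
    p_stay: np.ndarray = field(default_factory=lambda: np.zeros(2))
    df: float = 5.0

    def __post_init__(self) -> None:
        self.sigma_move = np.asarray(self.sigma_move, dtype=float)
        self.p_stay = np.asarray(self.p_stay, dtype=float)
        if self.sigma_move.shape != (2, 2):
            raise ValueError("sigma_move must be 2x2 [age, habitat]")
        if np.any(self.sigma_move <= 0):
            raise ValueError("sigma_move must be positive")
        if self.p_stay.shape != (2,) or np.any((self.p_stay < 0) | (self.p_stay > 1)):
            raise ValueError("p_stay must be two probabilities in [0, 1]")
        if self.df <= 0:
            raise ValueError("df must be positive")

    def p_stay_for(self, age: int, habitat: int) -> float:
        return 0.0 if age == FLEDGLING else float(self.p_stay[habitat])


def kernel_logdensity(
    dest: Location, origin: Location, sigma: float, df: float = 5.0
) -> float:
    """Log density of one dispersal step: independent T(df) in x and y.

    Both axes share the same location-scale T distribution centred on the
    origin with scale ``sigma``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive for a moving step")
    return float(
        stats.t.logpdf(dest.x, df, loc=origin.x, scale=sigma)
        + stats.t.logpdf(dest.y, df, loc=origin.y, scale=sigma)
    )


def sample_next_location(
    origin: Location, age: int, habitat: int, params: MovementParams, rng
) -> tuple[Location, int]:
    """Draw next year's location; returns (location, stay indicator).

    Breeders stay exactly at the origin with probability ``p_stay[habitat]``;
    otherwise (and always for fledglings) the step is T-distributed with the
    age- and habitat-specific scale.
    """
    rng = np.random.default_rng(rng)
    p_stay = params.p_stay_for(age, habitat)
    if p_stay > 0.0 and rng.random() < p_stay:
        return Location(origin.x, origin.y), 1
    sigma = params.sigma_move[age, habitat]
    step = sigma * rng.standard_t(params.df, size=2)
    return Location(origin.x + step[0], origin.y + step[1]), 0


def emigration_probability(
    origin: Location,
    age: int,
    habitat: int,
    params: MovementParams,
    area: StudyArea,
    n_mc: int = 10_000,
    rng=None,
) -> float:
    """Probability that next year's location falls outside the total area.

    Computed as (1 - p_stay) times the Monte-Carlo kernel mass outside
    ``area.total`` for a step starting at ``origin`` (which must lie inside
    the total area).
    """
    if not bool(area.contains_total(origin.x, origin.y)):
        raise ValueError(f"origin {origin} is outside the total study area")
    p_stay = params.p_stay_for(age, habitat)
    if p_stay >= 1.0:
        return 0.0
    rng = np.random.default_rng(rng)
    sigma = params.sigma_move[age, habitat]
    steps = sigma * rng.standard_t(params.df, size=(n_mc, 2))
    inside = area.contains_total(origin.x + steps[:, 0], origin.y + steps[:, 1])
    return float((1.0 - p_stay) * (1.0 - inside.mean()))


def population_emigration_rate(
    origins: list[tuple[Location, int, int]],
    params: MovementParams,
    area: StudyArea,
    n_mc: int = 10_000,
    rng=None,
) -> dict[tuple[int, int], float]:
    """Mean emigration probability per (age, habitat) stratum.

    ``origins`` is a list of (location, age, habitat).  Every stratum present
    in the data gets the arithmetic mean of its members' emigration
    probabilities; strata with no origins are reported as NaN (missing), not
    as zero.
    """
    if not origins:
        raise ValueError("empty origin list")
    rng = np.random.default_rng(rng)
    sums: dict[tuple[int, int], list[float]] = {}
    for loc, age, habitat in origins:
        p = emigration_probability(loc, age, habitat, params, area, n_mc, rng)
        sums.setdefault((age, habitat), []).append(p)
    out: dict[tuple[int, int], float] = {}
    for age in (FLEDGLING, BREEDER):
        for habitat in (0, 1):
            vals = sums.get((age, habitat))
            out[(age, habitat)] = float(np.mean(vals)) if vals else float("nan")
    return out
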