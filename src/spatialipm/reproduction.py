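"""Likelihoods for breeding success and fledgling production.

Reproduction is a two-step process.  The number of successful sites in
habitat ``h`` and year ``t`` is binomial,

    B_{h,t} ~ Bin(R_{h,t}, b_{h,t}),

over the ``R`` monitored sites with known outcome.  The total fledgling
count ``F`` over the ``S`` successful sites with known brood size is at
least ``S`` by definition, so the excess is modelled as Poisson,

    F_{h,t} - S_{h,t} ~ Poisson(2 f_{h,t} S_{h,t} - S_{h,t}),

where ``2 f`` is the expected total brood per successful site and ``f`` is
the per-sex expectation under an even sex ratio.  The rate is non-negative
only when ``f >= 1/2``; values below are rejected rather than truncated.

Both rates carry an intercept plus Gaussian random year effects on the link
scale: logit for ``b``, log for ``f``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "BreedingSuccessData",
    "FledglingData",
    "YearEffectSpec",
    "breeding_success_loglik",
    "fledgling_loglik",
    "expand_year_effects",
]


@dataclass
class BreedingSuccessData:
    """Trials/successes for one habitat-year: B successful of R monitored."""

    year: int
    habitat: int
    r: int
    b_obs: int

    def __post_init__(self) -> None:
        if not 0 <= self.b_obs <= self.r:
            raise ValueError(f"need 0 <= B <= R, got B={self.b_obs}, R={self.r}")


@dataclass
class FledglingData:
    """Successful-site count S and total fledglings F for one habitat-year."""

    year: int
    habitat: int
    s: int
    f_obs: int

    def __post_init__(self) -> None:
        if self.s < 0 or self.f_obs < self.s:
            raise ValueError(f"need F >= S >= 0, got F={self.f_obs}, S={self.s}")


@dataclass
class YearEffectSpec:
    """Intercept + random-year-effect specification on a link scale."""

    intercept: float
    sd: float
    link: str  # "logit" or "log"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("year-effect sd must be non-negative")
        if self.link not in ("logit", "log"):
            raise ValueError(f"unknown link {self.link!r}")


def breeding_success_loglik(data: BreedingSuccessData, b: float) -> float:
    """Log binomial pmf of B successes in R trials at success probability b."""
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"b must be in [0, 1], got {b}")
    return float(stats.binom.logpmf(data.b_obs, data.r, b))


def fledgling_loglik(data: FledglingData, f: float) -> float:
    """Log shifted-Poisson pmf: (F - S) ~ Poisson(2 f S - S).

    With ``S = 0`` there is no data and the contribution is 0.  At the
    boundary ``f = 1/2`` the rate is zero and the distribution degenerates
    to a point mass at ``F = S``.
    """
    if data.s == 0:
        return 0.0
    if f < 0.5:
        raise ValueError(
            f"f={f} implies a negative Poisson rate (requires f >= 0.5 when S > 0)"
        )
    rate = 2.0 * f * data.s - data.s
    k = data.f_obs - data.s
    if rate == 0.0:
        return 0.0 if k == 0 else -np.inf
    return float(stats.poisson.logpmf(k, rate))


def expand_year_effects(spec: YearEffectSpec, effects) -> np.ndarray:
    """Map intercept + per-year effects to natural-scale rates.

    logit link -> inverse-logit(intercept + effect) in (0, 1);
    log link -> exp(intercept + effect) > 0.
    """
    eta = spec.intercept + np.asarray(effects, dtype=float)
    if spec.link == "logit":
        return special.expit(eta)
    return np.exp(eta)
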