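"""Habitat-structured population projection and source-sink metrics.

The population is structured by two breeding habitats -- ``Short`` (short or
sparse ground vegetation) and ``Tall`` -- and a single adult age class.  The
deterministic core is the annual projection

    NB_{t+1} = A_t NB_t + Im_{t+1},

where ``NB`` holds the number of breeders per habitat, ``Im`` the net
immigrants (a residual that may be negative), and ``A_t`` is a 2x2 Leslie
matrix combining local recruitment (breeding success x brood size x
first-year survival) with breeder survival, each split between the two
habitats by constant habitat-switch probabilities.

The per-capita contribution of habitat ``h`` in year ``t``,

    C_{h,t} = b_{h,t} f_{h,t} phi_fl_{h,t} + phi_br_{h,t},

is the expected number of individuals alive next year stemming from one
breeder (itself included).  A habitat is a *source* when C > 1 and a *sink*
when C < 1; the classification here is made on posterior draws via the 95%
credible interval.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Habitat",
    "HABITAT_LABELS",
    "PopulationState",
    "VitalRates",
    "ProjectionMatrix",
    "ContributionEstimate",
    "build_projection_matrix",
    "project_deterministic",
    "project_stochastic",
    "per_capita_contribution",
    "net_immigration",
    "classify_status",
]


class Habitat(enum.IntEnum):
    """The two habitat classes, in the fixed index order (Short, Tall)."""

    SHORT = 0
    TALL = 1


HABITAT_LABELS = ("Short", "Tall")


def _as_pair(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"{name} must have shape (2,) = (Short, Tall), got {a.shape}")
    return a


def _check_prob(x: np.ndarray, name: str) -> np.ndarray:
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return x


@dataclass
class PopulationState:
    """Latent breeder numbers and net immigrants for one year.

    ``nb`` and ``im`` are indexed (Short, Tall).  ``nb`` is non-negative;
    ``im`` may be negative (a net outflow of breeders).
    """

    year: int
    nb: np.ndarray
    im: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.nb = _as_pair(self.nb, "nb")
        self.im = _as_pair(self.im, "im")
        if np.any(self.nb < 0):
            raise ValueError(f"nb must be non-negative, got {self.nb}")


@dataclass
class VitalRates:
    """Per-habitat vital rates for one year.

    b
        Breeding success probability (site produces at least one fledgling).
    f
        Fledglings of the modelled sex per successful site (>= 0).
    phi_fl, phi_br
        First-year (fledgling) and breeder annual survival probabilities.
    psi_fl, psi_br
        Probability of breeding in the *other* habitat than the natal /
        previous breeding habitat.  Constant across years in the full model.
    """

    year: int
    b: np.ndarray
    f: np.ndarray
    phi_fl: np.ndarray
    phi_br: np.ndarray
    psi_fl: np.ndarray
    psi_br: np.ndarray

    def __post_init__(self) -> None:
        self.b = _check_prob(_as_pair(self.b, "b"), "b")
        self.f = _as_pair(self.f, "f")
        if np.any(self.f < 0):
            raise ValueError(f"f must be non-negative, got {self.f}")
        for name in ("phi_fl", "phi_br", "psi_fl", "psi_br"):
            setattr(self, name, _check_prob(_as_pair(getattr(self, name), name), name))


@dataclass
class ProjectionMatrix:
    """2x2 habitat-structured Leslie matrix A_t (entries >= 0)."""

    a: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.a.shape != (2, 2):
            raise ValueError(f"A must be 2x2, got {self.a.shape}")
        if np.any(self.a < 0):
            raise ValueError("A entries must be non-negative")


@dataclass
class ContributionEstimate:
    """Per-capita contribution C per habitat with source/sink status.

    ``status`` per habitat is "source" if the lower 95% CI bound exceeds 1,
    "sink" if the upper bound is below 1, and "uncertain" otherwise.  For
    point values (no draws) the CI collapses onto the value.
    """

    year: int
    c: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    status: tuple[str, str]


def build_projection_matrix(v: VitalRates) -> ProjectionMatrix:
    """Assemble the 2x2 Leslie matrix A_t from one year's vital rates.

    Column ``h`` (origin habitat) contributes ``b_h f_h phi_fl_h`` recruits
    routed by the natal switch ``psi_fl_h`` plus surviving breeders routed by
    the breeding switch ``psi_br_h``; diagonal entries keep the (1 - psi)
    share, off-diagonal entries the psi share.
    """
    recruit = v.b * v.f * v.phi_fl
    a = np.empty((2, 2))
    for h in (0, 1):
        stay_r, switch_r = 1.0 - v.psi_fl[h], v.psi_fl[h]
        stay_s, switch_s = 1.0 - v.psi_br[h], v.psi_br[h]
        a[h, h] = recruit[h] * stay_r + v.phi_br[h] * stay_s
        a[1 - h, h] = recruit[h] * switch_r + v.phi_br[h] * switch_s
    return ProjectionMatrix(a)


def project_deterministic(
    state_t: PopulationState, a: ProjectionMatrix, im_next
) -> PopulationState:
    """One deterministic projection step: NB_{t+1} = A_t NB_t + Im_{t+1}.

    No clipping is applied: a sufficiently negative ``im_next`` can produce a
    negative result, which `PopulationState` will reject -- this is
    intentional, as latent breeder numbers cannot be negative while the
    residual immigration term legitimately can.
    """
    im_next = _as_pair(im_next, "im_next")
    nb_next = a.a @ state_t.nb + im_next
    return PopulationState(year=state_t.year + 1, nb=nb_next, im=im_next)


def project_stochastic(
    state_t: PopulationState, v: VitalRates, im_next, rng
) -> PopulationState:
    """One demographically stochastic projection step.

    Recruits arriving in habitat ``j`` from habitat ``h`` are Poisson with
    mean ``b_h f_h phi_fl_h rho(h->j) NB_h``; breeders from ``h`` are split by
    a three-outcome categorical (stay, switch, die) with probabilities
    ``(phi_br_h (1-psi_br_h), phi_br_h psi_br_h, 1-phi_br_h)``.  The
    expectation of the result equals `project_deterministic`'s.
    """
    rng = np.random.default_rng(rng)
    nb = np.asarray(state_t.nb)
    if not np.allclose(nb, np.round(nb)):
        raise ValueError("stochastic projection requires integer-valued nb")
    nb = np.round(nb).astype(np.int64)
    im_next = _as_pair(im_next, "im_next")

    recruit = v.b * v.f * v.phi_fl
    nb_next = im_next.copy()
    for h in (0, 1):
        rho = np.array([1.0 - v.psi_fl[h], v.psi_fl[h]])
        if h == 1:
            rho = rho[::-1]
        nb_next += rng.poisson(recruit[h] * rho * nb[h])
        p_stay = v.phi_br[h] * (1.0 - v.psi_br[h])
        p_switch = v.phi_br[h] * v.psi_br[h]
        stay, switch, _dead = rng.multinomial(
            nb[h], [p_stay, p_switch, 1.0 - p_stay - p_switch]
        )
        nb_next[h] += stay
        nb_next[1 - h] += switch
    if np.any(nb_next < 0):
        raise ValueError(
            f"projected breeder numbers are negative ({nb_next}); "
            "net immigration is too negative for the realized local production"
        )
    return PopulationState(year=state_t.year + 1, nb=nb_next, im=im_next)


def per_capita_contribution(v: VitalRates) -> np.ndarray:
    """Point per-capita contribution C_h = b_h f_h phi_fl_h + phi_br_h.

    Independent of the habitat-switch probabilities psi: an emigrant to the
    other habitat still counts towards its habitat of origin.  Equals the
    column sums of `build_projection_matrix(v)`.
    """
    return v.b * v.f * v.phi_fl + v.phi_br


def net_immigration(
    nb_series: list[PopulationState], a_series: list[ProjectionMatrix]
) -> np.ndarray:
    """Net immigration residuals Im_{t+1} = NB_{t+1} - A_t NB_t.

    ``a_series`` holds A_t for each transition, so it must be one element
    shorter than ``nb_series`` (or equal length, in which case the final
    matrix is unused).  Returns an array of shape (len(nb_series) - 1, 2);
    positive values indicate a surplus relative to the local projection.
    """
    n = len(nb_series)
    if n < 2:
        raise ValueError("need at least two population states")
    if len(a_series) not in (n - 1, n):
        raise ValueError(
            f"need {n - 1} projection matrices for {n} states, got {len(a_series)}"
        )
    out = np.empty((n - 1, 2))
    for t in range(n - 1):
        out[t] = nb_series[t + 1].nb - a_series[t].a @ nb_series[t].nb
    return out


def classify_status(
    c_samples: np.ndarray, year: int = 0, ci: float = 0.95
) -> ContributionEstimate:
    """Classify habitats as source/sink/uncertain from posterior draws of C.

    ``c_samples`` has shape (n_draws, 2).  Source: lower CI bound > 1;
    sink: upper CI bound < 1; otherwise uncertain.
    """
    c_samples = np.asarray(c_samples, dtype=float)
    if c_samples.ndim == 1:
        c_samples = c_samples[:, None]
    if c_samples.shape[0] == 0:
        raise ValueError("empty posterior sample")
    alpha = (1.0 - ci) / 2.0
    lo = np.quantile(c_samples, alpha, axis=0)
    hi = np.quantile(c_samples, 1.0 - alpha, axis=0)
    mean = c_samples.mean(axis=0)
    status = tuple(
        "source" if lo[h] > 1.0 else ("sink" if hi[h] < 1.0 else "uncertain")
        for h in range(c_samples.shape[1])
    )
    return ContributionEstimate(year=year, c=mean, ci_low=lo, ci_high=hi, status=status)
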