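"""Spatial multi-event mark-resight model: states, events, likelihoods.

Hidden states per individual-year: 0 = alive in Short habitat, 1 = alive in
Tall habitat, 2 = dead (absorbing).  Observed events use the field codes
1 = seen in Short, 2 = seen in Tall, 3 = seen but habitat undetermined,
4 = not seen.

The state process is a categorical transition through the matrix Omega
(survival phi and habitat switch psi, both age-specific); the movement
process places surviving individuals by the Student-T random walk of
:mod:`spatialipm.movement`; the observation process maps states to events
through the matrix theta built from detection probability ``p`` and
habitat-determination probability ``c``, which depend on the monitoring
zone (core / peripheral) of the individual's location and are zero outside
the total study area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .movement import (
    BREEDER,
    FLEDGLING,
    Location,
    MovementParams,
    StudyArea,
    kernel_logdensity,
)

__all__ = [
    "ALIVE_SHORT",
    "ALIVE_TALL",
    "DEAD",
    "EVENT_SEEN_SHORT",
    "EVENT_SEEN_TALL",
    "EVENT_SEEN_UNDET",
    "EVENT_NOT_SEEN",
    "EncounterHistory",
    "LatentTrack",
    "DetectionParams",
    "build_state_transition",
    "build_observation_matrix",
    "detection_zone",
    "augmented_joint_logdensity",
    "nonspatial_history_loglik",
]

ALIVE_SHORT, ALIVE_TALL, DEAD = 0, 1, 2
EVENT_SEEN_SHORT, EVENT_SEEN_TALL, EVENT_SEEN_UNDET, EVENT_NOT_SEEN = 1, 2, 3, 4
_SEEN = (EVENT_SEEN_SHORT, EVENT_SEEN_TALL, EVENT_SEEN_UNDET)


@dataclass
class EncounterHistory:
    """One individual's annual events from marking onwards.

    ``events[k]`` is the event in year ``first_year + k`` (field codes 1-4),
    with ``events[0]`` the marking occasion (always a "seen" code).  ``x`` and
    ``y`` hold sighting coordinates (km) and are NaN exactly where the
    individual was not seen.
    """

    id: str
    sex: str
    first_year: int
    mark_age: int  # FLEDGLING or BREEDER
    mark_habitat: int  # habitat at first capture
    events: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.events.shape == self.x.shape == self.y.shape):
            raise ValueError("events, x, y must have equal length")
        if self.events.size == 0 or self.events[0] not in _SEEN:
            raise ValueError("event at first capture must be a 'seen' code")
        if not np.all((self.events >= 1) & (self.events <= 4)):
            raise ValueError("events must use codes 1-4")
        seen = self.events != EVENT_NOT_SEEN
        if np.any(seen & (np.isnan(self.x) | np.isnan(self.y))):
            raise ValueError("sighting locations required whenever seen")
        if np.any(~seen & (~np.isnan(self.x) | ~np.isnan(self.y))):
            raise ValueError("locations must be absent when not seen")

    @property
    def n_occasions(self) -> int:
        return int(self.events.size)

    def age_at(self, k: int) -> int:
        """Age index at occasion k: fledgling only in the marking year when
        marked as a nestling, breeder otherwise."""
        return FLEDGLING if (self.mark_age == FLEDGLING and k == 0) else BREEDER


@dataclass
class LatentTrack:
    """Latent (state, location, stay) path aligned with an EncounterHistory.

    ``states[k]`` in {0, 1, 2}; ``x/y[k]`` are the latent coordinates,
    NaN once dead; ``stay[k]`` is the site-fidelity indicator for the
    transition k -> k+1 (used for breeders; last entry unused).
    """

    states: np.ndarray
    x: np.ndarray
    y: np.ndarray
    stay: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.stay is None:
            self.stay = np.zeros_like(self.states)
        self.stay = np.asarray(self.stay, dtype=np.int64)
        dead = self.states == DEAD
        if np.any(dead[:-1] & ~dead[1:]):
            raise ValueError("dead state is absorbing")
        if np.any(~dead & (np.isnan(self.x) | np.isnan(self.y))):
            raise ValueError("locations must be defined while alive")


@dataclass
class DetectionParams:
    """Detection (p) and habitat-determination (c) probabilities per zone.

    Constant across years for a given sex; ``p`` is structurally zero
    outside the total study area.
    """

    p_core: float
    p_peripheral: float
    c_core: float
    c_peripheral: float

    def __post_init__(self) -> None:
        for name in ("p_core", "p_peripheral", "c_core", "c_peripheral"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def p_at(self, zone: str) -> float:
        return {"core": self.p_core, "peripheral": self.p_peripheral, "outside": 0.0}[zone]

    def c_at(self, zone: str) -> float:
        # c is only meaningful where detection is possible; outside it is moot
        return {"core": self.c_core, "peripheral": self.c_peripheral, "outside": 0.0}[zone]


def build_state_transition(phi_s, phi_t, psi_s, psi_t) -> np.ndarray:
    """The 3x3 state transition matrix Omega.

    Rows index the current state (alive-Short, alive-Tall, dead), columns the
    next state; rows sum to one and death is absorbing.
    """
    for name, v in (("phi_s", phi_s), ("phi_t", phi_t), ("psi_s", psi_s), ("psi_t", psi_t)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return np.array(
        [
            [phi_s * (1.0 - psi_s), phi_s * psi_s, 1.0 - phi_s],
            [phi_t * psi_t, phi_t * (1.0 - psi_t), 1.0 - phi_t],
            [0.0, 0.0, 1.0],
        ]
    )


def build_observation_matrix(p, c) -> np.ndarray:
    """The 3x4 observation matrix theta.

    Rows index the latent state, columns the events (seen-Short, seen-Tall,
    seen-undetermined, not-seen); a dead individual is never seen.
    """
    if not 0.0 <= p <= 1.0 or not 0.0 <= c <= 1.0:
        raise ValueError(f"p and c must be in [0, 1], got p={p}, c={c}")
    return np.array(
        [
            [p * c, 0.0, p * (1.0 - c), 1.0 - p],
            [0.0, p * c, p * (1.0 - c), 1.0 - p],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def detection_zone(loc: Location, area: StudyArea) -> str:
    """Monitoring zone of a location: 'core', 'peripheral' or 'outside'."""
    if bool(area.contains_core(loc.x, loc.y)):
        return "core"
    if bool(area.contains_total(loc.x, loc.y)):
        return "peripheral"
    return "outside"


def _vitals_at(vitals, k: int):
    """Vital rates for transition occasion k: accepts one VitalRates used for
    all years or a sequence indexed by occasion."""
    if isinstance(vitals, (list, tuple)):
        return vitals[k]
    return vitals


def _log(x: float) -> float:
    return float(np.log(x)) if x > 0.0 else -np.inf


def augmented_joint_logdensity(
    history: EncounterHistory,
    track: LatentTrack,
    vitals,
    movement: MovementParams,
    det: DetectionParams,
    area: StudyArea,
) -> float:
    """Joint log density of a latent track and the observed events.

    Sums, over post-marking occasions, the state-transition terms (Omega),
    the movement terms (site-fidelity Bernoulli plus kernel density for
    movers; the first transition of an individual marked as a nestling uses
    the natal-dispersal scale), and the observation terms (theta with p and
    c taken from the detection zone of the latent location).  The likelihood
    conditions on the first release: state and location at marking are known
    and contribute no terms.

    A track inconsistent with the history (seen while latent-dead, or seen
    at a location different from the latent one) has density zero and
    returns ``-inf``.
    """
    n = history.n_occasions
    if track.states.shape != (n,):
        raise ValueError("track length must match history length")
    if track.states[0] != history.mark_habitat:
        return -np.inf
    logp = 0.0
    for k in range(n):
        ev = history.events[k]
        z = track.states[k]
        # consistency of track with observations
        if ev != EVENT_NOT_SEEN:
            if z == DEAD:
                return -np.inf
            if abs(track.x[k] - history.x[k]) > 1e-9 or abs(track.y[k] - history.y[k]) > 1e-9:
                return -np.inf
            if ev == EVENT_SEEN_SHORT and z != ALIVE_SHORT:
                return -np.inf
            if ev == EVENT_SEEN_TALL and z != ALIVE_TALL:
                return -np.inf
        if k > 0:
            # observation term (conditioning on first release skips k == 0)
            if z == DEAD:
                if ev != EVENT_NOT_SEEN:
                    return -np.inf
            else:
                zone = detection_zone(Location(track.x[k], track.y[k]), area)
                theta = build_observation_matrix(det.p_at(zone), det.c_at(zone))
                logp += _log(theta[z, ev - 1])
        if k < n - 1:
            # state transition k -> k+1
            v = _vitals_at(vitals, k)
            age = history.age_at(k)
            phi = v.phi_fl if age == FLEDGLING else v.phi_br
            psi = v.psi_fl if age == FLEDGLING else v.psi_br
            omega = build_state_transition(phi[0], phi[1], psi[0], psi[1])
            logp += _log(omega[z, track.states[k + 1]])
            # movement term, only while the individual remains alive
            if z != DEAD and track.states[k + 1] != DEAD:
                origin = Location(track.x[k], track.y[k])
                dest = Location(track.x[k + 1], track.y[k + 1])
                p_stay = movement.p_stay_for(age, int(z))
                if track.stay[k] == 1:
                    if age == FLEDGLING:
                        return -np.inf  # fledglings never use site fidelity
                    if dest.x != origin.x or dest.y != origin.y:
                        return -np.inf
                    logp += _log(p_stay)
                else:
                    logp += _log(1.0 - p_stay)
                    sigma = movement.sigma_move[age, int(z)]
                    logp += kernel_logdensity(dest, origin, sigma, movement.df)
        if not np.isfinite(logp):
            return -np.inf
    return float(logp)


def nonspatial_history_loglik(history: EncounterHistory, vitals, p: float, c: float) -> float:
    """Exact marginal log likelihood of one history, ignoring locations.

    Forward algorithm over the three hidden states with spatially constant
    detection ``p`` and habitat-determination ``c`` (the non-spatial model
    variant).  Conditions on the first release.
    """
    n = history.n_occasions
    if n <= 1:
        return 0.0
    theta = build_observation_matrix(p, c)
    alpha = np.zeros(3)
    alpha[history.mark_habitat] = 1.0
    for k in range(1, n):
        v = _vitals_at(vitals, k - 1)
        age = history.age_at(k - 1)
        phi = v.phi_fl if age == FLEDGLING else v.phi_br
        psi = v.psi_fl if age == FLEDGLING else v.psi_br
        omega = build_state_transition(phi[0], phi[1], psi[0], psi[1])
        alpha = (alpha @ omega) * theta[:, history.events[k] - 1]
    return _log(float(alpha.sum()))
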