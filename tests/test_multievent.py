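import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from spatialipm._cmr import pack_encounters, spatial_loglik
from spatialipm.demography import VitalRates
from spatialipm.movement import Location, MovementParams, StudyArea
from spatialipm.multievent import (
    ALIVE_SHORT,
    ALIVE_TALL,
    DEAD,
    DetectionParams,
    EncounterHistory,
    LatentTrack,
    augmented_joint_logdensity,
    build_observation_matrix,
    build_state_transition,
    detection_zone,
    nonspatial_history_loglik,
)

probs = st.floats(0.0, 1.0, allow_nan=False)


def vitals(phi_fl=(0.2, 0.15), phi_br=(0.5, 0.5), psi_fl=(0.1, 0.2), psi_br=(0.05, 0.1)):
    return VitalRates(
        year=0, b=(0.5, 0.5), f=(2, 2), phi_fl=phi_fl, phi_br=phi_br,
        psi_fl=psi_fl, psi_br=psi_br,
    )


class TestStateTransition:
    def test_printed_row(self):
        omega = build_state_transition(0.5, 0.6, 0.1, 0.2)
        assert np.allclose(omega[0], (0.45, 0.05, 0.50), atol=1e-12)

    def test_certain_survival_no_switch_is_identity_on_alive(self):
        omega = build_state_transition(1.0, 1.0, 0.0, 0.0)
        assert np.allclose(omega[:2, :2], np.eye(2))

    def test_no_survival_sends_all_to_dead(self):
        omega = build_state_transition(0.0, 0.0, 0.3, 0.3)
        assert np.allclose(omega[:, 2], (1, 1, 1))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(probs, probs, probs, probs)
    def test_rows_are_distributions_and_death_absorbs(self, ps, pt, qs, qt):
        omega = build_state_transition(ps, pt, qs, qt)
        assert np.allclose(omega.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(omega >= 0)
        assert np.allclose(omega[2], (0, 0, 1))


class TestObservationMatrix:
    def test_printed_row(self):
        theta = build_observation_matrix(0.6, 0.9)
        assert np.allclose(theta[0], (0.54, 0.0, 0.06, 0.40), atol=1e-12)

    def test_no_detection(self):
        theta = build_observation_matrix(0.0, 0.5)
        assert np.allclose(theta[:, 3], (1, 1, 1))

    def test_perfect_habitat_resolved_detection(self):
        theta = build_observation_matrix(1.0, 1.0)
        assert np.allclose(theta[:2, :2], np.eye(2))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(probs, probs)
    def test_rows_are_distributions_and_dead_unseen(self, p, c):
        theta = build_observation_matrix(p, c)
        assert np.allclose(theta.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(theta[2], (0, 0, 0, 1))


class TestDetectionZone:
    def test_zones(self):
        area = StudyArea.default()
        cx = (area.core_rect[0] + area.core_rect[1]) / 2
        cy = (area.core_rect[2] + area.core_rect[3]) / 2
        assert detection_zone(Location(cx, cy), area) == "core"
        assert detection_zone(Location(0.2, 0.2), area) == "peripheral"
        assert detection_zone(Location(100.0, 100.0), area) == "outside"


def history(events, x, y, mark_age=1, mark_habitat=0):
    return EncounterHistory(
        id="i1", sex="M", first_year=0,
        mark_age=mark_age, mark_habitat=mark_habitat,
        events=np.asarray(events), x=np.asarray(x, float), y=np.asarray(y, float),
    )


def enumerate_marginal(hist, v, p, c):
    """Brute-force marginal likelihood over all latent state paths."""
    theta = build_observation_matrix(p, c)
    total = []
    n = hist.n_occasions
    for path in itertools.product((ALIVE_SHORT, ALIVE_TALL, DEAD), repeat=n - 1):
        states = (hist.mark_habitat,) + path
        lp = 0.0
        for k in range(1, n):
            age = hist.age_at(k - 1)
            phi = v.phi_fl if age == 0 else v.phi_br
            psi = v.psi_fl if age == 0 else v.psi_br
            omega = build_state_transition(phi[0], phi[1], psi[0], psi[1])
            tr = omega[states[k - 1], states[k]]
            em = theta[states[k], hist.events[k] - 1]
            if tr == 0 or em == 0:
                lp = -np.inf
                break
            lp += math.log(tr) + math.log(em)
        total.append(lp)
    return logsumexp(total)


class TestNonspatialLikelihood:
    @pytest.mark.parametrize(
        "events", [[1, 4], [1, 3], [2, 2, 4], [1, 4, 3], [2, 4, 4]]
    )
    def test_matches_path_enumeration(self, events):
        v = vitals()
        x = [0.0 if e != 4 else np.nan for e in events]
        hist = history(events, x, x, mark_habitat=events[0] - 1 if events[0] < 3 else 0)
        got = nonspatial_history_loglik(hist, v, p=0.5, c=0.5)
        want = enumerate_marginal(hist, v, 0.5, 0.5)
        assert got == pytest.approx(want, abs=1e-10)

    def test_perfect_detection_reduces_to_transition_product(self):
        v = vitals()
        hist = history([1, 1, 2], [0, 0, 0], [0, 0, 0])
        got = nonspatial_history_loglik(hist, v, p=1.0, c=1.0)
        want = math.log(v.phi_br[0] * (1 - v.psi_br[0])) + math.log(
            v.phi_br[0] * v.psi_br[0]
        )
        assert got == pytest.approx(want, abs=1e-12)

    def test_history_of_single_occasion_contributes_nothing(self):
        hist = history([1], [0.0], [0.0])
        assert nonspatial_history_loglik(hist, vitals(), 0.5, 0.5) == 0.0


@pytest.fixture
def area():
    return StudyArea.default()


@pytest.fixture
def movement():
    return MovementParams(
        sigma_move=np.array([[1.5, 2.0], [0.4, 0.6]]), p_stay=np.array([0.5, 0.35])
    )


class TestAugmentedDensity:
    def test_faithful_resident_hand_computation(self, area):
        # breeder marked and resighted at the same core site, certain
        # detection and survival: only fidelity and transition terms remain
        mv = MovementParams(sigma_move=np.ones((2, 2)), p_stay=np.array([0.8, 0.8]))
        det = DetectionParams(1.0, 1.0, 1.0, 1.0)
        v = vitals(phi_br=(1.0, 1.0), psi_br=(0.1, 0.1))
        cx = (area.core_rect[0] + area.core_rect[1]) / 2
        cy = (area.core_rect[2] + area.core_rect[3]) / 2
        hist = history([1, 1], [cx, cx], [cy, cy])
        track = LatentTrack(
            states=[ALIVE_SHORT, ALIVE_SHORT], x=[cx, cx], y=[cy, cy], stay=[1, 0]
        )
        got = augmented_joint_logdensity(hist, track, v, mv, det, area)
        assert got == pytest.approx(math.log(0.8) + math.log(1.0 * 0.9), abs=1e-12)

    def test_seen_while_latent_dead_is_impossible(self, area, movement):
        det = DetectionParams(0.9, 0.5, 0.9, 0.8)
        hist = history([1, 1], [5, 5], [3, 3])
        track = LatentTrack(states=[ALIVE_SHORT, DEAD], x=[5, np.nan], y=[3, np.nan])
        got = augmented_joint_logdensity(hist, track, vitals(), movement, det, area)
        assert got == -np.inf

    def test_matches_spatial_forward_on_two_occasion_history(self, area, movement):
        """Sum over enumerable (state, stay) latent tracks with locations
        fixed at the sightings equals the spatial forward-algorithm
        marginal."""
        det = DetectionParams(0.9, 0.5, 0.9, 0.8)
        v = vitals()
        cx = (area.core_rect[0] + area.core_rect[1]) / 2
        cy = (area.core_rect[2] + area.core_rect[3]) / 2
        for events, dest in [
            ([1, 1], (cx + 0.7, cy - 0.4)),
            ([1, 3], (cx + 2.5, cy + 1.0)),
            ([2, 2], (cx - 1.2, cy + 0.3)),
        ]:
            hist = history(
                events,
                [cx, dest[0]],
                [cy, dest[1]],
                mark_habitat=0 if events[0] == 1 else 1,
            )
            terms = []
            for z1 in (ALIVE_SHORT, ALIVE_TALL):
                track = LatentTrack(
                    states=[hist.mark_habitat, z1],
                    x=[cx, dest[0]],
                    y=[cy, dest[1]],
                    stay=[0, 0],
                )
                terms.append(
                    augmented_joint_logdensity(hist, track, v, movement, det, area)
                )
            want = logsumexp(terms)

            import pandas as pd

            years = np.array([2001, 2002])
            df = pd.DataFrame(
                {
                    "id": ["i1"], "sex": ["M"], "mark_year": [2001],
                    "mark_age": ["breeder"],
                    "mark_habitat": ["Short" if hist.mark_habitat == 0 else "Tall"],
                    "event_2001": [events[0]], "x_2001": [cx], "y_2001": [cy],
                    "event_2002": [events[1]], "x_2002": [dest[0]], "y_2002": [dest[1]],
                }
            )
            packed = pack_encounters(df, years)
            tsteps, ustay = packed.particle_draws(16, 0)
            phi = np.empty((2, 2, 2))
            phi[:, 0, :] = v.phi_fl
            phi[:, 1, :] = v.phi_br
            psi = np.stack([np.asarray(v.psi_fl), np.asarray(v.psi_br)])
            got = spatial_loglik(
                packed.first, packed.mark_fl, packed.mark_hab, packed.events,
                packed.ox, packed.oy, tsteps, ustay,
                phi, psi, movement.sigma_move, movement.p_stay, 5.0,
                np.array([det.p_core, det.p_peripheral]),
                np.array([det.c_core, det.c_peripheral]),
                np.array(area.total_rect), np.array(area.core_rect),
            )
            assert got == pytest.approx(want, abs=1e-10)

    def test_exact_stay_resighting_uses_fidelity_atom(self, area, movement):
        """A breeder seen twice at precisely the same site is a stay event:
        the marginal equals the enumeration with the atom convention."""
        det = DetectionParams(0.9, 0.5, 0.9, 0.8)
        v = vitals()
        cx = (area.core_rect[0] + area.core_rect[1]) / 2
        cy = (area.core_rect[2] + area.core_rect[3]) / 2
        hist = history([1, 1], [cx, cx], [cy, cy])
        track_stay = LatentTrack(
            states=[ALIVE_SHORT, ALIVE_SHORT], x=[cx, cx], y=[cy, cy], stay=[1, 0]
        )
        want = augmented_joint_logdensity(hist, track_stay, v, movement, det, area)

        import pandas as pd

        df = pd.DataFrame(
            {
                "id": ["i1"], "sex": ["M"], "mark_year": [2001],
                "mark_age": ["breeder"], "mark_habitat": ["Short"],
                "event_2001": [1], "x_2001": [cx], "y_2001": [cy],
                "event_2002": [1], "x_2002": [cx], "y_2002": [cy],
            }
        )
        packed = pack_encounters(df, np.array([2001, 2002]))
        tsteps, ustay = packed.particle_draws(16, 0)
        phi = np.empty((2, 2, 2))
        phi[:, 0, :] = v.phi_fl
        phi[:, 1, :] = v.phi_br
        psi = np.stack([np.asarray(v.psi_fl), np.asarray(v.psi_br)])
        got = spatial_loglik(
            packed.first, packed.mark_fl, packed.mark_hab, packed.events,
            packed.ox, packed.oy, tsteps, ustay,
            phi, psi, movement.sigma_move, movement.p_stay, 5.0,
            np.array([det.p_core, det.p_peripheral]),
            np.array([det.c_core, det.c_peripheral]),
            np.array(area.total_rect), np.array(area.core_rect),
        )
        assert got == pytest.approx(want, abs=1e-10)


class TestEncounterHistoryInvariants:
    def test_first_event_must_be_seen(self):
        with pytest.raises(ValueError):
            history([4, 1], [np.nan, 0.0], [np.nan, 0.0])

    def test_locations_required_iff_seen(self):
        with pytest.raises(ValueError):
            history([1, 2], [0.0, np.nan], [0.0, np.nan])
        with pytest.raises(ValueError):
            history([1, 4], [0.0, 1.0], [0.0, 1.0])
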