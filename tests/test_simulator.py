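import numpy as np
import pytest
from scipy import special

from spatialipm.demography import PopulationState, ProjectionMatrix, net_immigration
from spatialipm.movement import FLEDGLING, Location, population_emigration_rate
from spatialipm.multievent import DetectionParams
from spatialipm.simulate import (
    SimScenario,
    closed_area,
    closed_scenario,
    generate_landscape,
    reduced_scenario,
    simulate_dataset,
    wheatear_scenario,
)


class TestLandscape:
    def test_deterministic_given_seed(self):
        a = generate_landscape(rng_seed=7)
        b = generate_landscape(rng_seed=7)
        assert a.sites.equals(b.sites)

    def test_requested_core_site_count(self):
        land = generate_landscape(n_core_sites=124, n_peripheral_sites=51, rng_seed=1)
        assert int(land.sites["in_core"].sum()) == 124
        assert len(land.sites) == 175
        assert np.all(
            land.area.contains_total(land.sites["x"].to_numpy(), land.sites["y"].to_numpy())
        )

    def test_habitat_mix_within_binomial_interval(self):
        land = generate_landscape(n_core_sites=300, n_peripheral_sites=0, prop_short=0.6, rng_seed=2)
        n_short = int((land.sites["habitat"] == 0).sum())
        se = np.sqrt(300 * 0.6 * 0.4)
        assert abs(n_short - 180) < 3 * se

    def test_zero_area_rejected(self):
        from spatialipm.movement import StudyArea

        with pytest.raises(ValueError):
            StudyArea.from_rects((0, 0, 0, 0), (0, 0, 0, 0))


class TestSimulatedStreams:
    def test_deterministic_given_seed(self, reduced_landscape):
        s1 = simulate_dataset(reduced_landscape, reduced_scenario(seed=4))
        s2 = simulate_dataset(reduced_landscape, reduced_scenario(seed=4))
        assert s1.counts.equals(s2.counts)
        assert s1.encounters.equals(s2.encounters)

    def test_default_scenario_sizes(self):
        land = generate_landscape(rng_seed=3)
        sim = simulate_dataset(land, wheatear_scenario(seed=1))
        n_fl = int((sim.encounters["mark_age"] == "fledgling").sum())
        n_br = int((sim.encounters["mark_age"] == "breeder").sum())
        assert 1000 <= n_fl <= 1500
        assert 250 <= n_br <= 405
        assert sim.truth["nb"].shape == (15, 2)

    def test_immortal_residents_always_resighted(self, reduced_landscape):
        sc = reduced_scenario(
            seed=2,
            b_intercept=(-20.0, -20.0),
            phi_br_intercept=(20.0, 20.0),
            phi_br_sd=(0.0, 0.0),
            psi_br=(0.0, 0.0),
            detection=DetectionParams(1.0, 1.0, 1.0, 1.0),
            immigration=None,
            n_mark_fledglings=0,
        )
        import dataclasses

        sc = dataclasses.replace(
            sc,
            movement=dataclasses.replace(sc.movement, p_stay=np.array([1.0, 1.0])),
        )
        sim = simulate_dataset(reduced_landscape, sc)
        enc = sim.encounters
        assert len(enc) > 0
        for _, row in enc.iterrows():
            xs = []
            for yr in range(int(row["mark_year"]), 2011):
                ev = int(row[f"event_{yr}"])
                assert ev == (1 if row["mark_habitat"] == "Short" else 2)
                xs.append((row[f"x_{yr}"], row[f"y_{yr}"]))
            assert all(p == xs[0] for p in xs)

    def test_sightings_never_outside_total_area(self, reduced_landscape):
        sim = simulate_dataset(reduced_landscape, reduced_scenario(seed=8))
        area = reduced_landscape.area
        for yr in range(2001, 2011):
            seen = sim.encounters[f"event_{yr}"].isin([1, 2, 3])
            xs = sim.encounters.loc[seen, f"x_{yr}"].to_numpy()
            ys = sim.encounters.loc[seen, f"y_{yr}"].to_numpy()
            assert np.all(area.contains_total(xs, ys))

    def test_huge_dispersal_scale_destroys_apparent_survival(self, reduced_landscape):
        import dataclasses

        sc = reduced_scenario(seed=5)
        sc = dataclasses.replace(
            sc,
            movement=dataclasses.replace(
                sc.movement, sigma_move=np.array([[50.0, 50.0], [0.4, 0.6]])
            ),
        )
        sim = simulate_dataset(reduced_landscape, sc)
        assert sim.truth["emigration_rate"][0].min() > 0.9
        fl = sim.encounters[sim.encounters["mark_age"] == "fledgling"]
        resighted = 0
        for _, row in fl.iterrows():
            for yr in range(int(row["mark_year"]) + 1, 2011):
                if int(row[f"event_{yr}"]) in (1, 2, 3):
                    resighted += 1
                    break
        assert resighted / max(len(fl), 1) < 0.03
        # the generating survival itself is untouched
        assert sim.truth["mean_rates"]["phi_fl"][0] > 0.1

    def test_extinction_returns_flag_not_exception(self, reduced_landscape):
        sc = reduced_scenario(
            seed=1,
            initial_nb=(4, 3),
            phi_br_intercept=(special.logit(0.05), special.logit(0.05)),
            phi_fl_intercept=(special.logit(0.02), special.logit(0.02)),
            immigration=None,
        )
        sim = simulate_dataset(reduced_landscape, sc)
        assert sim.extinct


class TestGenerativeConsistency:
    def test_breeding_success_matches_generating_rates(self, reduced_landscape):
        sim = simulate_dataset(reduced_landscape, reduced_scenario(seed=6))
        bs = sim.breeding_success
        rates = sim.truth["rates"]["b"]
        for t in range(10):
            for h, lab in enumerate(("Short", "Tall")):
                row = bs[(bs.year == 2001 + t) & (bs.habitat == lab)].iloc[0]
                if row.R < 10:
                    continue
                se = np.sqrt(rates[t, h] * (1 - rates[t, h]) / row.R)
                assert abs(row.B / row.R - rates[t, h]) < 4 * se + 0.02

    def test_realized_fledgling_emigration_matches_kernel_prediction(
        self, reduced_landscape
    ):
        """Natal dispersal starts at territory sites, so the realized
        emigration fraction must match the kernel mass outside the area
        averaged over sites."""
        sim = simulate_dataset(reduced_landscape, reduced_scenario(seed=7))
        sc = reduced_scenario(seed=7)
        sites = reduced_landscape.sites
        for h in (0, 1):
            sub = sites[sites["habitat"] == h]
            origins = [
                (Location(r.x, r.y), FLEDGLING, h) for r in sub.itertuples()
            ]
            pred = population_emigration_rate(
                origins, sc.movement, reduced_landscape.area, n_mc=4000, rng=1
            )[(FLEDGLING, h)]
            got = sim.truth["emigration_rate"][FLEDGLING, h]
            n = sim.truth["emigration_trials"][FLEDGLING, h]
            se = np.sqrt(pred * (1 - pred) / max(n, 1))
            assert abs(got - pred) < 3 * se + 0.02

    def test_closed_population_residuals_average_to_zero(self, closed_landscape):
        ims = []
        for seed in range(4):
            sim = simulate_dataset(closed_landscape, closed_scenario(seed=40 + seed))
            nb, a = sim.truth["nb"], sim.truth["A"]
            states = [PopulationState(t, nb[t]) for t in range(len(nb))]
            mats = [ProjectionMatrix(a[t]) for t in range(len(nb) - 1)]
            ims.append(net_immigration(states, mats).mean(axis=0))
        grand = np.mean(ims, axis=0)
        assert np.all(np.abs(grand) < 2.0)

    def test_scenario_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            SimScenario(detection=DetectionParams(1.2, 0.5, 0.9, 0.8))

    def test_closed_area_geometry(self):
        area = closed_area()
        assert area.total.area > 1e5
        assert area.total.covers(area.core)
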