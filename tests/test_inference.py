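import numpy as np
import pytest

from spatialipm.demography import per_capita_contribution
from spatialipm.inference import (
    FitConfig,
    Posterior,
    fit_ipm,
    posterior_predictive_check,
    prob_difference_positive,
    rhat,
    summarize_posterior,
)
from spatialipm.io import bundle_from_sim
from spatialipm.simulate import reduced_scenario, simulate_dataset


class TestRhat:
    def test_identical_chains_converge_to_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=1000)
        assert rhat(np.stack([chain, chain])) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(100, 1, 1000)])
        assert rhat(chains) > 10

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(4, 5000))
        assert rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        for _ in range(3):
            chains = np.cumsum(rng.normal(size=(3, 400)), axis=1) * 0.05 + rng.normal(
                size=(3, 1)
            )
            theirs = float(az.rhat(chains, method="split"))
            assert rhat(chains) == pytest.approx(theirs, abs=0.02)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))


class TestProbDifference:
    def test_two_thirds_example(self):
        assert prob_difference_positive([1, 2, 3], [2, 1, 1]) == pytest.approx(2 / 3)

    def test_identical_samples_give_zero(self):
        a = np.arange(10.0)
        assert prob_difference_positive(a, a) == 0.0

    def test_uniform_shift_gives_one(self):
        a = np.arange(10.0)
        assert prob_difference_positive(a + 1, a) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            prob_difference_positive([1, 2], [1, 2, 3])


def _toy_posterior(draws_c=None, n=2000, seed=0):
    rng = np.random.default_rng(seed)
    shape = (1, n)
    mk = lambda v: np.broadcast_to(v, shape + np.shape(v)).copy()
    nb = mk(np.full((4, 2), 30.0))
    if draws_c is None:
        draws_c = rng.uniform(0, 1, size=shape + (3, 2))
    return Posterior(
        draws={
            "nb": nb,
            "b": mk(np.full((4, 2), 0.7)),
            "f": mk(np.full((4, 2), 2.5)),
            "phi_fl": mk(np.full((3, 2), 0.2)),
            "phi_br": mk(np.full((3, 2), 0.5)),
            "C": draws_c,
            "im": mk(np.zeros((3, 2))),
            "im_rate": mk(np.zeros((3, 2))),
        },
        variant="spatial",
        years=np.arange(2001, 2005),
    )


class TestSummaries:
    def test_constant_draws_have_zero_width(self):
        post = _toy_posterior()
        table = summarize_posterior(post)
        row = table[table.parameter == "b_Short"].iloc[0]
        assert row["mean"] == pytest.approx(0.7)
        assert row["ci_low"] == pytest.approx(row["ci_high"])

    def test_uniform_draws_quantiles(self):
        rng = np.random.default_rng(5)
        post = _toy_posterior(
            draws_c=rng.uniform(0, 1, size=(1, 30_000, 3, 2)), n=30_000
        )
        c = post.stacked("C")[:, 0, 0]
        assert np.quantile(c, 0.025) == pytest.approx(0.025, abs=0.01)
        assert np.quantile(c, 0.975) == pytest.approx(0.975, abs=0.01)

    def test_zero_immigration_rate_summary(self):
        table = summarize_posterior(_toy_posterior())
        row = table[table.parameter == "omega_im_Short"].iloc[0]
        assert row["mean"] == 0.0


class TestFitBehaviour:
    def test_zero_resightings_warns_and_completes(self, reduced_landscape):
        sim = simulate_dataset(reduced_landscape, reduced_scenario(seed=60))
        enc = sim.encounters.copy()
        for col in enc.columns:
            if col.startswith("event_"):
                yr = int(col.split("_")[1])
                post_mark = enc["mark_year"] < yr
                enc.loc[post_mark, col] = 4
                enc.loc[post_mark, f"x_{yr}"] = np.nan
                enc.loc[post_mark, f"y_{yr}"] = np.nan
        sim.encounters = enc
        bundle = bundle_from_sim(sim, reduced_landscape.area)
        cfg = FitConfig.desk(
            seed=1, n_chains=2, n_adapt=60, n_burn=20, n_iter=60, thin=2,
            variant="nonspatial",
        )
        with pytest.warns(UserWarning, match="no resightings"):
            post = fit_ipm(bundle, cfg)
        assert post.n_draws > 0

    def test_posterior_roundtrip_and_rhat_table(self, tmp_path, emig_experiments):
        _, post, _ = emig_experiments[0]
        path = tmp_path / "post.npz"
        post.save(path)
        loaded = Posterior.load(path)
        assert loaded.variant == post.variant
        for key in post.draws:
            assert np.allclose(loaded.draws[key], post.draws[key], equal_nan=True)
        # convergence diagnostics computable for the headline parameters
        for name in ("alpha_phi_fl", "alpha_phi_br"):
            for h in range(2):
                r = rhat(post.draws[name][:, :, h])
                assert np.isfinite(r) and r < 1.5

    def test_contribution_draws_consistent_with_vital_rates(self, emig_experiments):
        """Derived C draws equal the contribution formula applied draw-wise."""
        _, post, _ = emig_experiments[0]
        b = post.stacked("b")[:, :-1, :]
        f = post.stacked("f")[:, :-1, :]
        phi_fl = post.stacked("phi_fl")
        phi_br = post.stacked("phi_br")
        want = b * f * phi_fl + phi_br
        assert np.allclose(post.stacked("C"), want, atol=1e-10)

    def test_contribution_matches_demography_module(self, emig_experiments):
        from spatialipm.demography import VitalRates

        _, post, _ = emig_experiments[0]
        j, t = 5, 2
        v = VitalRates(
            year=t,
            b=post.stacked("b")[j, t],
            f=post.stacked("f")[j, t],
            phi_fl=post.stacked("phi_fl")[j, t],
            phi_br=post.stacked("phi_br")[j, t],
            psi_fl=post.stacked("psi_fl")[j],
            psi_br=post.stacked("psi_br")[j],
        )
        assert np.allclose(per_capita_contribution(v), post.stacked("C")[j, t])


class TestPosteriorPredictiveChecks:
    def test_model_generated_data_not_flagged(self, emig_experiments, reduced_landscape):
        sim, post, _ = emig_experiments[0]
        bundle = bundle_from_sim(sim, reduced_landscape.area)
        pvals = posterior_predictive_check(post, bundle, n_draws=150, seed=1)
        for name in ("counts", "breeding", "fledglings"):
            assert 0.02 <= pvals[name] <= 0.98, f"{name} flagged: {pvals[name]}"
        assert 0.0 <= pvals["cmr"] <= 1.0

    def test_corrupted_counts_flagged(self, emig_experiments, reduced_landscape):
        sim, post, _ = emig_experiments[0]
        counts = sim.counts.copy()
        counts.loc[counts.index[4], "count"] *= 10
        sim2 = type(sim)(
            counts=counts,
            breeding_success=sim.breeding_success,
            fledglings=sim.fledglings,
            encounters=sim.encounters,
            truth=sim.truth,
        )
        bundle = bundle_from_sim(sim2, reduced_landscape.area)
        pvals = posterior_predictive_check(post, bundle, n_draws=150, seed=1)
        assert pvals["counts"] < 0.05 or pvals["counts"] > 0.95
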