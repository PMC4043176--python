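"""Evidence estimation, model enumeration, ranking and posterior means."""

import math
import warnings

import numpy as np
import pytest
from scipy.special import logsumexp

from applause.bayes_selection import (
    EvidenceEstimate,
    Prior,
    default_prior,
    enumerate_models,
    estimate_evidence,
    loglik_batch,
    model_from_name,
    posterior_mean,
    rank_models,
)
from applause.event_data import make_stop_observations
from applause.starting_models import PackedStartData
from applause.stopping_models import PackedStopData
from conftest import best_fit_study, toy_bout


@pytest.fixture(scope="module")
def toy_stop_data():
    return PackedStopData.from_observations(make_stop_observations(toy_bout()), n_max=10)


class TestEnumeration:
    def test_sixteen_models_per_family(self):
        for family in ("start", "stop"):
            models = enumerate_models(family)
            assert len(models) == 16
            assert len({m.name for m in models}) == 16

    def test_purely_social_stop_masks_flagged_impossible(self):
        models = {m.name: m for m in enumerate_models("stop")}
        assert models["G2"].structurally_impossible
        assert models["G4"].structurally_impossible
        assert models["G2+G4"].structurally_impossible
        assert not models["G1+G2"].structurally_impossible

    def test_restricted_family_allows_purely_social(self):
        models = {m.name: m for m in enumerate_models("stop", restricted=True)}
        assert not models["G2"].structurally_impossible


class TestEvidence:
    def test_no_free_parameters_gives_exact_likelihood(self, toy_stop_data):
        model = model_from_name("stop", "G1")
        fixed = Prior(names=(), dists=())
        est = estimate_evidence(model, toy_stop_data, prior=fixed, seed=1)
        # with an empty parameter vector the expanded model has gamma1=0,
        # which cannot explain the stops: exact value, zero error
        assert est.se == 0.0
        assert est.log_evidence == loglik_batch(model, toy_stop_data, np.empty((1, 0)))[0]

    def test_seeded_determinism(self, toy_stop_data):
        model = model_from_name("stop", "G1")
        a = estimate_evidence(model, toy_stop_data, n_samples=2000, seed=7)
        b = estimate_evidence(model, toy_stop_data, n_samples=2000, seed=7)
        assert a == b

    def test_logsumexp_shift_invariance(self, toy_stop_data):
        """The estimator equals the naive mean computed under a large
        constant shift that is removed afterwards (to 1e-10 relative)."""
        model = model_from_name("stop", "G1")
        est = estimate_evidence(model, toy_stop_data, n_samples=4000, replicates=2, seed=3)
        ss = np.random.SeedSequence(3)
        prior = default_prior(model)
        values = []
        for child in ss.spawn(2):
            rng = np.random.default_rng(child)
            theta = prior.sample(rng, 4000)
            ll = loglik_batch(model, toy_stop_data, theta)
            shift = -float(ll.max())  # arbitrary stabilising shift, removed below
            values.append(float(np.log(np.mean(np.exp(ll + shift))) - shift))
        assert est.log_evidence == pytest.approx(float(np.mean(values)), rel=1e-10)

    def test_all_impossible_draws_reported(self, toy_stop_data):
        model = model_from_name("stop", "G2")  # first stop has rho_stopped = 0
        est = estimate_evidence(model, toy_stop_data, n_samples=500, seed=0)
        assert est.log_evidence == -math.inf
        assert "zero likelihood" in est.diagnostic

    def test_monte_carlo_error_scales_inverse_sqrt(self, toy_stop_data):
        model = model_from_name("stop", "G1+G3")
        ses = {}
        for n in (400, 1600):
            reps = [
                estimate_evidence(model, toy_stop_data, n_samples=n, replicates=4, seed=s).se
                for s in range(12)
            ]
            ses[n] = np.mean(reps)
        ratio = ses[400] / ses[1600]
        assert 1.3 < ratio < 3.1  # ideal: 2


class TestGridOracle:
    def test_importance_sampling_matches_quadrature_on_toy_bout(self, toy_stop_data):
        from _oracles import grid_evidence

        for name in ("G1", "G3", "G1+G3", "G_stop"):
            model = model_from_name("stop", name)
            est = estimate_evidence(model, toy_stop_data, n_samples=20_000, seed=11)
            oracle = grid_evidence(model, toy_stop_data)
            assert abs(est.log_evidence - oracle) <= 3 * max(est.se, 1e-3), name


class TestRanking:
    def _est(self, name, lz, se=0.01):
        return EvidenceEstimate(name, lz, se, 1000, 8)

    def test_relative_probabilities_normalise(self):
        table = rank_models([self._est("a", math.log(0.5)), self._est("b", math.log(0.25))])
        assert list(table.model) == ["a", "b"]
        assert table.rel_prob.to_numpy() == pytest.approx([2 / 3, 1 / 3])

    def test_identical_estimates_flagged_tied(self):
        table = rank_models([self._est("a", -10.0), self._est("b", -10.0)])
        assert bool(table.loc[0, "unresolved_with_next"])

    def test_clear_gap_resolved(self):
        table = rank_models([self._est("a", -10.0), self._est("b", -20.0)])
        assert not table.loc[0, "unresolved_with_next"]

    def test_impossible_model_gets_zero_probability(self):
        table = rank_models([self._est("a", -5.0), self._est("b", -math.inf)])
        assert table.loc[1, "rel_prob"] == 0.0


class TestPosteriorMean:
    def test_flat_likelihood_returns_prior_mean(self, toy_stop_data):
        # gamma2 multiplies rho_stopped, which is zero for every toy clap
        # except the two late stops; use data where it is always zero
        obs = [o for o in make_stop_observations(toy_bout()) if o.rho_stopped == 0.0]
        data = PackedStopData.from_observations(obs, n_max=10)
        model = model_from_name("stop", "G1+G2")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = posterior_mean(model, data, n_samples=100_000, seed=5)
        assert summary.means["gam2"] == pytest.approx(0.5, abs=0.02)

    def test_conjugate_beta_geometric_oracle(self):
        """Constant stopping with a flat prior is Beta-conjugate: with s
        stops and f continuations the posterior mean is (1+s)/(2+s+f)."""
        obs = make_stop_observations(toy_bout())
        data = PackedStopData.from_observations(obs, n_max=10)
        s = int(sum(o.stopped for o in obs))
        f = len(obs) - s
        model = model_from_name("stop", "G1")
        summary = posterior_mean(model, data, n_samples=200_000, seed=9)
        exact = (1 + s) / (2 + s + f)
        assert summary.means["gam1"] == pytest.approx(exact, abs=0.003)

    def test_low_ess_warns(self):
        bouts = best_fit_study(seed=2)
        data = PackedStartData.from_bouts(bouts[:6], dt=0.1)
        model = model_from_name("start", "L1+L2+L3+L4")
        with pytest.warns(UserWarning, match="effective sample size"):
            posterior_mean(model, data, n_samples=300, seed=0)
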