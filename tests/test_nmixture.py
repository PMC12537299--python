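"""M0 likelihood kernel, grid-posterior oracle, MCMC fit, diagnostics."""

import itertools
import math

import numpy as np
import pytest

from straitpop.nmixture import (
    NMixtureConfig,
    NMixtureData,
    diagnostics,
    fit_nmixture,
    grid_posterior,
    m0_loglik_kernel,
    nmixture_data_from_events,
)
from straitpop.synthetic import SimulationScenario, simulate_capture_history

from conftest import make_events


class TestKernel:
    def test_hand_evaluated_log_factorial_case(self):
        # N=5, n_distinct=4, y_total=6, T=2, p=0.5:
        # ln(5!/1!) + 6 ln(1/2) + (10-6) ln(1/2) = ln 120 + 10 ln 0.5
        data = NMixtureData("hand", T=2, u=(4, 0), y_total=6)
        want = math.log(120) + 10 * math.log(0.5)
        assert m0_loglik_kernel(5, 0.5, data) == pytest.approx(want, abs=1e-9)

    def test_fewer_animals_than_detected_is_impossible(self):
        data = NMixtureData("hand", T=2, u=(4, 0), y_total=6)
        assert m0_loglik_kernel(3, 0.5, data) == -math.inf

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.3])
    def test_detection_probability_domain_is_open_unit_interval(self, p):
        data = NMixtureData("hand", T=2, u=(4, 0), y_total=6)
        with pytest.raises(ValueError):
            m0_loglik_kernel(5, p, data)

    @pytest.mark.parametrize("p", [0.2, 0.5, 0.7])
    def test_kernel_normalizes_over_enumerated_capture_histories(self, p):
        # N=3 animals, T=2 occasions: every animal independently gets one of
        # the 4 detection histories. Summing the model probability over all
        # multisets of observed (nonzero) histories must give 1, where the
        # probability of a multiset is exp(kernel) / prod_h f_h! with f_h the
        # multiplicity of each nonzero history.
        N, T = 3, 2
        histories = list(itertools.product([0, 1], repeat=T))
        total = 0.0
        for assign in itertools.combinations_with_replacement(histories, N):
            nonzero = [h for h in assign if any(h)]
            n_distinct = len(nonzero)
            y_total = sum(sum(h) for h in assign)
            mult = 1.0
            for h in set(nonzero):
                mult *= math.factorial(nonzero.count(h))
            if n_distinct == 0:
                total += (1 - p) ** (N * T)
                continue
            u = (n_distinct,) + (0,) * (T - 1)  # kernel depends on sum(u) only
            data = NMixtureData("enum", T=T, u=u, y_total=y_total)
            total += math.exp(m0_loglik_kernel(N, p, data)) / mult
        assert total == pytest.approx(1.0, rel=1e-12)

    def test_removals_shrink_the_at_risk_pool(self):
        with_rem = NMixtureData("r", T=3, u=(5, 2, 0), y_total=8, removals=(2, 0, 0))
        without = NMixtureData("r0", T=3, u=(5, 2, 0), y_total=8)
        # two animals removed before occasions 2 and 3: 4 fewer failure slots
        delta = m0_loglik_kernel(20, 0.3, with_rem) - m0_loglik_kernel(20, 0.3, without)
        assert delta == pytest.approx(-4 * math.log(0.7), abs=1e-9)


class TestGridPosterior:
    def test_symmetric_data_with_known_N_gives_symmetric_p_marginal(self):
        # N fixed at 2 via a one-point grid; y_total = N*T/2 makes the
        # likelihood invariant under p -> 1-p with a flat Beta(1,1) prior
        data = NMixtureData("sym", T=2, u=(2, 0), y_total=2)
        grid = grid_posterior(data, N_grid=np.array([2]))
        marg = grid.p_marginal
        assert np.allclose(marg, marg[::-1], atol=1e-12)
        assert grid.mean("p") == pytest.approx(0.5, abs=1e-9)

    def test_prior_only_posterior_is_the_discretized_prior(self):
        data = NMixtureData("prior", T=3, u=(3, 1, 0), y_total=5)
        cfg = NMixtureConfig(a_p=2.0, b_p=5.0)
        grid = grid_posterior(data, cfg, prior_only=True)
        joint = grid.joint
        # separable: joint = outer(N prior, p prior) after normalization
        outer = np.outer(grid.N_marginal, grid.p_marginal)
        assert np.allclose(joint, outer, atol=1e-12)
        # p marginal matches the Beta(2,5) shape on the grid
        from scipy.stats import beta

        want = beta.pdf(grid.p_grid, 2, 5)
        want /= want.sum()
        assert np.allclose(grid.p_marginal, want, rtol=1e-3)

    def test_stronger_pull_toward_high_p_lowers_abundance(self):
        data = NMixtureData("mono", T=4, u=(8, 4, 2, 1), y_total=20)
        flat = grid_posterior(data, NMixtureConfig(a_p=1, b_p=1))
        pull_up = grid_posterior(data, NMixtureConfig(a_p=20, b_p=1))
        assert pull_up.mean("N") < flat.mean("N")
        assert pull_up.mean("p") > flat.mean("p")


class TestFit:
    def test_full_detection_pins_abundance_at_count(self):
        # every animal seen at every occasion: y_total = N*T identifies p ~ 1
        # and the posterior for N collapses onto n_distinct
        n = 40
        data = NMixtureData("census", T=3, u=(n, 0, 0), y_total=n * 3)
        post = fit_nmixture(data, NMixtureConfig(chains=2, draws=500, tune=300, seed=2))
        lo, hi = post.summary.loc["N", ["ci_low", "ci_high"]]
        assert hi - lo < 1
        assert post.summary.loc["N", "median"] == n

    def test_posterior_support_respects_distinct_count(self):
        data = NMixtureData("sup", T=3, u=(6, 3, 1), y_total=12)
        post = fit_nmixture(data, NMixtureConfig(chains=2, draws=400, tune=200, seed=4))
        assert post.N_draws.min() >= data.n_distinct
        assert 0 < post.p_draws.min() and post.p_draws.max() < 1
        s = post.summary
        assert (s["ci_low"] <= s["ci_high"]).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sampler_agrees_with_grid_oracle(self, seed):
        scenario = SimulationScenario(true_N=300, p=0.15, T=6, tagging_prob=1.0, seed=seed)
        _, truth = simulate_capture_history(scenario)
        data = NMixtureData("sim", T=6, u=tuple(truth.U), y_total=sum(truth.C))
        cfg = NMixtureConfig(chains=4, draws=1000, tune=500, seed=seed + 100)
        post = fit_nmixture(data, cfg)
        grid = grid_posterior(data, cfg)
        for param in ("N", "p"):
            draws = post.N_draws if param == "N" else post.p_draws
            mcse = draws.std() / math.sqrt(post.ess_bulk[param])
            assert post.summary.loc[param, "mean"] == pytest.approx(
                grid.mean(param), abs=3 * max(mcse, 1e-6)
            )
        assert post.converged

    def test_fixed_seed_reproduces_draws_exactly(self):
        data = NMixtureData("rep", T=3, u=(10, 4, 2), y_total=18)
        cfg = NMixtureConfig(chains=2, draws=300, tune=200, seed=77)
        a = fit_nmixture(data, cfg)
        b = fit_nmixture(data, cfg)
        assert np.array_equal(a.p_draws, b.p_draws)
        assert np.array_equal(a.N_draws, b.N_draws)

    def test_too_tight_truncation_is_rejected(self):
        data = NMixtureData("tight", T=3, u=(10, 4, 2), y_total=18)
        with pytest.raises(ValueError, match="N_max"):
            fit_nmixture(data, NMixtureConfig(N_max=100))


class TestDiagnostics:
    def test_iid_chains_pass_rhat(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((4, 2000))
        r, ess = diagnostics({"x": draws})["x"]
        assert r < 1.01
        assert ess > 1000

    def test_disjoint_chains_fail_rhat(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((2, 500))
        draws[1] += 100.0
        r, _ = diagnostics({"x": draws})["x"]
        assert r > 1.1

    def test_constant_chain_is_flagged(self):
        draws = np.ones((2, 500))
        r, _ = diagnostics({"x": draws})["x"]
        assert not r <= 1.01  # degenerate chains never look converged

    def test_single_chain_is_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            diagnostics({"x": np.ones((1, 500))})
        with pytest.raises(ValueError, match="draws"):
            diagnostics({"x": np.ones((2, 50))})


class TestDataFromEvents:
    def test_stratum_statistics_from_event_table(self):
        events = make_events(
            [
                {"tag_id": "A", "event_date": "2024-04-02"},
                {"tag_id": None, "event_date": "2024-04-05",
                 "event_kind": "first_capture_untagged", "released": False},
                {"tag_id": "A", "event_date": "2024-05-11", "event_kind": "recapture"},
                {"tag_id": "B", "event_date": "2024-05-12"},
            ]
        )
        data = nmixture_data_from_events(events, "Kinmen", 2024)
        assert data.T == 2
        assert data.u == (2, 1)
        assert data.removals == (1, 0)
        assert data.y_total == 4
        assert data.n_distinct == 3
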