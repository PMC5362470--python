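"""The Bayesian network meta-analysis model and its MCMC sampler."""

import numpy as np
import pytest

import hccnma as h
from hccnma.nma import NMAModelSpec, build_model, league_table, run_mcmc

SHORT = dict(chains=2, iterations=2000, burn_in=800)


class TestModelBuilding:
    def test_single_design_single_parameter(self, make_contrast_set):
        model = build_model([make_contrast_set("t", "B", "A", 0.5, 0.1)], reference="A")
        assert model.treatments == ["A", "B"]
        assert model.n_params == 1
        np.testing.assert_array_equal(model.X2, [[1.0]])

    def test_triangle_consistency_construction(self, make_contrast_set):
        sets = [
            make_contrast_set("t1", "B", "A", 0.2, 0.1),
            make_contrast_set("t2", "C", "A", 0.5, 0.1),
            make_contrast_set("t3", "C", "B", 0.3, 0.1),
        ]
        model = build_model(sets, reference="A")
        assert model.treatments == ["A", "B", "C"]
        # rows: d_B, d_C, d_C - d_B
        np.testing.assert_array_equal(
            model.X2, [[1.0, 0.0], [0.0, 1.0], [-1.0, 1.0]]
        )

    def test_fixture_horizon_one_has_twelve_parameters(self, hcc_network):
        sim = h.simulate_network(h.fixture_scenario(tau=0.05), seed=2)
        contrasts = h.network_contrasts(sim.network, 1)
        model = build_model(contrasts, reference="TACE")
        assert model.n_params == 12

    def test_disconnected_network_rejected(self, make_contrast_set):
        sets = [
            make_contrast_set("t1", "B", "A", 0.2, 0.1),
            make_contrast_set("t2", "D", "C", 0.3, 0.1),
        ]
        with pytest.raises(ValueError, match="disconnected"):
            build_model(sets, reference="A")


class TestSampler:
    def test_single_contrast_matches_conjugate_posterior(self, make_contrast_set):
        """One trial, vague prior: posterior ~ N(y, se^2) (fixed-effect limit)."""
        sets = [make_contrast_set("t", "B", "A", 0.5, 0.1)]
        model = build_model(sets, reference="A")
        post = run_mcmc(model, NMAModelSpec(reference="A", seed=1, **SHORT))
        d = post.d_matrix()[:, 1]
        assert d.mean() == pytest.approx(0.5, abs=0.02)
        assert d.std() == pytest.approx(0.1, rel=0.10)

    def test_same_seed_bit_identical(self, make_contrast_set):
        sets = [make_contrast_set("t", "B", "A", 0.5, 0.1)]
        model = build_model(sets, reference="A")
        spec = NMAModelSpec(reference="A", seed=42, **SHORT)
        p1 = run_mcmc(model, spec)
        p2 = run_mcmc(model, spec)
        np.testing.assert_array_equal(p1.d, p2.d)
        np.testing.assert_array_equal(p1.tau, p2.tau)

    def test_consistent_triangle_with_tiny_se_recovers_truth(self, make_contrast_set):
        sets = [
            make_contrast_set("t1", "B", "A", 0.2, 0.002),
            make_contrast_set("t2", "C", "A", 0.5, 0.002),
            make_contrast_set("t3", "C", "B", 0.3, 0.002),
        ]
        model = build_model(sets, reference="A")
        post = run_mcmc(
            model, NMAModelSpec(reference="A", seed=3, tau_fixed=0.0, **SHORT)
        )
        med = np.median(post.d_matrix()[:, 1:], axis=0)
        np.testing.assert_allclose(med, [0.2, 0.5], atol=1e-3)

    def test_indirect_only_estimation_adds_means_and_variances(self, make_contrast_set):
        sets = [
            make_contrast_set("t1", "B", "A", 0.5, 0.1),
            make_contrast_set("t2", "C", "B", 0.3, 0.1),
        ]
        model = build_model(sets, reference="A")
        post = run_mcmc(model, NMAModelSpec(reference="A", seed=4, **SHORT))
        ca = post.contrast_draws("C", "A")
        assert ca.mean() == pytest.approx(0.8, abs=0.02)
        assert ca.var() == pytest.approx(0.02, rel=0.10)

    def test_consistency_identity_exact_per_draw(self, small_sim):
        contrasts = h.network_contrasts(small_sim.network, 1)
        model = build_model(contrasts, reference="A")
        post = run_mcmc(model, NMAModelSpec(reference="A", seed=5, **SHORT))
        ab = post.contrast_draws("A", "B")
        bc = post.contrast_draws("B", "C")
        ac = post.contrast_draws("A", "C")
        np.testing.assert_allclose(ac, ab + bc, atol=1e-12)

    def test_prior_dominance_shrinks_estimates(self, make_contrast_set):
        sets = [make_contrast_set("t", "B", "A", 1.0, 0.5)]
        means = []
        for sd in (10.0, 0.1, 0.01):
            model = build_model(sets, reference="A")
            post = run_mcmc(
                model, NMAModelSpec(reference="A", prior_sd=sd, seed=6, **SHORT)
            )
            means.append(abs(post.d_matrix()[:, 1].mean()))
        assert means[0] > means[1] > means[2]

    def test_rhat_reported_for_every_parameter(self, small_sim):
        contrasts = h.network_contrasts(small_sim.network, 1)
        model = build_model(contrasts, reference="A")
        post = run_mcmc(model, NMAModelSpec(reference="A", seed=7, **SHORT))
        assert set(post.rhat) == {"d_B", "d_C", "tau"}
        assert all(v < 1.1 for v in post.rhat.values())

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            NMAModelSpec(chains=1)
        with pytest.raises(ValueError):
            NMAModelSpec(iterations=500)
        with pytest.raises(ValueError):
            NMAModelSpec(tau_upper=0.0)


@pytest.fixture(scope="module")
def fitted(small_sim):
    contrasts = h.network_contrasts(small_sim.network, 1)
    return h.BayesianNMA(reference="A", seed=8, **SHORT).fit(contrasts)


class TestLeagueTable:

    def test_unit_diagonal(self, fitted):
        lt = fitted.league_table()
        np.testing.assert_array_equal(np.diag(lt.median), 1.0)

    def test_reciprocal_symmetry(self, fitted):
        lt = fitted.league_table()
        np.testing.assert_allclose(lt.median * lt.median.T, 1.0, rtol=1e-12)
        np.testing.assert_allclose(lt.low * lt.high.T, 1.0, rtol=1e-12)

    def test_two_treatment_network_equals_direct_posterior(self, make_contrast_set):
        """Degenerate-network oracle: NMA == the single design's pooled estimate."""
        sets = [
            make_contrast_set("t1", "B", "A", 0.4, 0.2),
            make_contrast_set("t2", "B", "A", 0.2, 0.2),
        ]
        fe = h.fixed_effect_pool([s.contrasts[0] for s in sets])
        nma = h.BayesianNMA(reference="A", seed=9, tau_fixed=0.0, **SHORT).fit(sets)
        d = nma.posterior_.d_matrix()[:, 1]
        assert d.mean() == pytest.approx(fe.loghr, abs=0.02)
        assert d.std() == pytest.approx(fe.se, rel=0.10)

    def test_estimator_interface(self, fitted):
        params = fitted.get_params()
        assert params["reference"] == "A"
        clone = h.BayesianNMA(**params)
        assert clone.get_params() == params
        with pytest.raises(RuntimeError):
            h.BayesianNMA().league_table()
        with pytest.raises(ValueError):
            clone.set_params(bogus=1)
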