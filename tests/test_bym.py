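"""Hierarchical Poisson smoothing: sampler correctness and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import embermap as em
from embermap.bym import BYMModel, dic, gelman_rubin, icar_tau_posterior_params, variance_partition
from embermap.errors import InvalidArgumentError


def _smr_frame(O, E, ids=None):
    ids = ids or [f"t{i}" for i in range(len(O))]
    return pd.DataFrame({"area_id": ids, "sex": "male", "O": O, "E": E,
                         "smr_raw": np.asarray(O) / np.asarray(E)})


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((4, 1000))
        assert gelman_rubin(chains) < 1.05

    def test_separated_chains_large(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((2, 500))
        chains[1] += 100.0
        assert gelman_rubin(chains) > 5.0

    def test_single_chain_errors(self):
        with pytest.raises(InvalidArgumentError):
            gelman_rubin(np.zeros((1, 100)))

    def test_constant_chains_error(self):
        with pytest.raises(InvalidArgumentError, match="within-chain"):
            gelman_rubin(np.ones((3, 100)))

    def test_agrees_with_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = np.cumsum(rng.standard_normal((4, 800)), axis=1) * 0.01 + \
            rng.standard_normal((4, 800))
        ours = gelman_rubin(chains)
        ref = float(arviz.rhat(arviz.convert_to_dataset(chains),
                               method="identity").x.values)
        assert ours == pytest.approx(ref, rel=0.02)


class TestGibbsConjugacy:
    def test_icar_precision_posterior_params_hand_derived(self):
        """Gamma(shape, rate) of tau_u | u on a path graph a-b-c.

        Edges (a,b), (b,c): pairwise SS = (u_a-u_b)^2 + (u_b-u_c)^2; three
        active areas, one connected component: shape = a + (3-1)/2.
        """
        g = em.AreaGraph(["a", "b", "c"], {"a": ["b"], "b": ["a", "c"], "c": ["b"]})
        u = np.array([0.3, -0.1, -0.2])
        ss = (0.3 - -0.1) ** 2 + (-0.1 - -0.2) ** 2
        shape, rate = icar_tau_posterior_params(u, g.laplacian(), a=0.5, b=5e-4, n_components=1)
        assert shape == pytest.approx(0.5 + 1.0)
        assert rate == pytest.approx(5e-4 + ss / 2)

    def test_isolate_excluded_from_rank(self):
        with pytest.warns(UserWarning, match="isolated"):
            g = em.AreaGraph(["a", "b", "c"], {"a": ["b"], "b": ["a"], "c": []})
        u = np.array([0.2, -0.2, 0.0])
        shape, rate = icar_tau_posterior_params(u, g.laplacian(), a=0.5, b=5e-4, n_components=1)
        assert shape == pytest.approx(0.5 + (2 - 1) / 2)
        assert rate == pytest.approx(5e-4 + 0.4 ** 2 / 2)


class TestOneAreaPosterior:
    def test_matches_quadrature_oracle(self):
        """Global model, single area, O=5, E=2: the flat prior on the
        intercept makes the marginal posterior of the log-rate flat, so the
        posterior of theta is proportional to theta^(O-1) exp(-E theta).
        The MCMC posterior mean must match the quadrature value within 2
        Monte-Carlo SEs."""
        O, E = 5, 2.0
        post = lambda t: t ** (O - 1) * np.exp(-E * t)
        norm, _ = integrate.quad(post, 0, 50)
        mean_oracle = integrate.quad(lambda t: t * post(t), 0, 50)[0] / norm
        g = em.AreaGraph(["x"], {"x": []})
        tab = _smr_frame([O], [E], ids=["x"])
        model = BYMModel(variant="global", chains=4, iterations=8000,
                         burn_in=3000, seed=21).fit(tab, g)
        draws = model.fit_.theta_draws().ravel()
        # MC SE via per-chain means (accounts for autocorrelation crudely)
        chain_means = model.fit_.theta_draws()[:, :, 0].mean(axis=1)
        mc_se = chain_means.std(ddof=1) / np.sqrt(len(chain_means))
        assert abs(draws.mean() - mean_oracle) < 2 * mc_se + 0.02 * mean_oracle


class TestShrinkage:
    def test_global_shrinks_uncertain_areas_harder(self):
        """An area with tiny E and raw SMR 6 is pulled toward the national
        mean more strongly than a well-measured area with the same SMR."""
        rng = np.random.default_rng(4)
        n = 30
        E = np.full(n, 20.0)
        O = rng.poisson(E)  # background areas near SMR 1
        E[0], O[0] = 0.5, 3      # raw SMR 6, tiny E
        E[1], O[1] = 50.0, 300   # raw SMR 6, large E
        tab = _smr_frame(O, E)
        g = em.generate_lattice(5, 6, seed=5)
        tab["area_id"] = g.area_ids
        model = BYMModel(variant="global", chains=2, iterations=4000,
                         burn_in=2000, seed=6).fit(tab, g)
        sm = model.theta_
        assert 1.0 < sm[0] < 6.0
        assert 1.0 < sm[1] < 6.0
        assert sm[0] < sm[1]  # tiny-E area smoothed further toward 1

    def test_local_pulls_toward_neighbour_mean(self):
        """A high-SMR area surrounded by well-measured SMR-1 neighbours is
        pulled toward the neighbours under the ICAR-only model."""
        g = em.generate_lattice(5, 5, seed=7)
        E = np.full(25, 50.0)
        O = np.full(25, 50)
        centre = 12  # middle of the grid
        O[centre] = 150  # raw SMR 3
        tab = _smr_frame(O, E, ids=list(g.area_ids))
        model = BYMModel(variant="local", chains=2, iterations=4000,
                         burn_in=2000, seed=8).fit(tab, g)
        assert model.theta_[centre] < 2.9
        assert model.theta_[centre] > 1.1

    def test_large_equal_E_converges_to_raw(self):
        """With E = 500 everywhere the data dominate: smoothed ~ raw."""
        g = em.generate_lattice(4, 5, seed=9)
        rng = np.random.default_rng(10)
        E = np.full(20, 500.0)
        theta = rng.lognormal(0, 0.2, 20)
        O = rng.poisson(E * theta)
        tab = _smr_frame(O, E, ids=list(g.area_ids))
        model = BYMModel(variant="convolution", chains=2, iterations=6000,
                         burn_in=3000, seed=11).fit(tab, g)
        assert np.max(np.abs(model.theta_ - tab["smr_raw"])) < 0.05


@pytest.fixture(scope="module")
def fitted(grid10, small_scenario):
    _, counts, _ = small_scenario
    tab = em.smr_table(counts, (1999, 2007), "male")
    model = BYMModel(variant="convolution", chains=2, iterations=1500,
                     burn_in=700, seed=12).fit(tab, grid10)
    return tab, model


class TestFitMechanics:

    def test_sum_to_zero_every_draw(self, fitted):
        _, model = fitted
        sums = model.fit_.u.sum(axis=2)
        assert np.max(np.abs(sums)) < 1e-10

    def test_reproducible_bit_for_bit(self, grid10, small_scenario):
        _, counts, _ = small_scenario
        tab = em.smr_table(counts, (1999, 2007), "male")
        kw = dict(variant="convolution", chains=2, iterations=400, burn_in=200, seed=13)
        f1 = BYMModel(**kw).fit(tab, grid10).fit_
        f2 = BYMModel(**kw).fit(tab, grid10).fit_
        np.testing.assert_array_equal(f1.alpha, f2.alpha)
        np.testing.assert_array_equal(f1.u, f2.u)
        np.testing.assert_array_equal(f1.tau_v, f2.tau_v)

    def test_posterior_mean_within_draw_envelope(self, fitted):
        _, model = fitted
        th = model.fit_.theta_draws().reshape(-1, model.fit_.n_areas)
        assert np.all(model.theta_ >= th.min(axis=0) - 1e-12)
        assert np.all(model.theta_ <= th.max(axis=0) + 1e-12)

    def test_smoothed_table_join(self, fitted):
        tab, model = fitted
        out = model.smoothed_table(tab)
        assert {"smr_smooth", "smr_lo", "smr_hi"} <= set(out.columns)
        assert len(out) == len(tab)

    def test_smoothed_table_id_mismatch_errors(self, fitted):
        tab, model = fitted
        bad = tab.copy()
        bad.loc[0, "area_id"] = "nonexistent"
        with pytest.raises(InvalidArgumentError, match="match"):
            model.smoothed_table(bad)

    def test_invalid_specs_rejected(self, fitted, grid10):
        tab, _ = fitted
        with pytest.raises(InvalidArgumentError):
            BYMModel(chains=1).fit(tab, grid10)
        with pytest.raises(InvalidArgumentError):
            BYMModel(iterations=100, burn_in=100).fit(tab, grid10)
        with pytest.raises(InvalidArgumentError):
            BYMModel(variant="besag").fit(tab, grid10)
        bad = tab.copy()
        bad.loc[0, "E"] = 0.0
        with pytest.raises(InvalidArgumentError, match="expected"):
            BYMModel().fit(bad, grid10)

    def test_sklearn_param_interface(self):
        model = BYMModel(variant="local", iterations=123)
        params = model.get_params()
        assert params["variant"] == "local"
        model.set_params(variant="global")
        assert model.variant == "global"


class TestDIC:
    def test_single_draw_pd_zero(self):
        fit = em.BYMFit(
            variant="global", area_ids=["a", "b"],
            O=np.array([3.0, 5.0]), E=np.array([4.0, 4.0]),
            alpha=np.zeros((2, 1)), u=np.zeros((2, 1, 2)), v=np.zeros((2, 1, 2)),
            tau_u=np.ones((2, 1)), tau_v=np.ones((2, 1)),
        )
        dbar, p_d, d = dic(fit)
        assert p_d == pytest.approx(0.0, abs=1e-9)
        assert d == pytest.approx(dbar)

    def test_saturated_beats_intercept_on_heterogeneous_data(self):
        O = np.array([2.0, 40.0, 9.0, 25.0])
        E = np.array([10.0, 10.0, 10.0, 10.0])
        common = dict(variant="global", area_ids=list("abcd"), O=O, E=E,
                      tau_u=np.ones((2, 1)), tau_v=np.ones((2, 1)))
        sat = em.BYMFit(alpha=np.zeros((2, 1)),
                        u=np.zeros((2, 1, 4)),
                        v=np.tile(np.log(O / E), (2, 1, 1)), **common)
        flat = em.BYMFit(alpha=np.full((2, 1), np.log(O.sum() / E.sum())),
                         u=np.zeros((2, 1, 4)), v=np.zeros((2, 1, 4)), **common)
        assert dic(sat)[0] < dic(flat)[0]


class TestVariancePartition:
    def _fit_with(self, u, v):
        m, d, n = u.shape
        return em.BYMFit(
            variant="convolution", area_ids=[str(i) for i in range(n)],
            O=np.ones(n), E=np.ones(n), alpha=np.zeros((m, d)),
            u=u, v=v, tau_u=np.ones((m, d)), tau_v=np.ones((m, d)),
        )

    def test_zero_v_gives_psi_one(self):
        rng = np.random.default_rng(14)
        u = rng.standard_normal((2, 10, 8))
        psi, lo, hi = variance_partition(self._fit_with(u, np.zeros_like(u)))
        assert (psi, lo, hi) == (1.0, 1.0, 1.0)

    def test_zero_u_gives_psi_zero(self):
        rng = np.random.default_rng(15)
        v = rng.standard_normal((2, 10, 8))
        psi, lo, hi = variance_partition(self._fit_with(np.zeros_like(v), v))
        assert (psi, lo, hi) == (0.0, 0.0, 0.0)

    def test_requires_convolution(self):
        fit = em.BYMFit(
            variant="global", area_ids=["a"], O=np.ones(1), E=np.ones(1),
            alpha=np.zeros((2, 2)), u=np.zeros((2, 2, 1)), v=np.zeros((2, 2, 1)),
            tau_u=np.ones((2, 2)), tau_v=np.ones((2, 2)),
        )
        with pytest.raises(InvalidArgumentError):
            variance_partition(fit)

    def test_conditional_method_uses_precisions(self):
        rng = np.random.default_rng(16)
        u = rng.standard_normal((2, 50, 8))
        v = rng.standard_normal((2, 50, 8))
        fit = self._fit_with(u, v)
        fit.tau_u[:] = 1.0   # sigma_u^2 = 1
        fit.tau_v[:] = 4.0   # sigma_v^2 = 0.25
        psi, _, _ = variance_partition(fit, method="conditional")
        assert psi == pytest.approx(1.0 / 1.25)
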