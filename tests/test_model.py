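"""Convolution model layer: design coding, contracts, posterior
invariants, diagnostics, persistence, and independent cross-checks."""

import numpy as np
import pandas as pd
import pytest

from neighwalk.exceptions import (
    CategorySupportError,
    ContractError,
    InsufficientChainsError,
    InvalidArgumentError,
)
from neighwalk.model import (
    BYMLogistic,
    BYMOrdinal,
    MCMCConfig,
    PosteriorSamples,
    check_convergence,
    design_from_cohort,
)
from neighwalk.simulate import GeneratorConfig, generate_cohort


class TestDesignFromCohort:
    def test_categorical_dummy_coding(self):
        df = pd.DataFrame({"a": [1, 2, 3, 1], "b": [0.5, 1.5, 2.5, 3.5], "s": [0, 1, 0, 1]})
        X, names = design_from_cohort(df, ["a", "b", "s"], intercept=True)
        assert names == ["intercept", "a[2]", "a[3]", "b", "s[1]"]
        assert np.array_equal(X[:, 1], [0, 1, 0, 0])
        assert np.array_equal(X[:, 4], [0, 1, 0, 1])

    def test_unknown_term_rejected(self):
        df = pd.DataFrame({"a": [1, 2]})
        with pytest.raises(InvalidArgumentError):
            design_from_cohort(df, ["zz"])


class TestModelContracts:
    def test_logistic_requires_binary(self, small_cohort):
        cohort, graph = small_cohort
        with pytest.raises(InvalidArgumentError):
            BYMLogistic.from_cohort(cohort, "walk_time_nbhd_cat", ["sex_male"], graph=graph)

    def test_ordinal_requires_three_categories(self, small_cohort):
        cohort, graph = small_cohort
        work = cohort.copy()
        work["y2"] = (work["walk_time_nbhd_cat"] > 2).astype(int) + 1
        with pytest.raises(CategorySupportError):
            BYMOrdinal.from_cohort(work, "y2", ["sex_male"], graph=graph)

    def test_unobserved_category_warns(self, small_cohort):
        cohort, graph = small_cohort
        work = cohort.copy()
        work["yc"] = work["walk_time_nbhd_cat"].clip(upper=4)  # collapse 4-5
        with pytest.warns(UserWarning, match="unobserved"):
            BYMOrdinal.from_cohort(work, "yc", ["sex_male"], graph=graph, n_categories=5)

    def test_graph_requires_groups(self, small_cohort):
        cohort, graph = small_cohort
        with pytest.raises(InvalidArgumentError):
            BYMLogistic(
                endog=cohort["walk_any"].to_numpy(),
                exog=np.ones((len(cohort), 1)),
                graph=graph,
            )


class TestPosteriorInvariants:
    def test_car_effects_sum_to_zero_every_iteration(self, logistic_fit):
        v = logistic_fit.samples.flat("v")
        assert np.abs(v.sum(axis=1)).max() < 1e-8

    def test_variance_parameters_positive(self, logistic_fit):
        assert (logistic_fit.samples.flat("sigma_u") > 0).all()
        assert (logistic_fit.samples.flat("tau_v") > 0).all()

    def test_cutpoints_ordered_every_draw(self, ordinal_fit):
        kap = ordinal_fit.samples.flat("kappa")
        assert (np.diff(kap, axis=1) > 0).all()

    def test_deterministic_given_seed(self, small_cohort):
        cohort, graph = small_cohort
        cfg = MCMCConfig(n_chains=2, n_iter=300, n_burnin=100, seed=5)
        r1 = BYMLogistic.from_cohort(cohort, "walk_any", ["sex_male"], graph=graph).fit(cfg)
        r2 = BYMLogistic.from_cohort(cohort, "walk_any", ["sex_male"], graph=graph).fit(cfg)
        for k in r1.samples.draws:
            assert np.array_equal(r1.samples.draws[k], r2.samples.draws[k])

    def test_posterior_contraction_with_sample_size(self):
        """Doubling the cohort shrinks the credible interval for beta."""
        widths = []
        for npn, seed in [(15, 3), (60, 3)]:
            cfg = GeneratorConfig(
                lattice_rows=6, lattice_cols=6, n_per_neighborhood=npn, vary_n=False,
                true_betas={"sex_male[1]": np.log(1.4)}, true_betas_ordinal={},
                sigma_u=0.2, tau_v=0.3, missing_rate=0.0, seed=seed,
            )
            cohort, graph = generate_cohort(cfg)
            res = BYMLogistic.from_cohort(cohort, "walk_any", ["sex_male"], graph=graph).fit(
                MCMCConfig(n_iter=1600, n_burnin=600, seed=11)
            )
            s = res.summary().loc["beta[sex_male[1]]"]
            widths.append(s["ci_97.5%"] - s["ci_2.5%"])
        assert widths[1] < widths[0]

    def test_neighborhood_relabeling_leaves_betas_unchanged(self, small_cohort):
        """Consistently relabeling neighborhood ids (order-preserving map,
        matching graph) is a pure renaming: identical draws."""
        from neighwalk.graphs import AdjacencyGraph

        cohort, graph = small_cohort
        mapping = {nid: nid * 10 for nid in graph.node_ids}
        graph2 = AdjacencyGraph(
            node_ids=[mapping[n] for n in graph.node_ids],
            edges=[(mapping[a], mapping[b]) for a, b in graph.edges],
        )
        cohort2 = cohort.copy()
        cohort2["neighborhood_id"] = cohort2["neighborhood_id"].map(mapping)
        cfg = MCMCConfig(n_chains=1, n_iter=400, n_burnin=100, seed=8)
        r1 = BYMLogistic.from_cohort(cohort, "walk_any", ["sex_male"], graph=graph).fit(cfg)
        r2 = BYMLogistic.from_cohort(cohort2, "walk_any", ["sex_male"], graph=graph2).fit(cfg)
        assert np.array_equal(r1.samples.draws["beta"], r2.samples.draws["beta"])
        assert np.array_equal(r1.samples.draws["v"], r2.samples.draws["v"])


class TestAgainstIndependentImplementations:
    def test_exchangeable_special_case_matches_statsmodels(self):
        """With the CAR term disabled, the multilevel logistic posterior
        means agree with statsmodels' variational BinomialBayesMixedGLM."""
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        cfg = GeneratorConfig(
            lattice_rows=8, lattice_cols=8, n_per_neighborhood=25, vary_n=False,
            true_betas={"sex_male[1]": np.log(1.5)}, true_betas_ordinal={},
            sigma_u=0.4, tau_v=0.0, missing_rate=0.0, seed=8,
        )
        cohort, graph = generate_cohort(cfg)
        res = BYMLogistic.from_cohort(
            cohort, "walk_any", ["sex_male"], graph=graph, include_car=False
        ).fit(MCMCConfig(n_iter=2500, n_burnin=1000, seed=4))
        assert (res.samples.flat("tau_v") == 0).all()
        med = res.coef_medians()

        vc = {"nb": "0 + C(neighborhood_id)"}
        vb = BinomialBayesMixedGLM.from_formula(
            "walk_any ~ sex_male", vc, cohort, vcp_p=2
        ).fit_vb()
        assert abs(med["intercept"] - vb.fe_mean[0]) < 0.08
        assert abs(med["sex_male[1]"] - vb.fe_mean[1]) < 0.08

    def test_proportional_odds_consistency_across_thresholds(self):
        """Under a proportional-odds truth, per-threshold binary logistic
        fits of the same data give nearly identical slopes."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 20000
        x = (rng.uniform(size=n) < 0.5).astype(float)
        lat = 0.5 * x + rng.logistic(size=n)
        kap = np.array([-0.5, 0.3, 1.0, 1.8])
        y = 1 + (lat[:, None] > kap[None, :]).sum(axis=1)
        slopes = []
        for k in range(1, 5):
            yk = (y > k).astype(float)
            fit = sm.GLM(yk, sm.add_constant(x), family=sm.families.Binomial()).fit()
            slopes.append(fit.params[1])
        assert max(slopes) - min(slopes) < 0.1


class TestDiagnosticsAndPersistence:
    def _fake_samples(self, chain_a, chain_b):
        draws = {
            "beta": np.stack([chain_a[:, None], chain_b[:, None]]),
            "sigma_u": np.zeros((2, chain_a.size)),
            "tau_v": np.zeros((2, chain_a.size)),
            "u": np.zeros((2, chain_a.size, 0)),
            "v": np.zeros((2, chain_a.size, 0)),
        }
        from neighwalk.model import ModelSpec

        spec = ModelSpec(outcome="y", family="logistic", terms=(), beta_names=("x",))
        return PosteriorSamples(draws=draws, spec=spec)

    def test_identical_chains_rhat_one(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal(1000)
        rep = check_convergence(self._fake_samples(c, c.copy()), min_ess=10)
        assert abs(rep.table.loc["beta[x]", "rhat"] - 1.0) <= 0.01

    def test_disagreeing_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(1000)
        rep = check_convergence(self._fake_samples(a, a + 5.0))
        assert rep.table.loc["beta[x]", "rhat"] > 1.1
        assert not rep.passed

    def test_white_noise_ess_near_nominal(self):
        rng = np.random.default_rng(2)
        rep = check_convergence(
            self._fake_samples(rng.standard_normal(1000), rng.standard_normal(1000))
        )
        assert abs(rep.table.loc["beta[x]", "ess"] - 2000) < 0.2 * 2000

    def test_single_chain_rejected(self, small_cohort):
        cohort, graph = small_cohort
        res = BYMLogistic.from_cohort(cohort, "walk_any", ["sex_male"], graph=graph).fit(
            MCMCConfig(n_chains=1, n_iter=200, n_burnin=100, seed=1)
        )
        with pytest.raises(InsufficientChainsError):
            check_convergence(res.samples)

    def test_posterior_bundle_roundtrip(self, tmp_path, logistic_fit):
        outdir = tmp_path / "posterior"
        logistic_fit.save(outdir)
        loaded = PosteriorSamples.load(outdir)
        for k, arr in logistic_fit.samples.draws.items():
            assert np.allclose(loaded.draws[k], arr)
        assert loaded.spec.beta_names == logistic_fit.samples.spec.beta_names

    def test_decompose_requires_spatial_model(self):
        rng = np.random.default_rng(0)
        samples = self._fake_samples(rng.standard_normal(100), rng.standard_normal(100))
        samples.draws.pop("v")
        with pytest.raises(ContractError):
            from neighwalk.decompose import decompose

            decompose(samples)


class TestMCMCConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            MCMCConfig(n_iter=100, n_burnin=100)
        with pytest.raises(InvalidArgumentError):
            MCMCConfig(thin=0)
        with pytest.raises(InvalidArgumentError):
            MCMCConfig(n_chains=0)
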