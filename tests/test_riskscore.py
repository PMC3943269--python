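"""Environmental risk score, quartiling, refits and bootstrap."""

import numpy as np
import pandas as pd
import pytest

from neighwalk.exceptions import ContractError, DegenerateScoreError, InvalidArgumentError
from neighwalk.model import MCMCConfig
from neighwalk.riskscore import (
    bootstrap_ors,
    compute_scores,
    refit_with_score,
    score_categories,
)
from neighwalk.simulate import GeneratorConfig, generate_cohort

_ENV_BETAS = {
    "nbhd_education[2]": np.log(1.3),
    "nbhd_education[3]": np.log(1.8),
    "nbhd_education[4]": np.log(2.2),
    "air_traffic[1]": np.log(0.6),
    "no2[2]": np.log(0.95),
    "no2[3]": np.log(0.85),
    "no2[4]": np.log(0.8),
    "green_space_quality[2]": np.log(1.05),
    "green_space_quality[3]": np.log(1.15),
    "green_space_quality[4]": np.log(1.4),
}


@pytest.fixture(scope="module")
def env_cohort():
    cfg = GeneratorConfig(
        lattice_rows=8, lattice_cols=8, n_per_neighborhood=30, vary_n=False,
        true_betas=dict(_ENV_BETAS), true_betas_ordinal={}, sigma_u=0.15, tau_v=0.2,
        missing_rate=0.0, seed=77,
    )
    return generate_cohort(cfg)


class TestComputeScores:
    def test_zero_coefficients_zero_scores(self, env_cohort):
        cohort, _ = env_cohort
        s = compute_scores(cohort, {"air_traffic[1]": 0.0})
        assert np.all(s == 0)

    def test_single_binary_exposure_published_coefficient(self, env_cohort):
        """Air traffic at the published OR 0.75: exposed individuals
        score ln(0.75) = -0.2877, unexposed 0."""
        cohort, _ = env_cohort
        s = compute_scores(cohort, {"air_traffic[1]": np.log(0.75)})
        exposed = cohort["air_traffic"].to_numpy() == 1
        assert np.allclose(s[exposed], -0.2877, atol=5e-4)
        assert np.all(s[~exposed] == 0)

    def test_linear_term_affine_equivariance(self, env_cohort):
        cohort, _ = env_cohort
        work = cohort.copy()
        work["expo"] = np.asarray(work["temp_mean_8d"], dtype=float)
        b = 0.37
        s1 = compute_scores(work, {"expo": b})
        work["expo"] = work["expo"] + 5.0
        s2 = compute_scores(work, {"expo": b})
        assert np.allclose(s2 - s1, b * 5.0)

    def test_unknown_coefficient_contract_error(self, env_cohort):
        cohort, _ = env_cohort
        with pytest.raises(ContractError):
            compute_scores(cohort, {"nope[1]": 0.1})


class TestScoreCategories:
    def test_multi_exposure_score_gives_near_equal_quartiles(self, env_cohort):
        cohort, _ = env_cohort
        cats = score_categories(compute_scores(cohort, _ENV_BETAS))
        sizes = np.bincount(cats)[1:]
        assert sizes.min() > 0.8 * len(cohort) / 4

    def test_two_valued_score_degenerate(self, env_cohort):
        cohort, _ = env_cohort
        s = compute_scores(cohort, {"air_traffic[1]": np.log(0.75)})
        with pytest.raises(DegenerateScoreError):
            score_categories(s)

    def test_monotone_transform_leaves_categories_unchanged(self, env_cohort):
        cohort, _ = env_cohort
        s = compute_scores(cohort, _ENV_BETAS)
        assert np.array_equal(score_categories(s), score_categories(2 * s))


class TestRefitWithScore:
    def test_positive_gradient_gives_nondecreasing_ors(self, env_cohort):
        cohort, graph = env_cohort
        cats = score_categories(compute_scores(cohort, _ENV_BETAS))
        _, ors = refit_with_score(
            cohort, "walk_any", ["age_class", "sex_male"], graph, cats,
            MCMCConfig(n_iter=1500, n_burnin=600, seed=3),
        )
        vals = ors["OR"].to_numpy()
        assert vals[0] > 1.0 and vals[2] > vals[0]

    def test_null_truth_intervals_cover_one(self):
        cfg = GeneratorConfig(
            lattice_rows=6, lattice_cols=6, n_per_neighborhood=30, vary_n=False,
            true_betas={}, true_betas_ordinal={}, sigma_u=0.1, tau_v=0.1,
            missing_rate=0.0, seed=55,
        )
        cohort, graph = generate_cohort(cfg)
        # a score built from irrelevant exposures
        cats = score_categories(
            compute_scores(cohort, {"no2[2]": 0.2, "no2[3]": 0.4, "no2[4]": 0.6,
                                    "highway[1]": -0.3})
        )
        _, ors = refit_with_score(
            cohort, "walk_any", ["sex_male"], graph, cats,
            MCMCConfig(n_iter=1500, n_burnin=600, seed=4),
        )
        assert ((ors["OR_2.5%"] <= 1.0) & (ors["OR_97.5%"] >= 1.0)).all()


class TestBootstrap:
    def test_two_replicates_median_is_midpoint(self, env_cohort):
        cohort, _ = env_cohort
        rs = bootstrap_ors(
            cohort, "walk_any", ["sex_male"], _ENV_BETAS, n_boot=2, seed=9
        )
        t = rs.or_table
        assert rs.n_boot == 2
        # with two replicates the percentile median is their midpoint,
        # so it sits strictly inside the percentile interval
        assert ((t["or_2.5%"] <= t["or_median"]) & (t["or_median"] <= t["or_97.5%"])).all()

    def test_deterministic_given_seed(self, env_cohort):
        cohort, _ = env_cohort
        r1 = bootstrap_ors(cohort, "walk_any", ["sex_male"], _ENV_BETAS, n_boot=20, seed=5)
        r2 = bootstrap_ors(cohort, "walk_any", ["sex_male"], _ENV_BETAS, n_boot=20, seed=5)
        pd.testing.assert_frame_equal(r1.or_table, r2.or_table)

    def test_nboot_below_two_rejected(self, env_cohort):
        cohort, _ = env_cohort
        with pytest.raises(InvalidArgumentError):
            bootstrap_ors(cohort, "walk_any", ["sex_male"], _ENV_BETAS, n_boot=1, seed=0)

    def test_interval_shrinks_with_cohort_size(self):
        widths = []
        for rows, cols, npn in [(6, 6, 15), (12, 12, 30)]:  # ~4x individuals
            cfg = GeneratorConfig(
                lattice_rows=rows, lattice_cols=cols, n_per_neighborhood=npn, vary_n=False,
                true_betas=dict(_ENV_BETAS), true_betas_ordinal={}, sigma_u=0.15,
                tau_v=0.2, missing_rate=0.0, seed=66,
            )
            cohort, _ = generate_cohort(cfg)
            rs = bootstrap_ors(
                cohort, "walk_any", ["sex_male"], _ENV_BETAS, n_boot=60, seed=8
            )
            t = rs.or_table
            widths.append(float((t["or_97.5%"] - t["or_2.5%"]).mean()))
        assert widths[1] < widths[0]

    def test_block_bootstrap_runs(self, env_cohort):
        cohort, _ = env_cohort
        rs = bootstrap_ors(
            cohort, "walk_any", ["sex_male"], _ENV_BETAS, n_boot=10, seed=2,
            block_by_neighborhood=True,
        )
        assert rs.or_table.shape == (3, 3)

    def test_ordinal_outcome_supported(self, env_cohort):
        cohort, _ = env_cohort
        rs = bootstrap_ors(
            cohort, "walk_time_nbhd_cat", ["sex_male"], _ENV_BETAS, n_boot=8, seed=3
        )
        assert rs.or_table.notna().all().all()

    def test_effect_magnitude_monotone_response(self):
        """Top-vs-bottom category OR grows with the injected
        environmental effect size (3-point grid)."""
        tops = []
        for mult in (0.0, 0.7, 1.4):
            betas = {k: mult * v for k, v in _ENV_BETAS.items()}
            cfg = GeneratorConfig(
                lattice_rows=7, lattice_cols=7, n_per_neighborhood=30, vary_n=False,
                true_betas=betas, true_betas_ordinal={}, sigma_u=0.1, tau_v=0.15,
                missing_rate=0.0, seed=88,
            )
            cohort, _ = generate_cohort(cfg)
            score_coefs = {k: v if mult else _ENV_BETAS[k] for k, v in betas.items()}
            rs = bootstrap_ors(
                cohort, "walk_any", ["sex_male"], score_coefs or _ENV_BETAS,
                n_boot=30, seed=12,
            )
            tops.append(float(rs.or_table.loc[4, "or_median"]))
        assert tops[0] < tops[1] < tops[2]
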