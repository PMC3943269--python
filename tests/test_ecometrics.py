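"""Ecometric measurement models and leave-one-out scoring."""

import numpy as np
import pandas as pd
import pytest

from neighwalk.ecometrics import (
    fit_ecometric_2level,
    fit_ecometric_3level,
    loo_scores,
)
from neighwalk.exceptions import IdentifiabilityError, InvalidArgumentError
from neighwalk.sampler import MCMCConfig
from neighwalk.simulate import GeneratorConfig, ItemModel, generate_cohort, generate_item_responses

_FAST = MCMCConfig(n_iter=1200, n_burnin=500, thin=2, seed=7)


def _cohort_and_items(truth_sd=0.5, rows=5, cols=8, npn=15, n_items=3, seed=0):
    cfg = GeneratorConfig(
        lattice_rows=rows, lattice_cols=cols, n_per_neighborhood=npn, vary_n=False,
        true_betas={}, true_betas_ordinal={}, missing_rate=0.0, seed=seed,
    )
    cohort, graph = generate_cohort(cfg)
    rng = np.random.default_rng(seed + 1)
    truth = truth_sd * rng.standard_normal(graph.n_nodes)
    intercepts = (0.0, 0.35, -0.35, 0.2)[:n_items]
    items = generate_item_responses(
        cohort,
        dict(zip(graph.node_ids, truth)),
        ItemModel(item_intercepts=intercepts, cutpoints=(-1.2, 0.0, 1.2)),
        seed=seed + 2,
    )
    return cohort, graph, truth, items


@pytest.fixture(scope="module")
def fitted_3level():
    cohort, graph, truth, items = _cohort_and_items(seed=10)
    return cohort, graph, truth, items, fit_ecometric_3level(items, _FAST)


class TestContracts:
    def test_single_neighborhood_unidentifiable(self):
        items = pd.DataFrame(
            {
                "neighborhood_id": [0] * 6,
                "individual_id": [0, 0, 1, 1, 2, 2],
                "item_id": [1, 2, 1, 2, 1, 2],
                "response": [1, 2, 2, 3, 1, 3],
            }
        )
        with pytest.raises(IdentifiabilityError):
            fit_ecometric_3level(items, _FAST)

    def test_3level_requires_multiple_items(self):
        items = pd.DataFrame(
            {
                "neighborhood_id": [0, 1],
                "individual_id": [0, 1],
                "item_id": [1, 1],
                "response": [1, 2],
            }
        )
        with pytest.raises(InvalidArgumentError):
            fit_ecometric_3level(items, _FAST)

    def test_2level_rejects_multiple_items(self, fitted_3level):
        _, _, _, items, _ = fitted_3level
        with pytest.raises(InvalidArgumentError):
            fit_ecometric_2level(items, _FAST)

    def test_empty_table_rejected(self):
        empty = pd.DataFrame(
            columns=["neighborhood_id", "individual_id", "item_id", "response"]
        )
        with pytest.raises(InvalidArgumentError):
            fit_ecometric_2level(empty, _FAST)

    def test_duplicate_individual_item_rejected(self):
        items = pd.DataFrame(
            {
                "neighborhood_id": [0, 0],
                "individual_id": [1, 1],
                "item_id": [1, 1],
                "response": [2, 3],
            }
        )
        with pytest.raises(InvalidArgumentError):
            fit_ecometric_3level(items, _FAST)


class TestScores:
    def test_null_neighborhood_variance_shrinks_scores(self):
        cohort, graph, truth, items = _cohort_and_items(truth_sd=0.0, seed=20)
        sc = fit_ecometric_3level(items, _FAST)
        assert sc.var_neighborhood < sc.var_individual
        assert np.abs(sc.scores["score"]).mean() < 0.15

    def test_scores_track_truth(self, fitted_3level):
        _, graph, truth, _, sc = fitted_3level
        est = sc.as_series().loc[list(graph.node_ids)].to_numpy()
        assert np.corrcoef(est, truth)[0, 1] > 0.7

    def test_two_level_orders_low_vs_high(self):
        rng = np.random.default_rng(5)
        rows = []
        for j, shift in [(0, -1.5), (1, 1.5)]:
            for i in range(40):
                lat = shift + rng.logistic()
                resp = 1 + int(lat > -1) + int(lat > 0) + int(lat > 1)
                rows.append((j, j * 100 + i, 1, resp))
        items = pd.DataFrame(
            rows, columns=["neighborhood_id", "individual_id", "item_id", "response"]
        )
        sc = fit_ecometric_2level(items, _FAST)
        s = sc.as_series()
        assert s[1] > s[0]

    def test_item_relabeling_invariance(self, fitted_3level):
        """Relabeling item ids (order-preserving) leaves scores identical."""
        _, _, _, items, sc = fitted_3level
        relabeled = items.assign(item_id=items["item_id"] * 7)
        sc2 = fit_ecometric_3level(relabeled, _FAST)
        pd.testing.assert_frame_equal(sc.scores, sc2.scores)

    def test_individual_relabeling_invariance(self, fitted_3level):
        _, _, _, items, sc = fitted_3level
        relabeled = items.assign(individual_id=items["individual_id"] * 3 + 1)
        sc2 = fit_ecometric_3level(relabeled, _FAST)
        pd.testing.assert_frame_equal(sc.scores, sc2.scores)


class TestVarianceComponentRecovery:
    def test_components_unbiased_over_replicates(self):
        """Posterior-mean neighborhood and individual variances recover
        the generating values within 2 Monte-Carlo SEs over 20
        replicates."""
        est_b, est_e = [], []
        for r in range(20):
            cohort, graph, truth, items = _cohort_and_items(
                truth_sd=0.5, rows=6, cols=10, npn=20, n_items=4, seed=300 + r
            )
            sc = fit_ecometric_3level(
                items, MCMCConfig(n_iter=1500, n_burnin=600, thin=2, seed=600 + r)
            )
            est_b.append(sc.var_neighborhood)
            est_e.append(sc.var_individual)
        est_b, est_e = np.asarray(est_b), np.asarray(est_e)
        se_b = est_b.std(ddof=1) / np.sqrt(len(est_b))
        se_e = est_e.std(ddof=1) / np.sqrt(len(est_e))
        assert abs(est_b.mean() - 0.25) < 2 * se_b + 0.02
        assert abs(est_e.mean() - 1.0) < 2 * se_e + 0.02


class TestLooScores:
    def test_individual_without_responses_gets_full_score(self, fitted_3level):
        cohort, _, _, items, sc = fitted_3level
        items_missing_one = items.loc[items["individual_id"] != 0]
        loo = loo_scores(items_missing_one, cohort, sc)
        row = loo.loc[loo["individual_id"] == 0].iloc[0]
        assert row["loo_score"] == pytest.approx(
            sc.as_series()[row["neighborhood_id"]]
        )
        assert row["loo_missing"] == 0

    def test_single_respondent_neighborhood_flagged_missing(self, fitted_3level):
        cohort, _, _, items, sc = fitted_3level
        nid = items["neighborhood_id"].iloc[0]
        keep_ind = items.loc[items["neighborhood_id"] == nid, "individual_id"].iloc[0]
        pruned = items.loc[
            (items["neighborhood_id"] != nid) | (items["individual_id"] == keep_ind)
        ]
        loo = loo_scores(pruned, cohort, sc)
        row = loo.loc[loo["individual_id"] == keep_ind].iloc[0]
        assert row["loo_missing"] == 1 and np.isnan(row["loo_score"])

    def test_loo_deviation_shrinks_with_respondent_count(self):
        """|loo - full| is larger in sparsely answered neighborhoods."""
        cohort, graph, truth, items = _cohort_and_items(rows=4, cols=6, npn=30, seed=33)
        # thin half the neighborhoods down to 3 respondents
        sparse_nbhds = list(graph.node_ids)[::2]
        keep = []
        for nid, grp in items.groupby("neighborhood_id"):
            inds = grp["individual_id"].unique()
            if nid in sparse_nbhds:
                inds = inds[:3]
            keep.append(grp.loc[grp["individual_id"].isin(inds)])
        items2 = pd.concat(keep)
        sc = fit_ecometric_3level(items2, _FAST)
        loo = loo_scores(items2, cohort, sc)
        answered = loo.loc[loo["individual_id"].isin(items2["individual_id"])]
        full = sc.as_series()
        dev = (answered["loo_score"] - full.loc[answered["neighborhood_id"]].to_numpy()).abs()
        is_sparse = answered["neighborhood_id"].isin(sparse_nbhds).to_numpy()
        assert dev[is_sparse].mean() > dev[~is_sparse].mean()

    def test_same_source_artifact_attenuated_by_loo(self):
        """When individuals' own responses leak their outcome, the
        association outcome ~ score weakens under leave-one-out scoring."""
        cohort, graph, truth, items = _cohort_and_items(rows=4, cols=6, npn=12, seed=44)
        rng = np.random.default_rng(45)
        # inject a same-source artifact: respondents with walk_any=1 answer higher
        leak = cohort.set_index("individual_id")["walk_any"].to_dict()
        bump = items["individual_id"].map(leak).to_numpy() * 2.0
        noisy = items.copy()
        noisy["response"] = np.minimum(
            4, noisy["response"] + (rng.uniform(size=len(noisy)) < bump / 3).astype(int)
        )
        sc = fit_ecometric_3level(noisy, _FAST)
        loo = loo_scores(noisy, cohort, sc)
        full_per_ind = sc.as_series().loc[cohort["neighborhood_id"]].to_numpy()
        y = cohort["walk_any"].to_numpy()
        r_full = np.corrcoef(full_per_ind, y)[0, 1]
        r_loo = np.corrcoef(loo["loo_score"].to_numpy(), y)[0, 1]
        assert r_loo < r_full
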