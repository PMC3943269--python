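"""Ecometric neighborhood scoring from survey item responses.

Residents' graded answers about their neighborhood (items within
individuals within neighborhoods) are aggregated into latent
neighborhood scores by multilevel cumulative-logit measurement models:
a 3-level model (item fixed effects + individual and neighborhood
random intercepts) for multi-item constructs, and a 2-level model
(neighborhood intercepts only) for single-item constructs. Scores are
posterior means of the neighborhood intercepts on the logit scale —
shrunken toward zero where a neighborhood carries little information —
and are subsequently quartile-categorized like any other exposure
before entering the outcome models.

A leave-one-out variant recomputes each individual's neighborhood score
from the other residents' responses only, to check that an
exposure-outcome association is not driven by same-source bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import IdentifiabilityError, InvalidArgumentError
from .sampler import HierOrdinalSampler, MCMCConfig

__all__ = ["EcometricScores", "fit_ecometric_3level", "fit_ecometric_2level", "loo_scores"]

_REQUIRED = ["neighborhood_id", "individual_id", "item_id", "response"]


@dataclass
class EcometricScores:
    """Neighborhood scores and variance components of one ecometric fit.

    ``scores`` has one row per neighborhood with a response: the
    posterior mean neighborhood intercept (logit scale) and its
    posterior SD. ``var_neighborhood`` / ``var_individual`` are
    posterior means of the corresponding variance components (the
    2-level model has no individual component).
    """

    scores: pd.DataFrame  # columns: neighborhood_id, score, se
    var_neighborhood: float
    var_individual: float | None
    n_levels: int
    draws: dict
    item_ids: list
    indiv_ids: list

    def as_series(self) -> pd.Series:
        return self.scores.set_index("neighborhood_id")["score"]

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)


def _validate_items(items: pd.DataFrame) -> pd.DataFrame:
    for c in _REQUIRED:
        if c not in items.columns:
            raise InvalidArgumentError(f"item table lacks column {c!r}")
    if len(items) == 0:
        raise InvalidArgumentError("empty item-response table")
    dup = items.duplicated(subset=["individual_id", "item_id"])
    if dup.any():
        raise InvalidArgumentError("each (individual, item) pair may appear at most once")
    resp = items["response"].to_numpy()
    if (resp < 1).any():
        raise InvalidArgumentError("responses must be ordered categories coded from 1")
    return items


def _fit(items: pd.DataFrame, three_level: bool, mcmc: MCMCConfig | None) -> EcometricScores:
    items = _validate_items(items)
    mcmc = mcmc or MCMCConfig(n_iter=3000, n_burnin=1000, thin=2)

    nb_ids = sorted(pd.unique(items["neighborhood_id"]))
    if len(nb_ids) < 2:
        raise IdentifiabilityError(
            "a neighborhood-level variance needs >= 2 neighborhoods"
        )
    item_ids = sorted(pd.unique(items["item_id"]))
    indiv_ids = sorted(pd.unique(items["individual_id"]))
    nb_ix = {k: i for i, k in enumerate(nb_ids)}
    it_ix = {k: i for i, k in enumerate(item_ids)}
    in_ix = {k: i for i, k in enumerate(indiv_ids)}

    # responses may skip categories; recode to consecutive 1..K
    levels = np.sort(pd.unique(items["response"]))
    recode = {lv: i + 1 for i, lv in enumerate(levels)}
    y = items["response"].map(recode).to_numpy(dtype=int)
    if len(levels) < 2:
        raise InvalidArgumentError("responses take a single value; nothing to fit")

    sampler = HierOrdinalSampler(
        resp=y,
        item_idx=items["item_id"].map(it_ix).to_numpy(),
        indiv_idx=items["individual_id"].map(in_ix).to_numpy(),
        nbhd_idx=items["neighborhood_id"].map(nb_ix).to_numpy(),
        n_items=len(item_ids),
        n_indiv=len(indiv_ids),
        n_nbhd=len(nb_ids),
        three_level=three_level,
    )
    draws = sampler.run(mcmc)
    b = draws["b"].reshape(-1, len(nb_ids))
    scores = pd.DataFrame(
        {
            "neighborhood_id": nb_ids,
            "score": b.mean(axis=0),
            "se": b.std(axis=0, ddof=1),
        }
    )
    var_b = float(np.mean(draws["sigma_b"] ** 2))
    var_e = float(np.mean(draws["sigma_e"] ** 2)) if three_level else None
    return EcometricScores(
        scores=scores,
        var_neighborhood=var_b,
        var_individual=var_e,
        n_levels=3 if three_level else 2,
        draws=draws,
        item_ids=item_ids,
        indiv_ids=indiv_ids,
    )


def fit_ecometric_3level(items: pd.DataFrame, mcmc: MCMCConfig | None = None) -> EcometricScores:
    """3-level measurement model: items within individuals within
    neighborhoods. Requires >= 2 items and >= 2 neighborhoods."""
    _validate_items(items)
    if pd.unique(items["item_id"]).size < 2:
        raise InvalidArgumentError("3-level model needs >= 2 items; use fit_ecometric_2level")
    return _fit(items, three_level=True, mcmc=mcmc)


def fit_ecometric_2level(items: pd.DataFrame, mcmc: MCMCConfig | None = None) -> EcometricScores:
    """2-level measurement model for a single-item construct."""
    _validate_items(items)
    if pd.unique(items["item_id"]).size != 1:
        raise InvalidArgumentError("2-level model requires exactly 1 item; use the 3-level model")
    return _fit(items, three_level=False, mcmc=mcmc)


def _logistic_trunc_mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """E[L | a < L < b] for standard logistic L.

    Uses the closed form of the integral of x f(x): the antiderivative
    of F is log(1 + e^x), so int_a^b x f = [x F(x) - log(1+e^x)]_a^b.
    """
    def part(x):
        xf = np.where(np.isfinite(x), x, 0.0)
        val = xf * expit(xf) - np.logaddexp(0.0, xf)
        return np.where(np.isfinite(x), val, 0.0)  # both limits vanish

    p = expit(b) - expit(a)
    num = part(b) - part(a)
    return num / np.maximum(p, 1e-12)


def loo_scores(
    items: pd.DataFrame, cohort: pd.DataFrame, fitted: EcometricScores
) -> pd.DataFrame:
    """Per-individual neighborhood scores excluding own responses.

    An empirical-Bayes approximation at the posterior means of the
    fitted model: each individual's responses are condensed into a
    working latent value (truncated-logistic conditional mean given the
    observed categories, item effects removed) with an information
    weight, and the neighborhood score is the precision-weighted
    shrinkage estimate over the remaining residents. Individuals with no
    responses inherit the all-residents score; a neighborhood whose only
    respondent is the focal individual gets a missing flag.

    Returns a frame with ``individual_id``, ``neighborhood_id``,
    ``loo_score`` (NaN where flagged) and ``loo_missing``.
    """
    items = _validate_items(items)
    if fitted.n_levels != 3:
        raise InvalidArgumentError("loo scoring expects a fitted 3-level model")
    draws = fitted.draws
    kappa = draws["kappa"].reshape(-1, draws["kappa"].shape[-1]).mean(axis=0)
    delta = draws["delta_item"].reshape(-1, draws["delta_item"].shape[-1]).mean(axis=0)
    sigma_b = float(np.mean(draws["sigma_b"]))
    sigma_e = float(np.mean(draws["sigma_e"]))

    it_ix = {k: i for i, k in enumerate(fitted.item_ids)}
    kk = np.concatenate(([-np.inf], kappa, [np.inf]))

    # working latent value per response: E[latent | category], item effect removed
    levels = np.sort(pd.unique(items["response"]))
    recode = {lv: i + 1 for i, lv in enumerate(levels)}
    resp = items["response"].map(recode).to_numpy(dtype=int)
    del_obs = delta[items["item_id"].map(it_ix).to_numpy()]
    z = _logistic_trunc_mean(kk[resp - 1] - del_obs, kk[resp] - del_obs)

    per_ind = pd.DataFrame(
        {
            "individual_id": items["individual_id"].to_numpy(),
            "neighborhood_id": items["neighborhood_id"].to_numpy(),
            "z": z,
        }
    ).groupby(["individual_id", "neighborhood_id"], as_index=False).agg(
        zbar=("z", "mean"), m=("z", "size")
    )
    # individual-level information: latent residual var pi^2/3 per item
    per_ind["w"] = 1.0 / (sigma_e**2 + (np.pi**2 / 3) / per_ind["m"])

    per_ind["wz"] = per_ind["w"] * per_ind["zbar"]
    agg = per_ind.groupby("neighborhood_id")[["w", "wz"]].sum().rename(
        columns={"w": "sw", "wz": "swz"}
    )
    n_resp = per_ind.groupby("neighborhood_id")["individual_id"].size()

    prior_prec = 1.0 / sigma_b**2

    out_rows = []
    agg_w = agg["sw"].to_dict()
    agg_wz = agg["swz"].to_dict()
    nresp = n_resp.to_dict()
    own = per_ind.set_index("individual_id")[["neighborhood_id", "w", "wz"]]
    full_scores = fitted.as_series()

    for iid, nid in zip(cohort["individual_id"], cohort["neighborhood_id"]):
        if iid not in own.index:
            # no own responses: nothing to leave out, keep the full score
            out_rows.append((iid, nid, float(full_scores.get(nid, np.nan)), 0))
            continue
        sw, swz, nr = agg_w[nid], agg_wz[nid], nresp[nid]
        sw_m = sw - float(own.at[iid, "w"])
        swz_m = swz - float(own.at[iid, "wz"])
        if nr - 1 <= 0:
            out_rows.append((iid, nid, np.nan, 1))
            continue
        out_rows.append((iid, nid, float(swz_m / (prior_prec + sw_m)), 0))
    return pd.DataFrame(
        out_rows, columns=["individual_id", "neighborhood_id", "loo_score", "loo_missing"]
    )
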