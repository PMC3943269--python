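"""Environmental risk score and bootstrapped disparity odds ratios.

The overall walking disparity predicted by the environment is
summarized by a per-individual linear risk score — the sum of the final
model's environmental coefficients times each individual's exposure
values — split into quartile categories and re-entered into the outcome
model in place of all environmental variables. Uncertainty in the
category odds ratios comes from a nonparametric bootstrap over
individuals (2000 replicates by default), reporting the replicate
median and the 2.5th/97.5th percentiles.

Per-replicate refits use the fast penalized-MAP multilevel fit (no CAR
term) for tractability; the headline, non-bootstrap category ORs should
come from the full MCMC refit (:func:`refit_with_score`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .approx import fit_penalized
from .exceptions import (
    ContractError,
    DegenerateScoreError,
    DegenerateVariableError,
    InvalidArgumentError,
)
from .model import BYMLogistic, BYMOrdinal, MCMCConfig, design_from_cohort
from .preprocess import quartile_categorize

__all__ = ["RiskScoreResult", "compute_scores", "score_categories", "refit_with_score", "bootstrap_ors"]

_COEF_RE = re.compile(r"^(?P<col>\w+)(\[(?P<lev>-?\d+)\])?$")


def compute_scores(cohort: pd.DataFrame, env_coefs: dict) -> np.ndarray:
    """Per-individual risk score: sum of coefficients times exposure values.

    ``env_coefs`` maps coefficient names — ``col`` for a linear term or
    ``col[level]`` for a category indicator — to log odds ratios
    (posterior medians of the final model's environmental terms).
    """
    s = np.zeros(len(cohort))
    for key, b in env_coefs.items():
        m = _COEF_RE.match(key)
        if m is None or m.group("col") not in cohort.columns:
            raise ContractError(f"coefficient {key!r} matches no cohort covariate")
        col = cohort[m.group("col")]
        if m.group("lev") is None:
            s += b * col.to_numpy(dtype=float)
        else:
            s += b * (col == int(m.group("lev"))).to_numpy(dtype=float)
    return s


def score_categories(scores) -> np.ndarray:
    """Quartile categories 1-4 of the risk score."""
    try:
        cats, _ = quartile_categorize(np.asarray(scores, dtype=float))
    except DegenerateVariableError as err:
        raise DegenerateScoreError(
            "risk score takes fewer than 4 distinct values (e.g. a single "
            "binary exposure); quartile categories are undefined"
        ) from err
    return cats


@dataclass
class RiskScoreResult:
    """Bootstrapped odds ratios for risk-score quartiles 2-4 vs 1."""

    scores: np.ndarray
    categories: np.ndarray
    or_table: pd.DataFrame  # index cat 2..4; columns or_median, or_2.5%, or_97.5%
    n_boot: int
    outcome: str

    def paragraph(self) -> str:
        t = self.or_table
        ors = [
            f"{t.loc[c, 'or_median']:.2f} (95% CI: {t.loc[c, 'or_2.5%']:.2f}, "
            f"{t.loc[c, 'or_97.5%']:.2f}) times"
            for c in (2, 3, 4)
        ]
        return (
            f"Compared to the least supportive environments, the odds of "
            f"{self.outcome} were {ors[0]}, {ors[1]}, and {ors[2]} higher in "
            f"the three categories of increasing environmental supportiveness "
            f"(bootstrap medians and percentile intervals, "
            f"{self.n_boot} replicates)."
        )


def _family_for(outcome_values: np.ndarray) -> str:
    vals = np.unique(outcome_values[~pd.isna(outcome_values)])
    return "logistic" if np.isin(vals, [0, 1]).all() else "ordinal"


def refit_with_score(
    cohort: pd.DataFrame,
    outcome: str,
    base_terms: list[str],
    graph,
    categories: np.ndarray,
    mcmc: MCMCConfig | None = None,
):
    """Full MCMC refit with risk-score categories replacing all
    environmental variables; returns ``(results, or_frame)`` with ORs
    for categories 2-4 versus 1."""
    work = cohort.copy()
    work["risk_score_cat"] = np.asarray(categories, dtype=int)
    family = _family_for(work[outcome].to_numpy())
    cls = BYMLogistic if family == "logistic" else BYMOrdinal
    model = cls.from_cohort(work, outcome, list(base_terms) + ["risk_score_cat"], graph=graph)
    res = model.fit(mcmc)
    ors = res.odds_ratios()
    sel = ors.loc[ors.index.str.startswith("risk_score_cat[")]
    sel.index = [int(ix.split("[")[1][:-1]) for ix in sel.index]
    return res, sel


def bootstrap_ors(
    cohort: pd.DataFrame,
    outcome: str,
    base_terms: list[str],
    env_coefs: dict,
    n_boot: int = 2000,
    seed: int = 0,
    block_by_neighborhood: bool = False,
    sigma_u: float = 0.5,
) -> RiskScoreResult:
    """Bootstrap the risk-score category odds ratios.

    Each replicate resamples individuals with replacement (or whole
    neighborhoods when ``block_by_neighborhood``), recomputes the score
    quartiles on the resampled data, and refits the outcome model by
    penalized MAP with the score categories as the only environmental
    terms. Categories 2-4 are reported against category 1.
    """
    if n_boot < 2:
        raise InvalidArgumentError("n_boot must be >= 2")
    work = cohort.loc[cohort[outcome].notna()].reset_index(drop=True)
    y_all = work[outcome].to_numpy()
    family = _family_for(y_all)
    if family == "ordinal":
        y_all = y_all.astype(int)
    scores = compute_scores(work, env_coefs)
    categories = score_categories(scores)

    X_base, base_names = design_from_cohort(
        work, base_terms, intercept=(family == "logistic")
    )
    nb_codes = pd.Categorical(work["neighborhood_id"]).codes.astype(int)
    rng = np.random.default_rng(seed)
    n = len(work)

    def fit_once(idx, start=None):
        cats_r = score_categories(scores[idx])
        dummies = np.stack([(cats_r == c).astype(float) for c in (2, 3, 4)], axis=1)
        X = np.hstack([X_base[idx], dummies])
        g = pd.factorize(nb_codes[idx])[0]
        fit = fit_penalized(
            y_all[idx], X, groups=g, family=family, sigma_u=sigma_u,
            compute_se=False, start=None,
        )
        return fit.beta[-3:]

    reps = np.empty((n_boot, 3))
    for b in range(n_boot):
        idx = _resample(rng, n, nb_codes, block_by_neighborhood)
        reps[b] = fit_once(idx)
    ors = np.exp(reps)
    lo, med, hi = np.percentile(ors, [2.5, 50, 97.5], axis=0)
    table = pd.DataFrame(
        {"or_median": med, "or_2.5%": lo, "or_97.5%": hi}, index=[2, 3, 4]
    )
    table.index.name = "risk_score_cat"
    return RiskScoreResult(
        scores=scores, categories=categories, or_table=table, n_boot=n_boot, outcome=outcome
    )


def _resample(rng, n, nb_codes, block: bool) -> np.ndarray:
    if not block:
        return rng.integers(0, n, size=n)
    nbs = np.unique(nb_codes)
    chosen = rng.choice(nbs, size=nbs.size, replace=True)
    parts = [np.flatnonzero(nb_codes == c) for c in chosen]
    return np.concatenate(parts)
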