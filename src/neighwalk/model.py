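"""Convolution (BYM) outcome models with a statsmodels-like interface.

The two between-neighborhood random effects of the convolution model —
an exchangeable intercept ``u_j`` and an intrinsic-CAR effect ``v_j`` —
enter the linear predictor together::

    logit P(walk_i = 1)   = x_i' beta + u_{j(i)} + v_{j(i)}          (binary)
    logit P(time_i <= k)  = kappa_k - (x_i' beta + u_{j(i)} + v_{j(i)})  (ordinal)

with u_j ~ N(0, sigma_u^2), v ~ ICAR(tau_v) under a sum-to-zero
constraint, N(0, 10^2) priors on regression coefficients and cutpoint
anchors, and half-N(0, 1) priors on both standard deviations (all
configurable). Estimation is by adaptive Metropolis-within-Gibbs
(:mod:`neighwalk.sampler`); results objects carry the posterior draws.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .approx import fit_penalized
from .exceptions import (
    CategorySupportError,
    ContractError,
    InsufficientChainsError,
    InvalidArgumentError,
)
from .graphs import AdjacencyGraph
from .sampler import BYMSampler, MCMCConfig

__all__ = [
    "ModelSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "BYMLogistic",
    "BYMOrdinal",
    "BYMResults",
    "check_convergence",
    "design_from_cohort",
]

_MAX_CAT_LEVELS = 8


def _is_categorical(col: pd.Series) -> bool:
    if isinstance(col.dtype, pd.CategoricalDtype):
        return True
    if pd.api.types.is_integer_dtype(col):
        return col.nunique() <= _MAX_CAT_LEVELS
    return False


def design_from_cohort(
    cohort: pd.DataFrame, terms: list[str], intercept: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Build a dummy-coded design matrix from cohort columns.

    Integer/categorical columns with few levels are expanded to
    indicator columns against their lowest level as reference (named
    ``col[level]``); float columns enter linearly. A 0/1 integer column
    therefore contributes the single indicator ``col[1]``.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        cols.append(np.ones(len(cohort)))
        names.append("intercept")
    for t in terms:
        if t not in cohort.columns:
            raise InvalidArgumentError(f"term {t!r} not found in cohort")
        col = cohort[t]
        if _is_categorical(col):
            levels = sorted(pd.unique(col.dropna()))
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{t}[{lev}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(t)
    if not cols:
        raise InvalidArgumentError("empty design")
    return np.column_stack(cols), names


@dataclass(frozen=True)
class ModelSpec:
    """What was fitted: outcome, terms, priors, graph summary."""

    outcome: str
    family: str
    terms: tuple
    beta_names: tuple
    beta_prior_sd: float = 10.0
    sd_prior_scale: float = 1.0
    n_neighborhoods: int = 0

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, default=str, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PosteriorSamples:
    """MCMC draws of all model parameters, indexed (chain, draw, ...).

    ``draws`` maps parameter names (``beta``, ``kappa``, ``sigma_u``,
    ``tau_v``, ``u``, ``v``) to arrays. The CAR effects satisfy
    sum_j v_j = 0 in every saved iteration.
    """

    draws: dict
    spec: ModelSpec
    node_ids: list = field(default_factory=list)
    seed: int | None = None

    @property
    def n_chains(self) -> int:
        return self.draws["beta"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["beta"].shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains stacked: (chain*draw, ...)."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def scalar_frame(self) -> pd.DataFrame:
        """All scalar parameters as columns of a (chain*draw) frame."""
        cols = {}
        beta = self.flat("beta")
        for i, nm in enumerate(self.spec.beta_names):
            cols[f"beta[{nm}]"] = beta[:, i]
        if "kappa" in self.draws:
            kap = self.flat("kappa")
            for k in range(kap.shape[1]):
                cols[f"kappa[{k + 1}]"] = kap[:, k]
        if self.draws.get("u") is not None and self.draws["u"].shape[-1] > 0:
            cols["sigma_u"] = self.flat("sigma_u")
            cols["tau_v"] = self.flat("tau_v")
        return pd.DataFrame(cols)

    def to_inference_data(self):
        import arviz as az

        data = {}
        beta = self.draws["beta"]
        for i, nm in enumerate(self.spec.beta_names):
            data[f"beta[{nm}]"] = beta[:, :, i]
        if "kappa" in self.draws:
            for k in range(self.draws["kappa"].shape[2]):
                data[f"kappa[{k + 1}]"] = self.draws["kappa"][:, :, k]
        if self.draws.get("u") is not None and self.draws["u"].shape[-1] > 0:
            data["sigma_u"] = self.draws["sigma_u"]
            data["tau_v"] = self.draws["tau_v"]
        return az.from_dict(posterior=data)

    # -- persistence: CSV bundle + JSON manifest -------------------------
    def save(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        manifest = {
            "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.spec.__dict__.items()},
            "spec_hash": self.spec.hash(),
            "seed": self.seed,
            "n_chains": self.n_chains,
            "n_draws": self.n_draws,
            "node_ids": [str(n) for n in self.node_ids],
            "parameters": {},
        }
        for name, arr in self.draws.items():
            if arr.size == 0:
                continue
            flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
            manifest["parameters"][name] = list(arr.shape)
            np.savetxt(os.path.join(outdir, f"{name}.csv"), flat, delimiter=",")
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, outdir) -> "PosteriorSamples":
        with open(os.path.join(outdir, "manifest.json")) as fh:
            manifest = json.load(fh)
        draws = {}
        for name, shape in manifest["parameters"].items():
            flat = np.loadtxt(os.path.join(outdir, f"{name}.csv"), delimiter=",", ndmin=2)
            draws[name] = flat.reshape(shape)
        spec_kwargs = manifest["spec"]
        spec_kwargs["terms"] = tuple(spec_kwargs["terms"])
        spec_kwargs["beta_names"] = tuple(spec_kwargs["beta_names"])
        spec = ModelSpec(**spec_kwargs)
        return cls(draws=draws, spec=spec, node_ids=manifest["node_ids"], seed=manifest["seed"])


class _BYMBase:
    """Shared machinery of the binary and ordinal convolution models."""

    family = ""

    def __init__(
        self,
        endog,
        exog,
        groups=None,
        graph: AdjacencyGraph | None = None,
        beta_names: list[str] | None = None,
        outcome_name: str = "y",
        terms: tuple = (),
        beta_prior_sd: float = 10.0,
        sd_prior_scale: float = 1.0,
        include_car: bool = True,
    ):
        self.include_car = include_car
        self.endog = np.asarray(endog)
        self.exog = np.asarray(exog, dtype=float)
        if self.endog.shape[0] != self.exog.shape[0]:
            raise InvalidArgumentError("endog and exog lengths differ")
        self.graph = graph
        if graph is not None:
            if groups is None:
                raise InvalidArgumentError("groups required when a graph is supplied")
            gidx = np.asarray([graph.index_of(g) for g in np.asarray(groups)])
            self.groups = gidx
        else:
            self.groups = None
        self.beta_names = list(beta_names) if beta_names else [
            f"x{i}" for i in range(self.exog.shape[1])
        ]
        self.spec = ModelSpec(
            outcome=outcome_name,
            family=self.family,
            terms=tuple(terms),
            beta_names=tuple(self.beta_names),
            beta_prior_sd=beta_prior_sd,
            sd_prior_scale=sd_prior_scale,
            n_neighborhoods=graph.n_nodes if graph is not None else 0,
        )
        self._validate()

    def _validate(self) -> None:
        raise NotImplementedError

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        outcome: str,
        terms: list[str],
        graph: AdjacencyGraph | None = None,
        group_col: str = "neighborhood_id",
        **kwargs,
    ):
        """Construct the model from a cohort table by dummy-coding ``terms``."""
        mask = cohort[outcome].notna()
        sub = cohort.loc[mask]
        X, names = design_from_cohort(sub, terms, intercept=(cls.family == "logistic"))
        groups = sub[group_col].to_numpy() if graph is not None else None
        return cls(
            endog=sub[outcome].to_numpy(),
            exog=X,
            groups=groups,
            graph=graph,
            beta_names=names,
            outcome_name=outcome,
            terms=tuple(terms),
            **kwargs,
        )

    def fit(self, mcmc: MCMCConfig | None = None, start: dict | None = None) -> "BYMResults":
        """Run the MCMC and return a results object with the draws."""
        mcmc = mcmc or MCMCConfig()
        if start is None:
            approx = fit_penalized(
                self.endog,
                self.exog,
                groups=self.groups,
                family=self.family,
                beta_prior_sd=self.spec.beta_prior_sd,
                compute_se=False,
            )
            start = {"beta": approx.beta}
            if approx.kappa is not None:
                kap = np.asarray(approx.kappa, dtype=float)
                want = getattr(self, "n_categories", None)
                if want and kap.size < want - 1:  # declared but unobserved top categories
                    extra = kap[-1] + np.arange(1, want - kap.size)
                    kap = np.concatenate([kap, extra])
                start["kappa"] = kap
        sampler = BYMSampler(
            self.endog,
            self.exog,
            self.groups,
            self.graph,
            family=self.family,
            beta_prior_sd=self.spec.beta_prior_sd,
            sd_prior_scale=self.spec.sd_prior_scale,
            start=start,
            include_car=self.include_car,
            n_categories=getattr(self, "n_categories", None),
        )
        draws = sampler.run(mcmc)
        samples = PosteriorSamples(
            draws=draws,
            spec=self.spec,
            node_ids=list(self.graph.node_ids) if self.graph is not None else [],
            seed=mcmc.seed,
        )
        return BYMResults(model=self, samples=samples, mcmc=mcmc)


class BYMLogistic(_BYMBase):
    """Multilevel-spatial logistic regression for a binary outcome.

    ``exog`` must contain an intercept column first (handled by
    :meth:`from_cohort`); random effects are omitted when ``graph`` is
    None, giving a plain Bayesian logistic regression.
    """

    family = "logistic"

    def _validate(self) -> None:
        vals = np.unique(self.endog[~pd.isna(self.endog)])
        if not np.isin(vals, [0, 1]).all():
            raise InvalidArgumentError("binary outcome must be coded 0/1")
        if not np.allclose(self.exog[:, 0], 1.0):
            raise InvalidArgumentError("first design column must be the intercept")


class BYMOrdinal(_BYMBase):
    """Multilevel-spatial proportional-odds model for ordinal 1..K.

    Identified through K-1 ordered cutpoints and no intercept. ``n_categories``
    may declare more categories than observed; unsupported cutpoints are then
    informed by the prior only, and a support warning is emitted.
    """

    family = "ordinal"

    def __init__(self, *args, n_categories: int | None = None, **kwargs):
        self.n_categories = n_categories
        super().__init__(*args, **kwargs)

    def _validate(self) -> None:
        import warnings

        y = self.endog.astype(int)
        self.endog = y
        if y.min() < 1:
            raise InvalidArgumentError("ordinal outcome must be coded 1..K")
        if np.unique(y).size < 3:
            raise CategorySupportError(
                f"only {np.unique(y).size} observed categories; need >= 3"
            )
        K = self.n_categories or int(y.max())
        missing = sorted(set(range(1, K + 1)) - set(np.unique(y).tolist()))
        if missing:
            warnings.warn(
                f"ordinal categories {missing} are unobserved; the corresponding "
                "cutpoints are identified by the prior only",
                UserWarning,
                stacklevel=2,
            )


@dataclass
class DiagnosticsReport:
    """Split-R-hat and effective sample size per scalar parameter."""

    table: pd.DataFrame
    rhat_threshold: float
    min_ess: float
    passed: bool

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return f"Convergence {status} (R-hat <= {self.rhat_threshold}, ESS >= {self.min_ess})\n" + str(
            self.table
        )


def check_convergence(
    samples: PosteriorSamples, rhat_threshold: float = 1.1, min_ess: float = 100.0
) -> DiagnosticsReport:
    """Rank-normalized split-R-hat and bulk ESS for every scalar parameter."""
    import arviz as az

    if samples.n_chains < 2:
        raise InsufficientChainsError("convergence diagnostics require >= 2 chains")
    idata = samples.to_inference_data()
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for name in rhat.data_vars:
        rows.append(
            {
                "parameter": name,
                "rhat": float(rhat[name].values),
                "ess": float(ess[name].values),
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    passed = bool((table["rhat"] <= rhat_threshold).all() and (table["ess"] >= min_ess).all())
    return DiagnosticsReport(
        table=table, rhat_threshold=rhat_threshold, min_ess=min_ess, passed=passed
    )


@dataclass
class BYMResults:
    """Posterior summaries, diagnostics and downstream analyses of a fit."""

    model: _BYMBase
    samples: PosteriorSamples
    mcmc: MCMCConfig

    # -- summaries -------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Posterior medians, SDs, 95% equal-tailed CrIs; OR scale for betas."""
        frame = self.samples.scalar_frame()
        rows = []
        for col in frame.columns:
            x = frame[col].to_numpy()
            lo, med, hi = np.percentile(x, [2.5, 50, 97.5])
            row = {
                "parameter": col,
                "median": med,
                "sd": x.std(ddof=1),
                "ci_2.5%": lo,
                "ci_97.5%": hi,
            }
            if col.startswith("beta[") and col != "beta[intercept]":
                row["OR"] = np.exp(med)
                row["OR_2.5%"] = np.exp(lo)
                row["OR_97.5%"] = np.exp(hi)
            rows.append(row)
        return pd.DataFrame(rows).set_index("parameter")

    def odds_ratios(self) -> pd.DataFrame:
        s = self.summary()
        out = s.loc[s.index.str.startswith("beta["), ["OR", "OR_2.5%", "OR_97.5%"]].dropna()
        out.index = [ix[5:-1] for ix in out.index]
        return out

    def coef_medians(self) -> pd.Series:
        beta = self.samples.flat("beta")
        return pd.Series(np.median(beta, axis=0), index=self.samples.spec.beta_names)

    # -- spatial ---------------------------------------------------------
    def spatial_effects(self) -> pd.Series:
        """Posterior mean CAR effect per neighborhood (canonical order)."""
        if "v" not in self.samples.draws or not self.samples.draws["v"].size:
            raise ContractError("model was fitted without spatial effects")
        v = self.samples.flat("v").mean(axis=0)
        return pd.Series(v, index=self.samples.node_ids, name="v_mean")

    def decompose(self):
        """Variance decomposition into structured/unstructured IqORs."""
        from .decompose import decompose

        return decompose(self.samples)

    def convergence(self, rhat_threshold: float = 1.1, min_ess: float = 100.0) -> DiagnosticsReport:
        return check_convergence(self.samples, rhat_threshold, min_ess)

    def save(self, outdir) -> None:
        self.samples.save(outdir)

    def plot_spatial_effects(self, ax=None):
        """Choropleth of posterior mean CAR effects on the graph polygons."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Polygon as MplPolygon
        from matplotlib.collections import PatchCollection

        graph = self.model.graph
        if graph is None or graph.polygons is None:
            raise ContractError("no polygons available for mapping")
        v = self.spatial_effects()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        patches = [MplPolygon(graph.polygons[nid], closed=True) for nid in graph.node_ids]
        pc = PatchCollection(patches, cmap="RdBu_r")
        pc.set_array(v.to_numpy())
        ax.add_collection(pc)
        ax.autoscale()
        ax.set_aspect("equal")
        plt.colorbar(pc, ax=ax, label="posterior mean spatial effect (log-odds)")
        return ax
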