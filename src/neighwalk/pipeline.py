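"""The five-step modeling workflow, end to end.

Mirrors the analysis strategy of the walking study:

1. age-and-sex models for both outcomes, to quantify raw
   between-neighborhood variability (with its spatial decomposition);
2. joint individual + weather models, retaining the variables
   independently associated with each outcome;
3. one-at-a-time pretests of every environmental variable on top of
   step 2;
4. progressive combination of the flagged environmental variables into
   one final model per outcome (forward inclusion by evidence strength,
   dropping variables whose association vanishes under mutual
   adjustment);
5. weather x environment interaction tests on the final models;

followed by the environmental risk-score disparity analysis with
bootstrap intervals, a run report (descriptives, per-stage variance
decompositions, OR tables, the risk-score paragraph, provenance), and
GeoJSON choropleths of the posterior spatial effects before and after
environmental adjustment.

Variable screening steps use the fast penalized-MAP fitter with Wald
intervals as the credible-interval analog; the per-stage models feeding
the decompositions and the final models are full MCMC fits.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import __version__
from .approx import fit_penalized
from .exceptions import ConfigError, NeighwalkError
from .model import BYMLogistic, BYMOrdinal, MCMCConfig, design_from_cohort
from .riskscore import bootstrap_ors
from .simulate import GeneratorConfig, generate_cohort

__all__ = [
    "PipelineConfig",
    "RunReport",
    "step_age_sex",
    "select_individual_weather",
    "pretest_environment",
    "build_final_model",
    "test_weather_interactions",
    "run_pipeline",
]

_AGE_SEX = ["age_class", "sex_male"]


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    When ``generate`` is true the synthetic generator provides cohort
    and graph; otherwise ``cohort_path`` / ``graph_path`` are read.
    All randomness derives from ``seed``.
    """

    generate: bool = True
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cohort_path: str | None = None
    graph_path: str | None = None
    output_dir: str = "neighwalk_run"
    outcomes: tuple = ("walk_any", "walk_time_nbhd_cat")
    individual_terms: tuple = (
        "living_alone",
        "education",
        "employment",
        "occupation",
        "income",
        "non_ownership",
        "hdi_class",
    )
    weather_terms: tuple = ("rain_cat", "temp_cat")
    env_terms: tuple = (
        "nbhd_education",
        "density_destinations",
        "green_space_quality",
        "no2",
        "social_cohesion",
        "insecurity",
        "air_traffic",
        "highway",
    )
    ci_level: float = 0.95
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    n_boot: int = 200
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            d["generator"] = GeneratorConfig(**d["generator"])
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            d["mcmc"] = MCMCConfig(**d["mcmc"])
        for key in ("outcomes", "individual_terms", "weather_terms", "env_terms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def hash(self) -> str:
        """Hash of the scientific configuration (file locations excluded)."""
        d = asdict(self)
        for key in ("output_dir", "cohort_path", "graph_path"):
            d.pop(key, None)
        payload = json.dumps(d, default=str, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one run produced, renderable as Markdown + CSV."""

    descriptives: pd.DataFrame
    decompositions: dict  # (outcome, stage) -> VarianceDecomposition
    or_tables: dict  # outcome -> DataFrame (final model ORs)
    pretests: dict  # outcome -> DataFrame
    retained: dict  # outcome -> {"individual_weather": [...], "environment": [...]}
    interactions: dict  # outcome -> DataFrame
    risk_scores: dict  # outcome -> RiskScoreResult
    convergence: dict  # (outcome, stage) -> bool
    provenance: dict

    def to_markdown(self) -> str:
        lines = ["# neighwalk run report", ""]
        prov = self.provenance
        lines += [
            f"- package version: {prov['version']}",
            f"- seed: {prov['seed']}",
            f"- config hash: {prov['config_hash']}",
            "",
            "## Sample description",
            "",
            self.descriptives.to_markdown(),
            "",
            "## Between-neighborhood variance decomposition by modeling stage",
            "",
        ]
        for (outcome, stage), dec in self.decompositions.items():
            flag = "" if self.convergence.get((outcome, stage), True) else "  [CONVERGENCE FLAG]"
            lines.append(f"- **{outcome} / {stage}**: {dec}{flag}")
        lines += ["", "## Final-model odds ratios", ""]
        for outcome, tab in self.or_tables.items():
            lines += [f"### {outcome}", "", tab.round(3).to_markdown(), ""]
        lines += ["## Environmental pretests (one at a time)", ""]
        for outcome, tab in self.pretests.items():
            n_flag = int(tab["flagged"].sum())
            lines.append(
                f"- {outcome}: {n_flag} of {len(tab)} environmental variables "
                f"associated one-by-one; retained after mutual adjustment: "
                f"{', '.join(self.retained[outcome]['environment']) or 'none'}"
            )
        lines += ["", "## Weather x environment interactions", ""]
        for outcome, tab in self.interactions.items():
            if len(tab) == 0:
                lines.append(f"- {outcome}: no retained environmental variables; no tests")
            else:
                n_flag = int(tab["flagged"].sum())
                lines.append(f"- {outcome}: {n_flag} of {len(tab)} pairs flagged")
        lines += ["", "## Environmental risk score", ""]
        for outcome, rs in self.risk_scores.items():
            lines += [rs.paragraph(), ""]
        return "\n".join(lines)

    def report_hash(self) -> str:
        return hashlib.sha256(self.to_markdown().encode()).hexdigest()

    def save(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "report.md"), "w") as fh:
            fh.write(self.to_markdown())
        self.descriptives.to_csv(os.path.join(outdir, "descriptives.csv"))
        rows = []
        for (outcome, stage), dec in self.decompositions.items():
            fr = dec.to_frame()
            fr.insert(0, "outcome", outcome)
            fr.insert(1, "stage", stage)
            rows.append(fr)
        pd.concat(rows).to_csv(os.path.join(outdir, "decompositions.csv"))
        for outcome, tab in self.or_tables.items():
            tab.to_csv(os.path.join(outdir, f"odds_ratios_{outcome}.csv"))
        for outcome, tab in self.pretests.items():
            tab.to_csv(os.path.join(outdir, f"pretests_{outcome}.csv"), index=False)
        for outcome, rs in self.risk_scores.items():
            rs.or_table.to_csv(os.path.join(outdir, f"risk_score_{outcome}.csv"))
        with open(os.path.join(outdir, "provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)


def fixture_config(output_dir: str = "neighwalk_run", seed: int = 0) -> PipelineConfig:
    """The packaged desk-scale demonstration configuration."""
    from importlib import resources

    import yaml

    text = resources.files("neighwalk").joinpath("data/fixture_config.yaml").read_text()
    d = yaml.safe_load(text)
    d["output_dir"] = output_dir
    d["seed"] = seed
    return PipelineConfig.from_dict(d)


def _descriptives(cohort: pd.DataFrame, terms) -> pd.DataFrame:
    rows = []
    for t in terms:
        if t not in cohort.columns:
            continue
        counts = cohort[t].value_counts(normalize=True).sort_index()
        for lev, frac in counts.items():
            rows.append({"variable": t, "level": lev, "percent": 100 * frac})
    return pd.DataFrame(rows).set_index(["variable", "level"])


def _model_for(cohort, outcome, terms, graph):
    y = cohort[outcome].dropna().to_numpy()
    binary = np.isin(np.unique(y), [0, 1]).all()
    cls = BYMLogistic if binary else BYMOrdinal
    return cls.from_cohort(cohort, outcome, terms, graph=graph)


def _approx_fit_terms(cohort, outcome, terms, ci_level):
    """Penalized-MAP fit; returns (names, beta, lo, hi) for the terms."""
    mask = cohort[outcome].notna()
    sub = cohort.loc[mask]
    y = sub[outcome].to_numpy()
    binary = np.isin(np.unique(y), [0, 1]).all()
    X, names = design_from_cohort(sub, list(terms), intercept=binary)
    groups = pd.Categorical(sub["neighborhood_id"]).codes.astype(int)
    fit = fit_penalized(
        y if binary else y.astype(int),
        X,
        groups=groups,
        family="logistic" if binary else "ordinal",
        compute_se=True,
    )
    z = norm.ppf(0.5 + ci_level / 2)
    lo = fit.beta - z * fit.se_beta
    hi = fit.beta + z * fit.se_beta
    return names, fit.beta, lo, hi


def _significant_vars(names, lo, hi, variables) -> dict:
    """Which variables have any non-reference level excluding zero, and
    the strongest |z|-like evidence per variable."""
    out = {}
    for var in variables:
        idx = [i for i, nm in enumerate(names) if nm == var or nm.startswith(f"{var}[")]
        if not idx:
            continue
        sig = any(lo[i] > 0 or hi[i] < 0 for i in idx)
        strengths = []
        for i in idx:
            hw = (hi[i] - lo[i]) / 2
            strengths.append(
                abs((lo[i] + hi[i]) / 2) / max(hw, 1e-12) if np.isfinite(hw) else 0.0
            )
        out[var] = (sig, max(strengths))
    return out


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------


def step_age_sex(cohort, graph, mcmc: MCMCConfig, outcome: str):
    """Stage 1: age + sex only; returns (results, decomposition)."""
    model = _model_for(cohort, outcome, _AGE_SEX, graph)
    res = model.fit(mcmc)
    return res, res.decompose()


def select_individual_weather(cohort, outcome: str, candidates, ci_level: float = 0.95):
    """Stage 2 screening: fit age/sex + all candidates jointly and keep
    the variables independently associated with the outcome (some
    interval excludes the null). Age and sex are always kept."""
    if len(list(candidates)) == 0:
        raise ConfigError("candidate list is empty")
    terms = _AGE_SEX + [c for c in candidates if c not in _AGE_SEX]
    names, beta, lo, hi = _approx_fit_terms(cohort, outcome, terms, ci_level)
    sig = _significant_vars(names, lo, hi, [c for c in candidates if c not in _AGE_SEX])
    return [v for v, (s, _) in sig.items() if s]


def pretest_environment(cohort, outcome: str, env_list, base_terms, ci_level: float = 0.95):
    """Stage 3: each environmental variable added alone to the stage-2
    model; returns a table with one row per variable."""
    rows = []
    for var in env_list:
        names, beta, lo, hi = _approx_fit_terms(
            cohort, outcome, list(base_terms) + [var], ci_level
        )
        sig = _significant_vars(names, lo, hi, [var])
        flagged, strength = sig.get(var, (False, 0.0))
        rows.append({"variable": var, "flagged": flagged, "evidence": strength})
    return pd.DataFrame(rows)


def build_final_model(
    cohort, outcome: str, pretest_table: pd.DataFrame, base_terms, ci_level: float = 0.95
):
    """Stage 4: progressively combine the flagged environmental
    variables (descending pretest evidence); a variable enters only if
    it stays associated given those already included, and a final prune
    removes variables whose association vanished. Returns the retained
    environmental variable list."""
    flagged = pretest_table.loc[pretest_table["flagged"]].sort_values(
        "evidence", ascending=False
    )["variable"].tolist()
    current: list[str] = []
    for var in flagged:
        names, beta, lo, hi = _approx_fit_terms(
            cohort, outcome, list(base_terms) + current + [var], ci_level
        )
        sig = _significant_vars(names, lo, hi, [var])
        if sig.get(var, (False, 0.0))[0]:
            current.append(var)
    # prune until stable
    for _ in range(5):
        if not current:
            break
        names, beta, lo, hi = _approx_fit_terms(
            cohort, outcome, list(base_terms) + current, ci_level
        )
        sig = _significant_vars(names, lo, hi, current)
        keep = [v for v in current if sig.get(v, (False, 0.0))[0]]
        if keep == current:
            break
        current = keep
    return current


def test_weather_interactions(
    cohort, outcome: str, final_terms, weather_vars, env_vars, ci_level: float = 0.95
):
    """Stage 5: weather x environment product terms, one pair at a time.

    Indicator-by-indicator products of the two variables' dummy
    expansions are appended to the final model; a pair is flagged when
    any product interval excludes the null."""
    rows = []
    for w in weather_vars:
        for e in env_vars:
            work = cohort.copy()
            prod_cols = []
            wX, wn = design_from_cohort(work, [w])
            eX, en = design_from_cohort(work, [e])
            for iw, nw in enumerate(wn):
                for ie, ne in enumerate(en):
                    cname = f"ix__{nw}__{ne}"
                    work[cname] = wX[:, iw] * eX[:, ie]
                    prod_cols.append(cname)
            names, beta, lo, hi = _approx_fit_terms(
                work, outcome, list(final_terms) + prod_cols, ci_level
            )
            idx = [i for i, nm in enumerate(names) if nm.startswith("ix__")]
            flagged = any(lo[i] > 0 or hi[i] < 0 for i in idx)
            rows.append({"weather": w, "environment": e, "flagged": flagged})
    return pd.DataFrame(rows, columns=["weather", "environment", "flagged"])


def _stage_seed(base_seed: int, k: int) -> int:
    return int(np.random.SeedSequence([base_seed, k]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, cohort=None, graph=None) -> RunReport:
    """Execute generation, all five modeling steps, the decompositions,
    the risk-score analysis, and write the report + artifacts.

    Stage failures raise a :class:`NeighwalkError` naming the stage;
    artifacts produced so far remain in ``config.output_dir``.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    stage = "inputs"
    try:
        if cohort is None or graph is None:
            if config.generate:
                gen_cfg = config.generator
                cohort, graph = generate_cohort(gen_cfg)
            else:
                from .io import load_cohort, load_graph

                cohort = load_cohort(config.cohort_path)
                graph = load_graph(config.graph_path)
        for term in list(config.individual_terms) + list(config.weather_terms) + list(
            config.env_terms
        ):
            if term not in cohort.columns:
                raise ConfigError(f"configured column {term!r} absent from cohort")

        descr = _descriptives(
            cohort, _AGE_SEX + list(config.individual_terms) + list(config.weather_terms)
        )

        decomps: dict = {}
        conv: dict = {}
        or_tables: dict = {}
        pretests: dict = {}
        retained: dict = {}
        interactions: dict = {}
        risk_results: dict = {}
        spatial_props: dict = {}
        k = 0

        for outcome in config.outcomes:
            # ---- stage 1: age & sex
            stage = f"{outcome}/age_sex"
            mc = MCMCConfig(**{**asdict(config.mcmc), "seed": _stage_seed(config.seed, k)})
            k += 1
            res1, dec1 = step_age_sex(cohort, graph, mc, outcome)
            decomps[(outcome, "age_sex")] = dec1
            conv[(outcome, "age_sex")] = res1.convergence().passed

            # ---- stage 2: individual + weather selection
            stage = f"{outcome}/select_individual_weather"
            candidates = list(config.individual_terms) + list(config.weather_terms)
            kept_iw = select_individual_weather(cohort, outcome, candidates, config.ci_level)
            base_terms = _AGE_SEX + kept_iw
            mc = MCMCConfig(**{**asdict(config.mcmc), "seed": _stage_seed(config.seed, k)})
            k += 1
            res2 = _model_for(cohort, outcome, base_terms, graph).fit(mc)
            decomps[(outcome, "individual_level")] = res2.decompose()
            conv[(outcome, "individual_level")] = res2.convergence().passed

            # ---- stage 3: environmental pretests
            stage = f"{outcome}/pretest_environment"
            pt = pretest_environment(
                cohort, outcome, config.env_terms, base_terms, config.ci_level
            )
            pretests[outcome] = pt

            # ---- stage 4: final model
            stage = f"{outcome}/final_model"
            kept_env = build_final_model(cohort, outcome, pt, base_terms, config.ci_level)
            retained[outcome] = {"individual_weather": kept_iw, "environment": kept_env}
            final_terms = base_terms + kept_env
            mc = MCMCConfig(**{**asdict(config.mcmc), "seed": _stage_seed(config.seed, k)})
            k += 1
            res_final = _model_for(cohort, outcome, final_terms, graph).fit(mc)
            decomps[(outcome, "environmental")] = res_final.decompose()
            conv[(outcome, "environmental")] = res_final.convergence().passed
            or_tables[outcome] = res_final.odds_ratios()

            # spatial effect maps before/after environmental adjustment
            v2 = res2.spatial_effects()
            v3 = res_final.spatial_effects()
            spatial_props[f"{outcome}_before_env"] = v2.to_dict()
            spatial_props[f"{outcome}_after_env"] = v3.to_dict()

            # ---- stage 5: interactions
            stage = f"{outcome}/weather_interactions"
            weather_kept = [w for w in config.weather_terms if w in kept_iw]
            interactions[outcome] = test_weather_interactions(
                cohort, outcome, final_terms, weather_kept, kept_env, config.ci_level
            )

            # ---- risk score
            stage = f"{outcome}/risk_score"
            coefs = res_final.coef_medians()
            env_coefs = {
                nm: float(b)
                for nm, b in coefs.items()
                if any(nm == e or nm.startswith(f"{e}[") for e in kept_env)
            }
            if env_coefs:
                rs = bootstrap_ors(
                    cohort,
                    outcome,
                    base_terms,
                    env_coefs,
                    n_boot=config.n_boot,
                    seed=_stage_seed(config.seed, k),
                )
                k += 1
                risk_results[outcome] = rs

        stage = "report"
        if graph.polygons is not None and spatial_props:
            graph.to_geojson(
                os.path.join(config.output_dir, "spatial_effects.geojson"),
                properties=spatial_props,
            )
        provenance = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.hash(),
            "n_individuals": int(len(cohort)),
            "n_neighborhoods": int(graph.n_nodes),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        report = RunReport(
            descriptives=descr,
            decompositions=decomps,
            or_tables=or_tables,
            pretests=pretests,
            retained=retained,
            interactions=interactions,
            risk_scores=risk_results,
            convergence=conv,
            provenance=provenance,
        )
        report.save(config.output_dir)
        return report
    except Exception as err:
        raise NeighwalkError(f"pipeline failed at stage {stage!r}: {err}") from err
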