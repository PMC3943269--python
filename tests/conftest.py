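"""Shared fixtures: small synthetic cohorts and reusable MCMC fits.

MCMC fits are session-scoped so that several invariant checks share one
sampler run instead of refitting.
"""

import numpy as np
import pytest

from neighwalk.model import BYMLogistic, BYMOrdinal, MCMCConfig
from neighwalk.simulate import GeneratorConfig, generate_cohort


def moran_i(field: np.ndarray, edges_i: np.ndarray, edges_j: np.ndarray) -> float:
    """Independent Moran's I implementation (binary weights, symmetric)."""
    x = np.asarray(field, dtype=float)
    z = x - x.mean()
    num = 2.0 * np.sum(z[edges_i] * z[edges_j])  # both directions of each edge
    W = 2.0 * edges_i.size
    return (x.size / W) * num / np.sum(z**2)


@pytest.fixture(scope="session")
def small_cohort():
    """8x8 lattice, ~15 individuals per cell, moderate spatial signal."""
    cfg = GeneratorConfig(
        lattice_rows=8,
        lattice_cols=8,
        n_per_neighborhood=15,
        vary_n=False,
        true_betas={"sex_male[1]": np.log(1.38)},
        true_betas_ordinal={"sex_male[1]": np.log(1.28)},
        sigma_u=0.25,
        tau_v=0.4,
        missing_rate=0.0,
        seed=123,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def logistic_fit(small_cohort):
    cohort, graph = small_cohort
    model = BYMLogistic.from_cohort(cohort, "walk_any", ["age_class", "sex_male"], graph=graph)
    return model.fit(MCMCConfig(n_chains=2, n_iter=1600, n_burnin=600, thin=2, seed=77))


@pytest.fixture(scope="session")
def ordinal_fit(small_cohort):
    cohort, graph = small_cohort
    model = BYMOrdinal.from_cohort(cohort, "walk_time_nbhd_cat", ["sex_male"], graph=graph)
    return model.fit(MCMCConfig(n_chains=2, n_iter=1600, n_burnin=600, thin=2, seed=78))


@pytest.fixture(scope="session")
def pipeline_report_and_dir(tmp_path_factory):
    """One small end-to-end pipeline run shared across tests."""
    from neighwalk.pipeline import PipelineConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline_run")
    cfg = PipelineConfig(
        generator=GeneratorConfig(
            lattice_rows=8, lattice_cols=8, n_per_neighborhood=15, seed=101
        ),
        mcmc=MCMCConfig(n_iter=1200, n_burnin=500, thin=2),
        n_boot=30,
        seed=42,
        output_dir=str(outdir),
    )
    report = run_pipeline(cfg)
    return report, outdir
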