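"""Shared fixtures: small simulated studies reused across test modules."""

import logging

import numpy as np
import pytest

from modtrait.preprocess import (
    build_analysis_table,
    estimate_slopes,
    transform_pathology,
)
from modtrait.synthetic import CohortConfig, EffectSpec, simulate_study

logging.disable(logging.WARNING)


def make_study(
    n_subjects=200,
    n_genes=100,
    n_modules=5,
    n_snps=6,
    seed=0,
    effects=None,
    **cohort_kwargs,
):
    config = CohortConfig(n_subjects=n_subjects, seed=seed, **cohort_kwargs)
    return simulate_study(
        config,
        effects or EffectSpec(),
        n_genes=n_genes,
        n_modules=n_modules,
        n_snps=n_snps,
        seed=seed,
    )


def analysis_table(study):
    return build_analysis_table(
        study.cohort,
        study.module_expr,
        transform_pathology(study.outcomes.pathology),
        estimate_slopes(study.outcomes.cognition),
        study.outcomes.ad,
    )


@pytest.fixture(scope="session")
def null_study():
    """A no-effect study: every downstream association is null."""
    return make_study(n_subjects=200, n_genes=100, n_modules=5, seed=11)


@pytest.fixture(scope="session")
def null_analysis(null_study):
    return analysis_table(null_study)


@pytest.fixture(scope="session")
def chain_study():
    """A study with the full planted trait->module->tau->slope->AD chain."""
    effects = EffectSpec(
        trait_to_module={"m2": 0.4},
        module_to_tau={"m2": 0.4},
        tau_to_slope=0.4,
        slope_to_ad=1.2,
    )
    return make_study(
        n_subjects=500, n_genes=150, n_modules=5, seed=21, effects=effects
    )


@pytest.fixture(scope="session")
def chain_analysis(chain_study):
    return analysis_table(chain_study)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
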