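"""Shared fixtures: one modest cohort simulated once per session."""

from types import SimpleNamespace

import numpy as np
import pytest

import pathprs as pp


@pytest.fixture(scope="session")
def small_config() -> pp.SimulationConfig:
    return pp.SimulationConfig(
        n_individuals=3000,
        n_variants=400,
        n_genes=40,
        n_pathways_per_library=10,
        genes_per_pathway=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    genotypes = pp.simulate_genotypes(small_config)
    annotation, libraries = pp.simulate_annotation(small_config)
    phenotypes, effects = pp.simulate_phenotypes(
        genotypes, annotation, libraries, small_config
    )
    return SimpleNamespace(
        config=small_config,
        genotypes=genotypes,
        annotation=annotation,
        libraries=libraries,
        phenotypes=phenotypes,
        effects=effects,
    )


@pytest.fixture(scope="session")
def male_gwas(small_cohort):
    """Linear GWAS of the balding pattern among males, age-adjusted."""
    phen = small_cohort.phenotypes
    mask = (phen["sex"] == "male") & phen["aga_pattern"].notna()
    idx = np.flatnonzero(mask.to_numpy())
    males = pp.subset_individuals(small_cohort.genotypes, idx)
    return pp.run_gwas(
        males,
        phen.loc[mask, "aga_pattern"].to_numpy(float),
        covariates=phen.loc[mask, "age_at_assessment"].to_numpy(float),
        model="linear",
    )
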