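"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

import varscreen as vs


@pytest.fixture(scope="session")
def small_config():
    return vs.SimConfig(seed=11, n_families=60, n_snps=120,
                        n_cases=80, n_controls=120,
                        exome_genes=30, wes_cases=50, wes_controls=300)


@pytest.fixture(scope="session")
def trio_cohort(small_config):
    return vs.simulate_trios(small_config)


@pytest.fixture(scope="session")
def cc_cohort(small_config):
    return vs.simulate_case_control(small_config)


@pytest.fixture(scope="session")
def exome_cohort(small_config):
    return vs.simulate_exome_cohort(small_config)


@pytest.fixture(scope="session")
def study(small_config):
    return vs.simulate_study(small_config)


def make_gm(genotypes, roles=None, sex=None, chrom="1", pos=None, r2=None):
    """Hand-built GenotypeMatrix for tiny worked examples."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_s, n_v = genotypes.shape
    meta = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(n_v)],
        "chrom": chrom,
        "pos": pos if pos is not None else 1000 * (np.arange(n_v) + 1),
        "ref": "A",
        "alt": "G",
        "imputation_r2": r2 if r2 is not None else np.nan,
    })
    return vs.GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n_s)],
        roles=np.array(roles if roles is not None else ["control"] * n_s, object),
        sex=np.array(sex if sex is not None else ["unknown"] * n_s, object),
        genotypes=genotypes,
        variant_meta=meta,
    )
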