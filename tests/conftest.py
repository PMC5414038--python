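import numpy as np
import pandas as pd
import pytest

from methylica.preprocess import BetaMatrix, residualize
from methylica.synthetic import (
    SyntheticDesign,
    generate_annotation,
    generate_genotypes,
    generate_methylome,
    generate_phenotypes,
)


@pytest.fixture(scope="session")
def small_design() -> SyntheticDesign:
    return SyntheticDesign(n_samples=200, n_cpgs=2000, n_components=3, seed=1)


@pytest.fixture(scope="session")
def small_fixtures(small_design):
    """Full synthetic fixture set at desk scale, shared across tests."""
    betas, truth = generate_methylome(small_design)
    phenotypes = generate_phenotypes(small_design, truth)
    cpgs, transcripts = generate_annotation(small_design)
    genotypes, snp_table = generate_genotypes(small_design, truth, cpgs, transcripts)
    return {
        "design": small_design,
        "betas": betas,
        "truth": truth,
        "phenotypes": phenotypes,
        "cpgs": cpgs,
        "transcripts": transcripts,
        "genotypes": genotypes,
        "snp_table": snp_table,
    }


@pytest.fixture(scope="session")
def recovery_model():
    """A decomposition of strongly planted components, shared across tests."""
    from methylica.decompose import decompose

    # signal_scale is kept small so the logistic squashing stays near-linear
    # and the planted rank is exactly what RMT should report
    design = SyntheticDesign(
        n_samples=300, n_cpgs=8000, n_components=4, loading_scale=6.0, signal_scale=0.05, seed=5
    )
    betas, truth = generate_methylome(design)
    residuals = residualize(betas)
    model = decompose(residuals, k=4, n_restarts=5, seed=5)
    return {"design": design, "truth": truth, "residuals": residuals, "model": model}


def toy_beta_matrix(values, sample_prefix="s", cpg_prefix="cg") -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return BetaMatrix(
        values,
        [f"{sample_prefix}{i}" for i in range(n)],
        [f"{cpg_prefix}{j}" for j in range(p)],
    )
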