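import numpy as np
import pandas as pd
import pytest

import birdreg as br


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_truth():
    """A small simulated dataset shared by fast tests."""
    cfg = br.SimulationConfig(
        n_train=15,
        n_test=6,
        n_genes=200,
        n_gene_clusters=8,
        n_loci=300,
        n_pathways=10,
        seed=1,
    )
    return br.simulate(cfg)


@pytest.fixture(scope="session")
def small_model(small_truth):
    model = br.BIRD(
        n_gene_clusters=12, n_predictors=4, pathway_sizes=(10,), random_state=0
    )
    model.fit(small_truth.expr_train, small_truth.dh_train)
    return model


@pytest.fixture(scope="session")
def noiseless_truth():
    """Noise-free data: DH rows are exact affine functions of the latent
    module activities, so a well-specified model can fit them exactly."""
    cfg = br.SimulationConfig(
        n_train=12,
        n_test=5,
        n_genes=60,
        n_gene_clusters=6,
        n_loci=80,
        n_pathways=8,
        predictors_per_pathway=3,
        expression_noise_sd=0.0,
        dh_noise_sd=0.0,
        propensity_sd=1.0,
        seed=3,
    )
    return br.simulate(cfg)


@pytest.fixture(scope="session")
def noiseless_model(noiseless_truth):
    model = br.BIRD(
        n_gene_clusters=6,
        n_predictors=6,
        pathway_sizes=(),
        map_to_training_quantiles=False,
        random_state=0,
    )
    model.fit(noiseless_truth.expr_train, noiseless_truth.dh_train)
    return model


def make_bins(n, chrom="chr1", width=200, start=0):
    starts = start + np.arange(n) * width
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width})
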