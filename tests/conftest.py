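import logging

import numpy as np
import pytest

from rnmkit.pheno import standardize
from rnmkit.qc import compute_grm
from rnmkit.reml import VarianceComponents, fit_nested_models
from rnmkit.synthetic import SimulationConfig, simulate_dataset

# convergence chatter from deliberately stressed fits is noise in test output
logging.getLogger("rnmkit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def interaction_data():
    """One simulated dataset with both GxE and RxE interaction planted."""
    cfg = SimulationConfig(
        n_individuals=400,
        n_snps=400,
        seed=11,
        vc_true=VarianceComponents(
            sigma2_a0=0.4, sigma2_a1=0.3, sigma2_t0=0.3, sigma2_t1=0.2
        ),
    )
    d = simulate_dataset(cfg)
    d["grm"] = compute_grm(d["genotypes"])
    d["c"] = standardize(d["covariate"]).values
    d["config"] = cfg
    return d


@pytest.fixture(scope="session")
def interaction_fits(interaction_data):
    """The four nested REML fits on the interaction dataset."""
    d = interaction_data
    return fit_nested_models(d["phenotype"], d["grm"].values, d["c"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
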