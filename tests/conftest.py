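import logging

import pytest

from cfsecretome import SimConfig, simulate_all
from cfsecretome.config import DropoutConfig

logging.disable(logging.WARNING)


def small_sizes() -> dict[str, int]:
    return {
        "ecm_scaffold": 4,
        "collagen": 4,
        "cytokine": 4,
        "mmp_timp": 4,
        "other_secreted": 14,
        "membrane": 2,
        "er": 2,
        "intracellular": 4,
    }


@pytest.fixture(scope="session")
def default_bundle():
    """One simulated study at the default (acceptance) conditions."""
    return simulate_all(SimConfig(), seed=20211112 % 2**16)


@pytest.fixture(scope="session")
def noiseless_config():
    """All random variation off: planted values must be recovered exactly."""
    return SimConfig(
        patient_sd=0.0,
        noise_sd=0.0,
        peptide_sd=0.0,
        ms_dropout=DropoutConfig(enabled=False),
        n_proteins=small_sizes(),
        probes_per_gene=(1, 3),
        n_below_threshold_genes=3,
    )


@pytest.fixture(scope="session")
def noiseless_bundle(noiseless_config):
    return simulate_all(noiseless_config, seed=5)
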