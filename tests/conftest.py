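import numpy as np
import pytest
from hypothesis import settings

from gpcrbias.simulate import (
    BIAS_PANEL_CONCENTRATIONS,
    AssayDesign,
    TruthRecord,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def noise_free_design():
    """Single noise-free experiment on the bias-panel grid."""
    return AssayDesign(
        concentrations=BIAS_PANEL_CONCENTRATIONS.copy(),
        replicates_per_conc=1,
        n_experiments=1,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture
def default_design():
    """Study-condition design: 8 half-log concentrations, triplicate wells,
    three independent experiments, 5% well noise."""
    return AssayDesign(concentrations=BIAS_PANEL_CONCENTRATIONS.copy(), seed=0)


@pytest.fixture
def reference_truth():
    """High-efficacy full agonist (tau=100, K_A=100 nM -> logR=9)."""
    return TruthRecord("REF", "gprotein", tau=100.0, ka=1e-7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
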