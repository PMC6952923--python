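import numpy as np
import pytest

from mirtorus import SimSpec, simulate_expression, simulate_sequences
from mirtorus.simulate import DiseasePanel


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def small_panel():
    """A small simulated pool with two well-separated disease panels."""
    spec = SimSpec(
        seed=7,
        n_mirnas=60,
        diseases=(
            DiseasePanel("D1", n_mirnas=30, log2fc_sd=1.5),
            DiseasePanel("D2", n_mirnas=30, log2fc_sd=1.5),
        ),
        slope_separation=3.0,
        outlier_rate=0.0,
    )
    sequences = simulate_sequences(spec)
    records = simulate_expression(spec, sequences)
    return spec, sequences, records


def random_sequence(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))
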