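import logging

import numpy as np
import pandas as pd
import pytest

from sedseq.synthetic import CONTROL, ConditionSpec, make_catalog, simulate_experiment

# fit-time clamp warnings flood simulation-heavy tests; failures still raise
logging.getLogger("sedseq.physical").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def catalog():
    return make_catalog(2000, seed=101)


@pytest.fixture(scope="session")
def stress_condition():
    return ConditionSpec(
        name="stress",
        mu=1.5,
        induction_log2fc={"induced": 3.0},
        escape_effect={"induced": 1.5},
    )


@pytest.fixture(scope="session")
def control_experiment(catalog):
    return simulate_experiment(catalog=catalog, condition=CONTROL, depth=2e6, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def length_table(catalog):
    return catalog[["transcript_id", "length_nt"]]


def baseline_lopsup(lengths, beta=4e-4, chi=0.8, mu=0.0):
    """Exact log-odds pSup under the mass/condensation law (test helper)."""
    pellet = np.clip(beta * np.asarray(lengths, float) ** chi * np.exp(mu), 1e-12, 1 - 1e-9)
    return np.log((1 - pellet) / pellet)


@pytest.fixture(scope="session")
def psup_frame():
    def make(ids, psup):
        return pd.DataFrame({"transcript_id": ids, "psup": psup})

    return make
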