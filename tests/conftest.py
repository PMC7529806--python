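import warnings

import numpy as np
import pandas as pd
import pytest

from vpeca.pipeline import fit_study
from vpeca.simulate import SimulationConfig, default_recovery_config, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """The canonical synthetic study at the documented seed."""
    return simulate_study(default_recovery_config(), seed=1)


@pytest.fixture(scope="session")
def default_result(default_study):
    s = default_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_study(
            s.expression, s.openness, s.design, s.snps, s.res, s.cmap, s.B,
            s.panel_expression, s.panel_openness, seed=1,
        )


@pytest.fixture(scope="session")
def small_config():
    """A miniature study for fast end-to-end checks."""
    return SimulationConfig(n_genes=12, n_tfs=10, n_panel_contexts=20,
                            genome_len=2_000_000)


@pytest.fixture
def toy_design_frame():
    rows = []
    for pop, tag in (("adaptive", "A"), ("wildtype", "W")):
        for i in (1, 2):
            for t in ("0h", "6h"):
                rows.append((f"{tag}{i}_{t}", f"{tag}{i}", t, pop))
    return pd.DataFrame(rows, columns=["sample_id", "individual", "time", "population"])
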