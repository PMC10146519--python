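import numpy as np
import pandas as pd
import pytest

from gcvolatiles import PeakTable, SimConfig, simulate_study


def make_table(areas, lines=None, sexes=None, matings=None, batches=None, labels=None, tag=""):
    """Small hand-built peak table for unit tests."""
    areas = np.asarray(areas, dtype=float)
    n, p = areas.shape
    labels = labels if labels is not None else [round(5.0 + 0.5 * i, 2) for i in range(p)]
    idx = pd.Index([f"s{i + 1}" for i in range(n)], name="sample_id")
    meta = pd.DataFrame(
        {
            "line": lines if lines is not None else ["L1"] * n,
            "sex": sexes if sexes is not None else ["male"] * n,
            "mating": matings if matings is not None else ["virgin"] * n,
            "batch": batches if batches is not None else ["B1"] * n,
        },
        index=idx,
    )
    return PeakTable(meta, pd.DataFrame(areas, index=idx, columns=labels), dataset_tag=tag)


@pytest.fixture(scope="session")
def sim_study():
    """One default-configuration simulated study shared across tests."""
    tables, truth = simulate_study(SimConfig(), seed=7)
    return tables, truth


@pytest.fixture(scope="session")
def sim_male_mixed(sim_study):
    tables, _ = sim_study
    return tables[("male", "mixed")]
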