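import numpy as np
import pandas as pd
import pytest

from nsclc_scmet import synthetic_data as sd
from nsclc_scmet.io_formats import ClinicalTable, ExpressionMatrix, GeneSetCollection


@pytest.fixture(scope="session")
def sc_sim():
    """Default planted-pathway simulation (shared across tests)."""
    return sd.simulate_sc(sd.SCSimSpec(seed=1))


@pytest.fixture(scope="session")
def traj_sim():
    return sd.simulate_trajectory(sd.TrajSimSpec(seed=1))


@pytest.fixture(scope="session")
def surv_sim():
    return sd.simulate_survival(sd.SurvSimSpec(seed=1))


@pytest.fixture
def worked_pathway_fixture():
    """2-cluster, 3-gene matrix whose pathway score is 19/18 / 17/18 by hand.

    g1 (only in P1): cluster A cells (2,2), B cells (1,1) -> r_A=4/3, r_B=2/3.
    g2 (in P1 and P2, weight 1/2): A (0.5,0.5), B (1.5,1.5) -> r_A=1/2, r_B=3/2.
    g3 pads P2.
    """
    values = np.array([
        [2.0, 2.0, 1.0, 1.0],
        [0.5, 0.5, 1.5, 1.5],
        [1.0, 1.0, 1.0, 1.0],
    ])
    m = ExpressionMatrix(values, ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"],
                         layer_tag="normalized")
    labels = np.array(["A", "A", "B", "B"])
    gsc = GeneSetCollection({"P1": ["g1", "g2"], "P2": ["g2", "g3"]})
    return m, labels, gsc


def make_clinical(times, events, prefix="s"):
    ids = [f"{prefix}{i}" for i in range(len(times))]
    return ClinicalTable(pd.DataFrame(
        {"time": np.asarray(times, float), "event": np.asarray(events, int)},
        index=pd.Index(ids, name="sample_id"),
    ))


@pytest.fixture
def clinical_factory():
    return make_clinical
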