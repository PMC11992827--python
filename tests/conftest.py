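import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ctpdn.simulate import SimSpec, gen_cti_dataset, gen_network, gen_peak_table

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def network_fixture():
    return gen_network(SimSpec(seed=11))


@pytest.fixture(scope="session")
def cti_small():
    """Small labelled CTI dataset shared by the model tests."""
    return gen_cti_dataset(SimSpec(seed=7, cti_n_compounds=40, cti_n_targets=12, n_pairs=300))


@pytest.fixture(scope="session")
def peaks_default():
    return gen_peak_table(SimSpec(seed=5, noisy_qc_features=2))


@pytest.fixture
def toy_compounds():
    return pd.DataFrame({
        "compound_id": ["a", "b", "c", "d"],
        "smiles": ["CCO", "c1ccccc1", "CC(C)O", "CCN"],
        "ob": [35.0, 30.0, 25.0, 80.0],
        "dl": [0.20, 0.18, 0.50, 0.10],
        "admet_as": [1.0] * 4,
        "admet_bbb": [2.0] * 4,
        "admet_cyp2d6": [0.0] * 4,
        "admet_hepatotoxicity": [1.0] * 4,
        "admet_ppb": [0.0] * 4,
    })


@pytest.fixture
def toy_pathways():
    return pd.DataFrame({
        "pathway_id": ["p1", "p2", "p3"],
        "name": ["one", "two", "three"],
        "p_value": [1e-9, 1e-7, 1e-9],
        "q_value": [1e-8, 1e-6, 1e-8],
        "member_targets": ["AKT1", "AKT1;CAT", ""],
        "diseases": ["d1", "d1", "d1"],
    })


def make_peak_table(values, groups, is_qc, feature_ids=None):
    """Assemble a PeakTable from a plain array plus annotations."""
    from ctpdn.metabolomics import PeakTable

    values = np.asarray(values, dtype=float)
    samples = [f"S{i}" for i in range(values.shape[1])]
    if feature_ids is None:
        feature_ids = [f"F{i}" for i in range(values.shape[0])]
    return PeakTable(
        intensities=pd.DataFrame(values, index=feature_ids, columns=samples),
        groups=pd.Series(list(groups), index=samples),
        is_qc=pd.Series(list(is_qc), index=samples),
    )
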