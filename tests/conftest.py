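import numpy as np
import pandas as pd
import pytest

from metabloc.containers import FeatureMatrix
from metabloc.preprocess import autoscale, pqn_normalize
from metabloc.synthdata import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the study's NMR-arm dimensions (141 x 74, 14 blocks)."""
    return generate_dataset(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def default_pipeline_state(default_dataset):
    """PQN + autoscaled matrices and dummy-coded labels for the default dataset."""
    ds = default_dataset
    pqn = pqn_normalize(ds.features)
    scaled, scaler = autoscale(pqn.normalized)
    y = (ds.metadata["group"] == "Prem").astype(int).to_numpy()
    return {"ds": ds, "pqn": pqn, "scaled": scaled, "scaler": scaler, "y": y}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def toy_matrix(values, state="raw"):
    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        arr,
        index=[f"S{i+1}" for i in range(arr.shape[0])],
        columns=[f"M{j+1}" for j in range(arr.shape[1])],
    )
    return FeatureMatrix(df, state=state)
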