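import io

import numpy as np
import pandas as pd
import pytest
import skbio

import terraomics as t


@pytest.fixture
def small_table():
    """4 samples x 5 features count table."""
    rng = np.random.default_rng(7)
    vals = rng.integers(0, 50, size=(4, 5)).astype(float)
    vals[0, 2] = 0.0
    return t.FeatureTable(vals, [f"s{i}" for i in range(4)],
                          [f"f{j}" for j in range(5)], "counts")


@pytest.fixture
def small_metadata():
    rows = []
    for i in range(4):
        env = "env_a" if i < 2 else "env_b"
        rows.append((f"s{i}", "free-living", "non-saline", "water", env,
                     "study_00", "bulk", "none"))
    df = pd.DataFrame(rows, columns=["sample_id", "empo_1", "empo_2", "empo_3",
                                     "empo_4", "study_id", "device",
                                     "control_role"]).set_index("sample_id")
    return t.SampleMetadata(df)


@pytest.fixture
def star_tree():
    """Star phylogeny with four unit branches A-D."""
    return skbio.TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1):0;"))


@pytest.fixture(scope="session")
def default_study():
    """One default coupled simulation shared across tests."""
    cfg = t.SimulationConfig(seed=0)
    return t.simulate_study(cfg), cfg


@pytest.fixture(scope="session")
def recovery_study():
    """Larger study (50 samples/environment, 100 microbes) for parameter
    recovery checks."""
    cfg = t.SimulationConfig(seed=3, samples_per_environment=50, n_microbes=100)
    return t.simulate_study(cfg), cfg
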