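import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sigscreen as sg

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def tiny_counts():
    """3 genes x 4 samples, two groups, literal values."""
    values = pd.DataFrame(
        [[50, 40, 5, 8], [20, 25, 22, 18], [3, 2, 70, 60]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    ann = pd.DataFrame({"Group": ["A", "A", "B", "B"]}, index=values.columns)
    return sg.ExpressionDataset(values=values, scale="raw_counts", annotations=ann)


@pytest.fixture(scope="session")
def sim_dataset():
    """One simulated 4-group dataset with planted markers, shared across tests."""
    return sg.generate_counts(
        n_groups=4, n_per_group=5, n_genes=800, n_markers_per_group=25,
        lfc=2.0, dispersion=0.1, seed=7,
    )


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("NK\tsrc\tGZMB\tPRF1\tGZMB\nT\tsrc\tCD3D\tPRF1\n")
    return path
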