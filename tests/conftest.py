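import numpy as np
import pandas as pd
import pytest

from isodiff import generate_preset
from isodiff.tables import ABSOLUTE, PROPORTION, IsotopologueTable, SampleSheet


def make_iso_table(values: dict[str, list[float]], samples: list[str], mode: str):
    """Tiny isotopologue table from {metabolite: flat values per sample}."""
    rows = []
    index = []
    for met, vecs in values.items():
        n_iso = len(vecs[0])
        for i in range(n_iso):
            index.append((met, i))
            rows.append([vec[i] for vec in vecs])
    data = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index), columns=samples)
    return IsotopologueTable(data=data, mode=mode)


@pytest.fixture
def two_sample_sheet():
    frame = pd.DataFrame(
        {
            "sample_id": ["c1", "c2", "c3", "k1", "k2", "k3"],
            "condition": ["ctrl"] * 3 + ["ko"] * 3,
            "timepoint_name": ["T48"] * 6,
            "timepoint_hours": [48.0] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    ).set_index("sample_id")
    return SampleSheet(data=frame)


@pytest.fixture
def abs_table():
    # two metabolites (n=2 and n=3), two samples
    return make_iso_table(
        {
            "Ala": [[10.0, 30.0, 60.0], [20.0, 20.0, 60.0]],
            "Mal": [[5.0, 5.0, 5.0, 5.0], [1.0, 0.0, 0.0, 3.0]],
        },
        ["s1", "s2"],
        ABSOLUTE,
    )


@pytest.fixture
def prop_table():
    return make_iso_table(
        {
            "Ala": [[0.10, 0.30, 0.60], [0.20, 0.20, 0.60]],
            "Mal": [[0.25, 0.25, 0.25, 0.25], [0.25, 0.0, 0.0, 0.75]],
        },
        ["s1", "s2"],
        PROPORTION,
    )


@pytest.fixture(scope="session")
def ldh_dataset():
    dataset, truth = generate_preset("ldh_ko_48h", seed=11)
    return dataset, truth


@pytest.fixture(scope="session")
def timecourse_dataset():
    dataset, truth = generate_preset("timecourse_p3", seed=11)
    return dataset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
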