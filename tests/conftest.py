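import numpy as np
import pandas as pd
import pytest

import bioage as b

SEED = 1


@pytest.fixture(scope="session")
def preset_cohort():
    """The classical 13-marker synthetic cohort with its ground truth."""
    table, truth = b.generate(b.paper_like_preset(seed=SEED))
    return table, truth


@pytest.fixture()
def toy_table():
    """5 subjects, 2 biomarkers, no missing values."""
    idx = pd.Index([f"S{i}" for i in range(5)], name="subject")
    ca = pd.Series([20.0, 30.0, 40.0, 50.0, 60.0], index=idx)
    data = pd.DataFrame({
        "BM": [1.0, 3.0, 2.0, 5.0, 4.0],
        "LIN": [50.0, 70.0, 90.0, 110.0, 130.0],  # 10 + 2*CA
    }, index=idx)
    return b.CohortTable(data, ca)


def make_cohort(ca, columns):
    idx = pd.Index([f"S{i}" for i in range(len(ca))], name="subject")
    data = pd.DataFrame({k: np.asarray(v, float) for k, v in columns.items()}, index=idx)
    return b.CohortTable(data, pd.Series(np.asarray(ca, float), index=idx))
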