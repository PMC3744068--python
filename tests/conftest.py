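import logging

import numpy as np
import pandas as pd
import pytest

from anchorprio.io import ExpressionStudy, StudyEffectTable

logging.getLogger("anchorprio").setLevel(logging.ERROR)


@pytest.fixture
def tiny_study() -> ExpressionStudy:
    values = pd.DataFrame(
        [[2.0, 4.0, 5.0, 6.0],
         [1.0, 1.0, 3.0, 2.0],
         [0.0, 2.0, 1.0, 1.0]],
        index=["gA", "gB", "gC"],
        columns=["c1", "c2", "d1", "d2"],
    )
    groups = {"c1": "control", "c2": "control", "d1": "case", "d2": "case"}
    return ExpressionStudy("tiny", values, groups)


@pytest.fixture
def small_effect_table() -> StudyEffectTable:
    rows = []
    for study, (mean, p) in enumerate(zip([0.2, 0.4, 0.6], [0.01, 0.05, 0.2])):
        rows.append({"gene": "gA", "study_id": f"s{study}", "log2fc_mean": mean,
                     "se": 0.1, "presence_p": p})
    rows.append({"gene": "gB", "study_id": "s0", "log2fc_mean": 1.0,
                 "se": 0.1, "presence_p": 0.01})
    rows.append({"gene": "gB", "study_id": "s1", "log2fc_mean": 1.5,
                 "se": 0.1, "presence_p": 0.5})
    return StudyEffectTable(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
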