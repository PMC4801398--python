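import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

settings.register_profile(
    "vaxsig",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("vaxsig")


@pytest.fixture()
def toy_responses() -> pd.DataFrame:
    """Two experiments, each with its own rAd_1 reference group."""
    rows = []
    design = {
        "exp1": {"rAd_1": 4.0, "A": 2.0, "B": 0.4},
        "exp2": {"rAd_1": 8.0, "A": 4.0, "C": 0.8},
    }
    for exp, groups in design.items():
        for vec, peak in groups.items():
            for mouse in range(1, 4):
                for day, frac in ((5, 0.4), (7, 1.0), (10, 0.7)):
                    rows.append((exp, vec, f"{exp}.{vec}.m{mouse}", day, peak * frac))
    return pd.DataFrame(
        rows, columns=["experiment", "vector", "mouse", "day", "tetramer_pct"]
    )


@pytest.fixture()
def small_dataset():
    """Deterministic 12-gene, 3v3 dataset for ranking/bootstrapping."""
    from vaxsig.datasets import ExpressionDataset

    rng = np.random.default_rng(11)
    genes = [f"G{i:02d}" for i in range(12)]
    cols = ["c1", "c2", "c3", "v1", "v2", "v3"]
    values = pd.DataFrame(rng.normal(8.0, 1.0, (12, 6)), index=genes, columns=cols)
    values.loc[["G00", "G01", "G02"], ["v1", "v2", "v3"]] += 2.0
    groups = pd.Series(["control"] * 3 + ["vector"] * 3, index=cols)
    return ExpressionDataset(values=values, groups=groups, vector_id="toy")
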