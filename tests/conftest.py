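import numpy as np
import pandas as pd
import pytest

import estrofinger as ef


@pytest.fixture(scope="session")
def table1():
    """Packaged worked-example contrasts (E2, SH, SM) over the 44 probes."""
    e2, sh, sm = ef.table1_fixture()
    return {"E2": e2, "SH": sh, "SM": sm}


@pytest.fixture(scope="session")
def table1_ann():
    return ef.table1_annotation()


@pytest.fixture
def small_config():
    """Down-scaled simulation (fast) keeping the default effect structure."""
    return ef.SimulationConfig(n_probes=2000, seed=11)


@pytest.fixture
def small_experiment(small_config):
    return ef.generate_experiment(small_config)


def random_matrix(seed: int, n_probes: int = 5, groups=("C", "EM"), reps: int = 3):
    """Small ExpressionMatrix with i.i.d. Gaussian log2 intensities."""
    rng = np.random.default_rng(seed)
    sample_ids, meta = [], []
    for g in groups:
        for r in range(1, reps + 1):
            sid = f"{g}_{r}"
            sample_ids.append(sid)
            meta.append({"sample_id": sid, "group": g, "dose_mg_ml": np.nan, "replicate": r})
    values = pd.DataFrame(
        rng.normal(8, 1, size=(n_probes, len(sample_ids))),
        index=pd.Index([f"p{i}" for i in range(n_probes)], name="probe_id"),
        columns=sample_ids,
    )
    samples = pd.DataFrame(meta).set_index("sample_id")
    return ef.ExpressionMatrix(values, samples)
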