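import numpy as np
import pandas as pd
import pytest

import statelife as sl
from statelife.gompertz import TransitionModel


@pytest.fixture(scope="session")
def default_cfg():
    """Default generating process at a moderate size, shared across tests."""
    return sl.default_config(8000, seed=123)


@pytest.fixture(scope="session")
def default_sim(default_cfg):
    return sl.simulate_cohort(default_cfg)


@pytest.fixture(scope="session")
def constant_hazard_models():
    """All death intensities constant at 0.05/yr, up-moves negligible."""
    tiny = TransitionModel(0.0, 1e-30, {})
    dead = TransitionModel(0.0, 0.05, {})
    return {1: tiny, 3: tiny, 5: tiny, 2: dead, 4: dead, 6: dead, 7: dead}


def make_cohort(rows) -> pd.DataFrame:
    """Hand-built cohort table from (id, sex, q, entry, exit, reason, onsets)."""
    recs = []
    for r in rows:
        rec = {"id": r[0], "sex": r[1], "simd_quintile": r[2],
               "entry_age": r[3], "exit_age": r[4], "exit_reason": r[5]}
        for col, age in (r[6] if len(r) > 6 else {}).items():
            rec[f"onset_{col}"] = age
        recs.append(rec)
    df = pd.DataFrame(recs)
    for col in ("onset_retinopathy_maculopathy", "onset_cvd", "onset_ckd",
                "onset_diabetic_foot"):
        if col not in df:
            df[col] = np.nan
    return df
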