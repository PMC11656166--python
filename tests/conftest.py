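import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import corticolimbic as cl

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def atlas():
    return cl.default_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """Compact two-modality cohort for unit tests (fast to generate)."""
    cfg = cl.GeneratorConfig(n_cn=60, n_ad=60, seed=7)
    return cl.simulate_study(config=cfg)


def make_tiny_atlas():
    """Five-region toy atlas: hippocampus, two association regions, one other, one reference."""
    df = pd.DataFrame({
        "region_id": ["hip", "ctx_a", "ctx_b", "sub", "ref"],
        "region_name": ["hippocampus", "cortex a", "cortex b", "subcortex", "reference"],
        "hemisphere_scope": ["bilateral-merged"] * 5,
        "tissue_class": ["subcortical", "cortical", "cortical", "subcortical", "subcortical"],
        "pattern_class": ["limbic", "cortical-association", "cortical-association",
                          "other", "other"],
        "is_hippocampus": [True, False, False, False, False],
        "is_reference": [False, False, False, False, True],
    })
    return cl.RoiAtlas(df)


@pytest.fixture
def tiny_atlas():
    return make_tiny_atlas()


def make_matrix(values, regions, modality="MRI", units="mm^3", state="raw", prefix="S"):
    arr = np.asarray(values, float)
    ids = [f"{prefix}{i}" for i in range(arr.shape[0])]
    return cl.RoiMatrix(modality, units, state,
                        pd.DataFrame(arr, index=ids, columns=regions))


def make_meta(n, icv=None, age=None, diagnosis="CN", prefix="S", seed=0):
    rng = np.random.default_rng(seed)
    icv = np.full(n, 1.5e6) if icv is None else np.asarray(icv, float)
    age = rng.uniform(65, 85, n) if age is None else np.asarray(age, float)
    df = pd.DataFrame({
        "subject_id": [f"{prefix}{i}" for i in range(n)],
        "diagnosis": diagnosis,
        "age": age,
        "sex": np.where(rng.random(n) < 0.5, "F", "M"),
        "education": rng.uniform(10, 20, n),
        "apoe4_carrier": rng.random(n) < 0.4,
        "icv": icv,
        "amyloid_status": "negative" if diagnosis == "CN" else "positive",
    })
    return cl.SubjectMeta(df)
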