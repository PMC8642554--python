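import numpy as np
import pandas as pd
import pytest

from subtypegan import gan, preprocess, synthetic
from subtypegan.io import ROI_PREFIX, ROITable


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-subject separable cohort on the default 145-ROI atlas."""
    return synthetic.SyntheticCohortSpec(
        n_cn=150,
        n_pt_per_subtype=(70, 70, 70),
        a_min=0.2,
        a_max=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return synthetic.generate_cross_sectional(small_spec)


@pytest.fixture(scope="session")
def small_prepared(small_cohort):
    table, gt = small_cohort
    prepared, cov, norm = preprocess.preprocess(table)
    return prepared, gt


@pytest.fixture(scope="session")
def quick_hp():
    """Tiny budget for API-level tests that make no quality claims."""
    return gan.HyperParams(M=3, max_iters=250, plateau_window=50, seed=3, max_restarts=1)


@pytest.fixture(scope="session")
def trained_small(small_prepared):
    """One adequately trained model on the compact cohort (session-wide)."""
    prepared, gt = small_prepared
    cn = prepared.select_diagnosis("CN")
    pt = prepared.select_diagnosis("MCI", "Dementia")
    # two D steps per generator step: the conservative setting, sturdier on
    # this reduced-subject cohort than the faster default
    hp = gan.HyperParams(M=3, max_iters=4000, d_steps=2, lr_d=5e-4, seed=5, max_restarts=2)
    model = gan.train(cn, pt, hp)
    return model, cn, pt, gt


def make_cn_table(n=50, n_rois=3, seed=0, age=None, sex=None, values=None):
    """Hand-rolled CN table for preprocessing tests."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(55, 85, n) if age is None else np.asarray(age, dtype=float)
    sex = (np.arange(n) % 2).astype(float) if sex is None else np.asarray(sex, dtype=float)
    if values is None:
        values = rng.normal(10.0, 1.0, size=(n, n_rois))
    df = pd.DataFrame(
        {
            "participant_id": [f"s{i}" for i in range(n)],
            "visit_time": 0.0,
            "diagnosis": "CN",
            "age": age,
            "sex": sex,
        }
    )
    for j in range(values.shape[1]):
        df[f"{ROI_PREFIX}{j:03d}"] = values[:, j]
    return ROITable(df)
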