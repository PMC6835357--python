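import numpy as np
import pandas as pd
import pytest

from dietmet import FeatureTable, SimulationSpec, generate_study


def noise_free_spec(**overrides) -> SimulationSpec:
    """All random components off: planted fold changes appear exactly."""
    base = dict(
        technical_cv=0.0, is_technical_cv=0.0, creatinine_technical_cv=0.0,
        biological_cv_plasma=0.0, biological_cv_urine=0.0,
        within_subject_cv=0.0, response_sd=0.0, efficiency_cv=0.0,
        dilution_cv=0.0, drift_per_injection=0.0, lod_quantile=0.0,
        nonadherent_fraction=0.0, n_cross_fluid_pairs=0, seed=0,
    )
    base.update(overrides)
    return SimulationSpec(**base)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic cohort shared by read-only tests."""
    return generate_study(SimulationSpec(seed=11))


@pytest.fixture()
def small_table() -> FeatureTable:
    """3 features x 4 samples (2 participants x 2 timepoints), one missing."""
    cols = ["P1_base", "P1_wk2", "P2_base", "P2_wk2"]
    resp = pd.DataFrame(
        [[4.0, 8.0, 2.0, 2.0],
         [1.0, np.nan, 3.0, 4.0],
         [10.0, 10.0, 10.0, 10.0]],
        index=pd.Index(["f1", "f2", "f3"], name="feature_id"), columns=cols,
    )
    samples = pd.DataFrame({
        "participant_id": ["P1", "P1", "P2", "P2"],
        "arm": ["W-P", "W-P", "P-W", "P-W"],
        "timepoint": ["baseline", "week2", "baseline", "week2"],
        "matrix": ["plasma"] * 4,
        "age": [30, 30, 40, 40], "sex": ["F", "F", "M", "M"],
        "bmi": [24.0, 24.0, 28.0, 28.0],
        "run_id": ["r1"] * 4, "injection_position": [1, 2, 3, 4],
        "is_qc": [False] * 4,
    }, index=pd.Index(cols, name="sample_id"))
    features = pd.DataFrame({
        "name": ["a", "b", "c"], "mz": [100.0, 200.0, 300.0],
        "rmt": [0.5, 1.0, 1.5], "ion_mode": ["+", "-", "+"],
        "platform": ["MSI-CE-MS"] * 3, "id_level": [1, 2, 3],
    }, index=resp.index)
    return FeatureTable(resp, features, samples)
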