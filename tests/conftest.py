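import numpy as np
import pytest

from mvcnn3d import NoduleStack, SyntheticConfig, ViewSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_view_spec():
    """Downscaled views to keep unit tests light."""
    return ViewSpec(crop_sizes=(8, 10, 12), target_shape=(6, 12, 12))


@pytest.fixture
def tiny_stack(rng):
    slices = [rng.normal(size=(32, 32)).astype(np.float32) for _ in range(7)]
    return NoduleStack(
        patient_id="P0001",
        nodule_id="P0001-N000",
        slices=slices,
        center=(16, 16),
        nodule_diag=1,
        patient_diag=1,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort spanning all three classes."""
    cfg = SyntheticConfig(
        n_patients={"benign": 4, "primary": 3, "metastatic": 3},
        nodules_per_patient={"benign": 2.0, "primary": 2.0, "metastatic": 2.0},
        seed=7,
    )
    return generate_cohort(cfg)
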