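import hypothesis
import numpy as np
import pytest

from smoothnet import CohortSpec, generate_cohort, generate_parcellation
from smoothnet.pipeline import SweepConfig, run_sweep

hypothesis.settings.register_profile(
    "repro", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("repro")


@pytest.fixture(scope="session")
def parc96():
    """Default 96-ROI two-hemisphere parcellation on a 20x20x10 grid."""
    return generate_parcellation((20, 20, 10), 96, 1.0, seed=0)


@pytest.fixture(scope="session")
def small_parc():
    """8 ROIs on an 8x8x4 grid, equal target sizes."""
    return generate_parcellation((8, 8, 4), 8, 0.0, seed=0)


@pytest.fixture(scope="session")
def noise_free_subject(small_parc):
    """Single noise-free subject: voxel series equal their ROI latents."""
    spec = CohortSpec(
        n_subjects=1,
        n_timepoints=120,
        voxel_noise_sd=0.0,
        subject_variation_sd=0.0,
        seed=7,
    )
    return generate_cohort(small_parc, spec)[0]


@pytest.fixture(scope="session")
def sweep_report(parc96):
    """Full 13-subject default sweep (FWHM 0/5/8/12 mm), seed 0."""
    cfg = SweepConfig(seed=0)
    cohort = generate_cohort(parc96, CohortSpec(seed=0))
    return run_sweep(cfg, parcellation=parc96, cohort=cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
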