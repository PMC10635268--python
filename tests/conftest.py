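import numpy as np
import pytest

from cuesync.simulate import SimConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete two-group, two-session synthetic study."""
    cfg = SimConfig(
        n_subjects_per_group=(6, 5),
        n_rois=6,
        voxels_per_roi=8,
        n_unassigned_voxels=40,
        n_trs=160,
        n_drop=10,
        drug_locked_rois=(0, 1),
        ofc_rois=(2, 3),
        seed=7,
    )
    return simulate_study(cfg)
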