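import numpy as np
import pytest

from physioeval.synthgen import make_bold_study, make_network_atlas


@pytest.fixture(scope="session")
def atlas_small():
    return make_network_atlas((14, 14, 7), n_networks=7, seed=0)


@pytest.fixture(scope="session")
def sim_runs(atlas_small):
    """Two subjects x one run of the long-TR condition, with recordings."""
    return make_bold_study(atlas_small, n_subjects=2, n_runs=1, tr=2.0,
                           n_frames=240, seed=3)


@pytest.fixture(scope="session")
def sim_run(sim_runs):
    return sim_runs[0]
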