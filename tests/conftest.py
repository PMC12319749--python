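import warnings

import numpy as np
import pytest

from caudconn import studies, synthgen

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def atlas():
    return synthgen.make_toy_atlas()


@pytest.fixture(scope="session")
def profile(atlas):
    return synthgen.default_coupling_profile(atlas)


@pytest.fixture(scope="session")
def noiseless_profile(atlas):
    return synthgen.default_coupling_profile(atlas).noiseless()


@pytest.fixture(scope="session")
def subjects():
    return synthgen.generate_subject_table(n=12, seed=1234)


@pytest.fixture(scope="session")
def noiseless_rest(atlas, noiseless_profile, subjects):
    subj = subjects.iloc[0]
    run, motion, truth = synthgen.generate_rest_bold(
        subj, atlas, noiseless_profile, seed=42
    )
    return subj, run, motion, truth


@pytest.fixture(scope="session")
def toy_rois(atlas):
    return studies.toy_roi_voxels(atlas)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
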