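import numpy as np
import pytest

from figmem.rpcm import fit_person_only, fit_rpcm, fit_rpcm_r
from figmem.simulation import synthesize_study


@pytest.fixture(scope="session")
def study_data():
    """One synthetic pilot-study dataset (208 x 9, grouped, censored at 20)."""
    return synthesize_study(7)


@pytest.fixture(scope="session")
def study_fits(study_data):
    """Person-only, RPCM and RPCM-r fits on the shared synthetic study."""
    return {
        "person_only": fit_person_only(study_data),
        "rpcm": fit_rpcm(study_data),
        "rpcm_r": fit_rpcm_r(study_data),
    }


@pytest.fixture(scope="session")
def tiny_data():
    """A 6-person x 3-item matrix small enough for brute-force oracles."""
    from figmem.data import ResponseMatrix

    rng = np.random.default_rng(42)
    scores = rng.poisson([9.0, 7.0, 5.0], size=(6, 3))
    return ResponseMatrix(
        scores=np.minimum(scores, 20),
        radical_levels=[1, 2, 3],
        incidental_ids=[1, 1, 1],
    )
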