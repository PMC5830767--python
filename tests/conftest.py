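import warnings

import numpy as np
import pytest

from membranekit.synthetic import (DispersionSpec, MembraneSpec,
                                   build_membrane_frames,
                                   simulate_constant_q_scan)


@pytest.fixture(autouse=True)
def _quiet_mdanalysis():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="MDAnalysis")
        yield


@pytest.fixture(scope="session")
def three_mode_scan():
    """One noisy constant-q scan from the default three-branch dispersion."""
    return simulate_constant_q_scan(DispersionSpec.well_separated(),
                                    q=1.4, seed=1)


@pytest.fixture(scope="session")
def plain_membrane_frame():
    """Pure-DMPC frame at the default target area."""
    return build_membrane_frames(MembraneSpec(jitter=0.05), 1, seed=2)[0]


@pytest.fixture(scope="session")
def asa_membrane_frames():
    """Frames with cholesterol rings and an aspirin superlattice."""
    spec = MembraneSpec(n_lipids=512, chol_fraction=0.2, asa_fraction=0.08)
    return build_membrane_frames(spec, 2, seed=5)


def poisson_errors(counts):
    return np.maximum(1.0, np.sqrt(counts))
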