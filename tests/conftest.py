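import numpy as np
import pytest

import myelinmap as mm


@pytest.fixture(scope="session")
def ico3():
    return mm.build_mesh("icosphere", 3)


@pytest.fixture(scope="session")
def ico3_atlas(ico3):
    return mm.build_atlas(ico3)


@pytest.fixture(scope="session")
def planar():
    # 12x12-vertex unit-spacing patch
    return mm.build_mesh("planar_patch", 10)


@pytest.fixture(scope="session")
def small_phantom(ico3, ico3_atlas):
    """One subject's ground truth plus a noiseless and a noisy session."""
    pop = mm.PopulationParams()
    curv = mm.synthetic_curvature(ico3, seed=11)
    gt = mm.sample_ground_truth(ico3, ico3_atlas, pop, subject_seed=5,
                                curvature=curv)
    acq = mm.AcquisitionSpec()
    quiet = mm.AcquisitionSpec(noise_sd_gre=0.0, noise_sd_t1=0.0)
    return {
        "mesh": ico3, "atlas": ico3_atlas, "population": pop,
        "curvature": curv, "gt": gt, "acq": acq,
        "session": mm.simulate_session(gt, acq, session_seed=7),
        "noiseless": mm.simulate_session(gt, quiet, session_seed=7),
    }


@pytest.fixture(scope="session")
def default_bundle():
    """Full default-design experiment (10 subjects, 3 rescans, icosphere 4)."""
    return mm.run_experiment(seed=1)
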