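import numpy as np
import pytest

from septatrack.loc3d import calibrate_astigmatism
from septatrack.simcell import AstigmatismModel, SimParams, simulate_bead_stack


@pytest.fixture(scope="session")
def psf_model():
    return AstigmatismModel()


@pytest.fixture(scope="session")
def bead_calib(psf_model):
    """Noiseless bead calibration over +/-600 nm."""
    table = simulate_bead_stack(sigma_model=psf_model)
    return calibrate_astigmatism(table)


@pytest.fixture()
def clean_slow_params():
    """One slow molecule at a deterministic speed, no observation noise."""
    return SimParams(n_molecules=1, population_fractions=(0.0, 1.0, 0.0),
                     slow_speed_logparams=(np.log(9.0), 0.0),
                     loc_noise_xy=0.0, loc_noise_z=0.0, detection_prob=1.0,
                     blink_off_mean=0.0, run_time_mean=60.0, seed=11)
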