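import numpy as np
import pytest

import perfusekit as pk


@pytest.fixture(scope="session")
def gamma_params():
    """Bolus solved for the study calibration: 8 mg/mL peak, 10 s FWHM."""
    return pk.solve_gamma_params(peak=8.0, fwhm=10.0, t0=3.0)


@pytest.fixture(scope="session")
def acq_times():
    """36 ECG-triggered time points spanning ~26.9 s."""
    return pk.ecg_triggered_times(36, 26.9 / 35.0, 0.05, seed=7)


@pytest.fixture(scope="session")
def aif(gamma_params, acq_times):
    return pk.gamma_variate_aif(gamma_params, acq_times)


@pytest.fixture(scope="session")
def small_phantom():
    """Down-scaled phantom (160 voxels/region) for fast multi-seed runs."""
    return pk.PhantomConfig(
        shape=(1, 40, 28), myo_row_start=2, band_rows=8,
        col_start=4, col_stop=24,
        blood_pool_row_start=30, blood_pool_rows=8,
    )


@pytest.fixture(scope="session")
def full_phantom():
    """Full calibration: >=500 voxels per tissue region."""
    return pk.PhantomConfig()


@pytest.fixture(scope="session")
def noiseless_sim(small_phantom):
    return pk.simulate_series(small_phantom, "iodine_density", seed=11,
                              noise=False)
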