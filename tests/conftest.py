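import numpy as np
import pytest

from spikecal.synthetic_data import SimConfig, render_movie, simulate_ap_train


@pytest.fixture(scope="session")
def small_recording():
    """A modest paired recording with active neuropil, shared across tests."""
    cfg = SimConfig(seed=11, duration_s=60.0, fov_px=(32, 32), soma_radius_px=6,
                    indicator="6f", firing_rate=2.0, neuropil_amp=0.3,
                    neuropil_rate=8.0, r_true=0.8, baseline_photons=20.0,
                    neuropil_ring_px=(2, 8))
    aps = simulate_ap_train(cfg)
    return render_movie(aps, cfg)


@pytest.fixture(scope="session")
def quiet_movie():
    """A 1000-frame signal-free movie for photon-statistics tests."""
    cfg = SimConfig(seed=7, duration_s=1000 / 158.0, fov_px=(32, 32),
                    soma_radius_px=6, firing_rate=0.0, neuropil_amp=0.0,
                    photon_gain=2.0, pedestal=100.0, baseline_photons=50.0)
    return render_movie(np.array([]), cfg)
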