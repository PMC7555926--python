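import numpy as np
import pytest

from axotrace import default_parameters
from axotrace.protocols import ProtocolLattices, ThresholdTracker

#: control-group excitability index targets (group mean, SEM)
CHOW_INDICES = {
    "ted_10_20": (37.48, 0.81),
    "resting_iv_slope": (1.04, 0.03),
    "refractoriness_2p5": (6.20, 1.63),
    "superexcitability_5": (-0.65, 0.68),
    "subexcitability": (8.16, 0.69),
}

#: cafeteria-diet group excitability index targets (group mean, SEM)
CAF_INDICES = {
    "ted_10_20": (36.01, 0.95),
    "resting_iv_slope": (1.06, 0.04),
    "refractoriness_2p5": (7.81, 1.24),
    "superexcitability_5": (2.14, 0.83),
    "subexcitability": (8.00, 0.96),
}

#: calibration free parameters (membrane conductances + pump current)
CALIBRATION_FREE = ("G_NaT", "f_NaP", "G_Ks_n", "G_Ks_i", "G_Kf_i", "G_H",
                    "G_BB", "G_Lk_i", "I_pump")

#: reduced stimulus lattices for fitting-speed-sensitive tests
SMALL_LATTICES = ProtocolLattices(
    sd_durations=(0.2, 0.6, 1.0),
    te_levels=(40.0, -40.0),
    te_delays=(10.0, 13.0, 16.0, 20.0, 60.0, 110.0),
    iv_levels=(40.0, 10.0, -10.0, -40.0),
    rc_isis=(2.5, 3.5, 5.0, 7.0, 10.0, 18.0, 32.0, 56.0, 100.0, 200.0),
)


#: tracker options for fitting-grade tests (fine bisection)
SMALL_OPTS = {"lattices": SMALL_LATTICES, "bracket_rtol": 7e-4}


@pytest.fixture(scope="session")
def default_params():
    return default_parameters()


@pytest.fixture(scope="session")
def tracker(default_params):
    return ThresholdTracker(default_params)


@pytest.fixture(scope="session")
def small_tracker(default_params):
    return ThresholdTracker(default_params, lattices=SMALL_LATTICES)


@pytest.fixture(scope="session")
def calibrated_params(default_params):
    """Baseline calibrated to the control-group indices (shared, seeded)."""
    from axotrace.fitting import calibrate_baseline

    targets = {k: v[0] for k, v in CHOW_INDICES.items()}
    scales = {k: v[1] for k, v in CHOW_INDICES.items()}
    fitted, res = calibrate_baseline(
        targets, CALIBRATION_FREE, seed=1, scales=scales, n_restarts=2,
        maxfev=400, tracker_opts={"bracket_rtol": 7e-4})
    return fitted
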