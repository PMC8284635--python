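import numpy as np
import pytest

from accelbird import (
    CalibrationProfile,
    TagKind,
    calibrate,
    classify,
    synth_accel,
)
from accelbird.synth import GeneratorConfig, standard_foraging_script


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def two_hour_run(gen_config):
    """One standard two-hour synthetic deployment, calibrated and classified.

    Session-scoped: several test modules probe different aspects of the same
    record (truth ethogram, calibration profile, classification result).
    """
    script = standard_foraging_script(7200, seed=11, config=gen_config)
    series, truth = synth_accel(script, gen_config)
    profile = calibrate(series)
    result = classify(series, profile)
    return {
        "series": series,
        "truth": truth,
        "profile": profile,
        "result": result,
    }


@pytest.fixture
def simple_profile() -> CalibrationProfile:
    """A hand-set profile for unit tests of individual classification rules."""
    return CalibrationProfile(
        pfm_windows=[(0.0, 60.0)],
        flap_threshold_g=0.4,
        large_pitch_change_deg=15.0,
        pfm_pitch_min_med_deg=-20.0,
        pfm_pitch_mean_med_deg=0.0,
        pfm_pitch_var_med_deg2=5.0,
        tag_kind=TagKind.chest_mounted,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
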