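"""Shared fixtures: a calibrated detector pair and the 30+30 gesture
benchmark, generated once per session from a single seed."""

import numpy as np
import pytest
from hypothesis import settings

from facetouch import bounds_for, detect_streams, make_benchmark
from facetouch.imudetect import ImuDetector
from facetouch.magdetect import MagDetector
from facetouch.simkit import (
    NecklaceModel,
    SimConfig,
    calibration_scripts,
    generate_stream,
    rest_script,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def necklace():
    return NecklaceModel()


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def right_bounds():
    return bounds_for("right")


@pytest.fixture(scope="session")
def calibration_streams(necklace, sim_config):
    """Phase-1 (arm far), phase-2 (approach to 20 cm) and still-arm
    calibration recordings, all drawn from the session seed."""
    rng = np.random.default_rng(sim_config.seed)
    phase1, phase2 = calibration_scripts()
    return {
        "phase1": generate_stream(phase1, necklace, sim_config, rng=rng),
        "phase2": generate_stream(phase2, necklace, sim_config, rng=rng),
        "rest": generate_stream(rest_script(), necklace, sim_config, rng=rng),
    }


@pytest.fixture(scope="session")
def mag_detector(right_bounds, calibration_streams):
    det = MagDetector(right_bounds)
    det.calibrate_phase1(calibration_streams["phase1"].data)
    det.calibrate_phase2(calibration_streams["phase2"].data)
    return det


@pytest.fixture(scope="session")
def imu_detector(right_bounds, calibration_streams):
    det = ImuDetector(right_bounds)
    det.calibrate(calibration_streams["rest"].data)
    return det


@pytest.fixture(scope="session")
def benchmark(necklace, sim_config):
    """The 30 face-touch + 30 ADL in-silico protocol."""
    return make_benchmark(30, 30, necklace, sim_config)


@pytest.fixture(scope="session")
def benchmark_results(benchmark, mag_detector, imu_detector):
    return {
        "mag": detect_streams(mag_detector, benchmark),
        "imu": detect_streams(imu_detector, benchmark),
    }
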