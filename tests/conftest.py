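import numpy as np
import pytest

from lcphantom.config import StudyConfig
from lcphantom.geometry import build_cdrad_column, build_plate_a, build_plate_b
from lcphantom.materials import get_material
from lcphantom.simulate import AcquisitionConfig, DetectorModel, simulate_frame
from lcphantom.spectrum import DEFAULT_BEAMS


@pytest.fixture(scope="session")
def plate_a():
    return build_plate_a()


@pytest.fixture(scope="session")
def plate_b():
    return build_plate_b()


@pytest.fixture(scope="session")
def cdrad():
    return build_cdrad_column()


@pytest.fixture(scope="session")
def pmma():
    return get_material("pmma")


@pytest.fixture(scope="session")
def q1():
    return DEFAULT_BEAMS["Q1"]


@pytest.fixture(scope="session")
def default_detector():
    return DetectorModel()


@pytest.fixture(scope="session")
def q1_frame(plate_a, default_detector):
    """One default Q1 frame of the central LC module (seeded)."""
    acq = AcquisitionConfig(DEFAULT_BEAMS["Q1"], air_kerma_rate=73.0, seed=11)
    return simulate_frame(plate_a, default_detector, acq)


@pytest.fixture()
def study_config(tmp_path):
    return StudyConfig(master_seed=3, output_dir=str(tmp_path / "out"))
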