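import numpy as np
import pytest

from mulchdeg import film_quant, io_cli


@pytest.fixture(scope="session")
def fixtures():
    return io_cli.load_fixtures()


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


@pytest.fixture
def sim_calibration():
    # matches the synthetic film generator's default gray levels
    return film_quant.GrayCalibration(gray_fresh=30.0, gray_background=200.0)
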