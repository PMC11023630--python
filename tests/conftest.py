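import numpy as np
import pytest

from drivecage.genetics import DriveParams


@pytest.fixture
def study_params() -> DriveParams:
    """Drive performance rates measured in the study's two-generation crosses."""
    return DriveParams(c_f=0.076, c_m=0.146)  # r defaults to c/2 per sex


@pytest.fixture
def mendelian_params() -> DriveParams:
    """No conversion, no resistance, no fitness cost: plain Mendelian locus."""
    return DriveParams(c_f=0.0, c_m=0.0, r_f=0.0, r_m=0.0, f_het=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240405)
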