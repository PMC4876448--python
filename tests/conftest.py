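import numpy as np
import pytest

from snoreforge import SubjectAnatomy, derive_geometry

FS = 12500.0


@pytest.fixture
def mean_subject() -> SubjectAnatomy:
    """Cohort-mean anatomy with paired after-sleep measurements."""
    return SubjectAnatomy(
        subject_id="mean",
        nc=41.8,
        ua_xsa=2.6,
        ua_length=9.1,
        nc_after=42.3,
        ua_xsa_after=2.2,
        ahi=27.6,
        pitch_hz=102.1,
    )


@pytest.fixture
def mean_geometry(mean_subject):
    return derive_geometry(mean_subject)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
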