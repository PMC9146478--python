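import numpy as np
import pytest

from vagdx.cohort import generate_recording
from vagdx.types import Chain, GeneratorConfig, Group, Sex, SubjectProfile


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Short recordings (3 cycles) for unit-level pipeline tests."""
    return GeneratorConfig(n_hc=6, n_oa=8, n_cycles=3, seed=3)


@pytest.fixture(scope="session")
def oa_subject() -> SubjectProfile:
    return SubjectProfile(subject_id="OA900", group=Group.OA, icrs_grade=3,
                          age=58.0, sex=Sex.M, height=1.70, weight=88.0,
                          bmi=88.0 / 1.70**2)


@pytest.fixture(scope="session")
def hc_subject() -> SubjectProfile:
    return SubjectProfile(subject_id="HC900", group=Group.HC, icrs_grade=0,
                          age=25.0, sex=Sex.F, height=1.68, weight=60.0,
                          bmi=60.0 / 1.68**2)


@pytest.fixture(scope="session")
def oa_recording(oa_subject, small_config):
    return generate_recording(oa_subject, Chain.OKC, small_config, seed=11)


@pytest.fixture(scope="session")
def two_tone():
    """5 Hz + 50 Hz mixture at the acquisition rate; EMD should split it."""
    fs = 1400.0
    t = np.arange(int(3 * fs)) / fs
    lo = np.sin(2 * np.pi * 5.0 * t)
    hi = 0.6 * np.sin(2 * np.pi * 50.0 * t)
    return t, lo, hi, lo + hi
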