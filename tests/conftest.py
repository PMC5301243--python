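import logging

import numpy as np
import pytest

from cardioraman.io import SpectrumRecord
from cardioraman.synth import SynthConfig


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    # validation warnings are expected in many small fixtures
    logging.getLogger("cardioraman").setLevel(logging.ERROR)
    yield


@pytest.fixture
def cfg():
    return SynthConfig()


@pytest.fixture
def tiny_cfg():
    """A 1/1/1-heart, single-point cohort for fast file-tree tests."""
    from cardioraman.synth import CohortParams
    return SynthConfig(cohort=CohortParams(
        group_sizes={"control": 1, "SI": 1, "IPC": 1}, points_per_time=1))


def lorentzian(wn, center, fwhm, amplitude=1.0):
    return amplitude / (1.0 + ((np.asarray(wn) - center) / (fwhm / 2.0)) ** 2)


@pytest.fixture
def make_spectrum():
    """Factory for background-subtracted test spectra on a 600-1800 grid."""
    def _make(intensities=None, func=None, subtracted=True, **meta):
        wn = np.arange(600.0, 1801.0, 1.0)
        if intensities is None:
            intensities = func(wn) if func else np.zeros_like(wn)
        return SpectrumRecord(wn, np.asarray(intensities, dtype=float),
                              background_subtracted=subtracted, **meta)
    return _make
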