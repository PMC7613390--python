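import numpy as np
import pytest

from phenolai import (AcquisitionSchedule, DetectionConfig, lai_truth_curve,
                      nile_delta_calendar, parcel_truth, sample_series)


@pytest.fixture(scope="session")
def calendar():
    return nile_delta_calendar()


@pytest.fixture(scope="session")
def rice_truth(calendar):
    """One clean rice season in 2016 (no parameter jitter)."""
    return lai_truth_curve("rice", 2016, calendar)


@pytest.fixture(scope="session")
def double_crop_truth(calendar):
    """Two years of rice/wheat double cropping, deterministic parameters."""
    return parcel_truth([(2016, "rice"), (2016, "wheat"),
                         (2017, "rice"), (2017, "wheat")], calendar, 2016)


@pytest.fixture(scope="session")
def double_crop_series(double_crop_truth):
    """Noise-free 10-day sampling of the double-cropping truth."""
    sched = AcquisitionSchedule("S2", 10.0, jitter=0.0, end=1095.0)
    return sample_series(double_crop_truth, sched, noise_sd=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cfg():
    return DetectionConfig()
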