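import numpy as np
import pytest

from eoscluster import PatientRecord


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_record(
    subject_id="S1",
    etiology="congenital",
    age=5.0,
    cobb_major=80.0,
    kyphosis=40.0,
    levels_cobb=6.0,
    levels_kyphosis=5.0,
):
    return PatientRecord(
        subject_id=subject_id,
        etiology=etiology,
        age=age,
        cobb_major=cobb_major,
        kyphosis=kyphosis,
        levels_cobb=levels_cobb,
        levels_kyphosis=levels_kyphosis,
    )


@pytest.fixture
def two_clouds(rng):
    """Two tight, well-separated point clouds in 6-d (centers +/-5, SD 0.3)."""
    a = rng.normal(-5.0, 0.3, size=(100, 6))
    b = rng.normal(5.0, 0.3, size=(100, 6))
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], 100)
    return X, labels
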