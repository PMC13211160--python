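import numpy as np
import pytest

from drivehull import AccelSeries


@pytest.fixture
def make_series():
    """Factory for AccelSeries on a uniform 10 Hz grid."""

    def _make(
        xyz,
        rate_hz: float = 10.0,
        device_role: str = "vehicle",
        participant_id: str = "T01",
    ) -> AccelSeries:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        t = np.arange(len(xyz)) / rate_hz
        return AccelSeries(
            device_role=device_role,
            participant_id=participant_id,
            sample_rate_hz=rate_hz,
            t=t,
            xyz=xyz,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
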