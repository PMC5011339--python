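import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # frame_factory is stateless; reuse across generated examples is safe
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def frame_factory():
    """Build small ComplexFrame objects with shared metadata."""
    from mrgfus.thermometry import ComplexFrame

    def make(data, timestamp_s=0.0, te_s=0.010, b0_T=4.7, fov_mm=(60.0, 60.0)):
        return ComplexFrame(
            data=np.asarray(data, dtype=complex),
            te_s=te_s,
            timestamp_s=timestamp_s,
            b0_T=b0_T,
            fov_mm=fov_mm,
        )

    return make
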