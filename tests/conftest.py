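import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cisquant import ColorTimeSeries, DatasetDesign, KineticParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_design() -> DatasetDesign:
    """Three well-separated levels, two replicates each, 30 s at 1 Hz."""
    return DatasetDesign(
        levels=((10.0, 2), (100.0, 2), (1000.0, 2)),
        duration_s=30.0,
        frame_rate_hz=1.0,
    )


@pytest.fixture
def noiseless_params() -> KineticParams:
    return KineticParams(noise_sd=0.0, replicate_amplitude_cv=0.0)


def make_series(
    values, tube_id="t0", interval=1.0, conc=None, channels=None
) -> ColorTimeSeries:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(values.shape[0]))
    return ColorTimeSeries(
        tube_id=tube_id,
        channel_names=tuple(channels),
        values=values,
        sampling_interval_s=interval,
        true_concentration=conc,
    )
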