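import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ttroi import FrameSeries

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def series_of(times, labels=None, duration_s=None, video_id="v", fps=30.0):
    """Shorthand FrameSeries constructor for tests."""
    times = np.sort(np.asarray(times, dtype=float))
    if labels is None:
        labels = ["cancer"] * times.size
    elif isinstance(labels, str):
        labels = [labels] * times.size
    if duration_s is None and times.size:
        duration_s = float(times.max()) + 1.0
    return FrameSeries(video_id, times, labels, duration_s=duration_s, fps=fps)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
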