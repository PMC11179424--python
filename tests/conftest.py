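import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cagtrace import PeakTable, SizeToRepeatMap

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def smap():
    """Default repeat map with zero intercept (bp = repeat * 2.724117)."""
    return SizeToRepeatMap()


@pytest.fixture
def make_table(smap):
    """Build a PeakTable from (repeat, height) pairs on the default map."""

    def _make(pairs, sample_id="s1", size_map=smap):
        repeats = np.array([r for r, _ in pairs], dtype=float)
        heights = np.array([h for _, h in pairs], dtype=float)
        return PeakTable(sample_id, np.asarray(size_map.repeat_to_bp(repeats)), heights)

    return _make


def random_peak_table(rng, sample_id="rnd", max_peaks=15):
    """Randomized peak table on the repeat grid with sub-repeat size jitter."""
    n = int(rng.integers(1, max_peaks + 1))
    repeats = rng.choice(np.arange(80, 160), size=n, replace=False)
    smap = SizeToRepeatMap()
    sizes = np.asarray(smap.repeat_to_bp(repeats)) + rng.uniform(-0.4, 0.4, size=n)
    heights = rng.uniform(10.0, 10000.0, size=n)
    return PeakTable(sample_id, sizes, heights)
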