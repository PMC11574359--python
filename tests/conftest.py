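import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from liponta import SizeDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dist(conc_by_centre: dict, bin_width: float = 5.0, **kw) -> SizeDistribution:
    """Build a SizeDistribution from a {centre: concentration} mapping."""
    centres = sorted(conc_by_centre)
    lo = round(centres[0] / bin_width - 0.5)
    hi = round(centres[-1] / bin_width - 0.5)
    grid = (np.arange(lo, hi + 1) + 0.5) * bin_width
    conc = np.array([conc_by_centre.get(float(c), 0.0) for c in grid], dtype=float)
    kw.setdefault("n_particles", int(conc.sum()))
    return SizeDistribution(bin_centres=grid, concentration=conc, bin_width=bin_width, **kw)


@pytest.fixture
def worked_dist():
    """The four-bin distribution used in the box-statistics worked example."""
    return make_dist({77.5: 1.0, 82.5: 4.0, 87.5: 1.0, 92.5: 3.0})
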