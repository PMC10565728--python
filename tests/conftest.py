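import pytest

from evodyn import (
    ModelParams,
    ScenarioConfig,
    Species,
)
from evodyn.scenarios import _run_single


@pytest.fixture
def params():
    """Baseline parameter set (Gaussian kernel, single-peak regime)."""
    return ModelParams()


@pytest.fixture
def radiation_params():
    """Niche-packing regime: bounded kernel, narrow competition."""
    return ModelParams(kernel="bounded", sigma_a2=2.0, extinction_threshold=0.0)


@pytest.fixture
def resident_at_equilibrium(params):
    """A lone slow evolver at its closed-form eco-evolutionary equilibrium."""
    return [Species(id="slow_0", k=0.2, u=0.0, x=96.0)]


@pytest.fixture(scope="session")
def radiation_equilibrium():
    """Fast + slow evolver equilibrated (no speciation) in the bounded,
    sigma_a2=2 regime: both lineages end on convergent-stable minima.

    Session-scoped because the run takes a moment and several tests probe
    the same community.
    """
    cfg = ScenarioConfig("adaptive_radiation", u0=0.5, t_end=4000.0)
    traj = _run_single(cfg)
    community = [s for s in traj.species if s.extant]
    assert len(community) == 2
    return community, cfg.resolved_params()


def finite_difference(f, v, h=1e-4):
    """Central-difference first and second derivatives of a scalar f."""
    d1 = (f(v + h) - f(v - h)) / (2.0 * h)
    d2 = (f(v + h) - 2.0 * f(v) + f(v - h)) / h**2
    return d1, d2
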