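import numpy as np
import pytest

from hotwalk import ArenaConfig, Trajectory, default_layout, default_phenotypes


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def phenotypes():
    return default_phenotypes()


@pytest.fixture(scope="session")
def arena():
    return ArenaConfig()


def make_traj(xy, t=None, rate=13.0, pid="P1", group="NC"):
    """Build a trajectory from an (n, 2) array (timestamps default to rate)."""
    xy = np.asarray(xy, dtype=float)
    if t is None:
        t = np.arange(len(xy)) / rate
    return Trajectory(pid, group, np.asarray(t, dtype=float), xy,
                      nominal_rate_hz=rate)


def random_walk(n, step=0.05, seed=0, start=(1.5, 2.0), rate=13.0, pid="P1"):
    """Planar Gaussian random walk used as a generic test input."""
    rng = np.random.default_rng(seed)
    xy = np.cumsum(rng.normal(scale=step, size=(n, 2)), axis=0) + start
    return make_traj(xy, rate=rate, pid=pid)
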