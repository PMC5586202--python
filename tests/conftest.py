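import numpy as np
import pytest

from sitefid import (
    GridSpec,
    NestGeometry,
    SiteSequence,
    Trajectory,
    make_grid,
)


@pytest.fixture(scope="session")
def geometry() -> NestGeometry:
    return NestGeometry(width=50.0, height=35.0, entrance_xy=(25.0, 0.0))


@pytest.fixture(scope="session")
def grid(geometry) -> GridSpec:
    return make_grid(geometry, 3.0)


def make_trajectory(
    coords,
    colony="C01",
    ant="A1",
    caste="worker",
    tick_minutes=10.0,
) -> Trajectory:
    """Build a trajectory from a list of (x, y) or None (missing fix)."""
    x = np.array([np.nan if c is None else c[0] for c in coords], dtype=float)
    y = np.array([np.nan if c is None else c[1] for c in coords], dtype=float)
    return Trajectory(
        colony_id=colony,
        ant_id=ant,
        caste=caste,
        ticks=np.arange(len(coords)),
        x=x,
        y=y,
        tick_minutes=tick_minutes,
    )


def make_site_sequence(sites, grid, ant="A1", tick_minutes=10.0) -> SiteSequence:
    """Site sequence straight from integer codes (-1 = missing)."""
    sites = np.asarray(sites, dtype=int)
    return SiteSequence(
        colony_id="C01",
        ant_id=ant,
        caste="worker",
        ticks=np.arange(len(sites)),
        sites=sites,
        grid=grid,
        tick_minutes=tick_minutes,
    )
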