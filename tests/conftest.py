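import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ccm

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


D = dt.date  # shorthand for hand-built records


def record(date, species, x, y, dbh=30.0, lifeform="tree", group="G"):
    return ccm.FeedingRecord(
        date=date, group_id=group, species=species, x=x, y=y, dbh=dbh, lifeform=lifeform
    )


@pytest.fixture
def grid50():
    return ccm.GridSpec(cell_size=50.0)


@pytest.fixture
def toy_occupancy(grid50):
    """5 records / 3 species / 4 distinct cells, with one within-cell repeat."""
    recs = [
        record(D(2020, 1, 1), "A", 10, 10),
        record(D(2020, 1, 2), "A", 60, 10),
        record(D(2020, 1, 3), "B", 10, 60),
        record(D(2020, 1, 1), "B", 12, 62),
        record(D(2020, 1, 4), "C", 60, 60),
    ]
    return ccm.rasterize_records(recs, grid50)


@pytest.fixture
def toy_inventory():
    """4 plots, a handful of stems with DBH straddling the size minima."""
    plots = pd.DataFrame(
        dict(plot_id=["p1", "p2", "p3", "p4"], x=[25, 75, 125, 175], y=[25, 25, 25, 25])
    )
    stems = pd.DataFrame(
        dict(
            plot_id=["p1", "p1", "p2", "p3", "p3", "p4", "p4"],
            species=["A", "B", "A", "A", "C", "B", "C"],
            dbh_cm=[25.0, 6.0, 19.0, 40.0, 12.0, 30.0, 4.0],
            lifeform=["tree", "liana", "tree", "tree", "tree", "tree", "liana"],
        )
    )
    return ccm.PlotInventory(plots=plots, stems=stems)


@pytest.fixture(scope="session")
def scenario():
    """A moderately sized synthetic study shared across tests.

    20 species, 250 days, 4 x 4 km landscape with a ~9 km² 95% home
    range — small enough to run in under a second, large enough for the
    rank/recovery properties to hold comfortably.
    """
    cfg = ccm.default_scenario(n_species=20, n_days=250, window=(0.0, 0.0, 4000.0, 4000.0))
    cfg.forager = ccm.ForagerSpec(center=(2000.0, 2000.0), spread=(700.0, 700.0))
    return ccm.recovery_experiment(cfg, seed=7)


@pytest.fixture(scope="session")
def gaussian_ud():
    """Analytic symmetric bivariate Gaussian UD on a 25 m raster (sigma 500 m)."""
    from ccm.homerange import UtilizationDistribution

    res, sig, half = 25.0, 500.0, 3000.0
    g = np.arange(-half, half, res) + res / 2
    X, Y = np.meshgrid(g, g)
    dens = np.exp(-(X**2 + Y**2) / (2 * sig**2))
    ud = UtilizationDistribution(
        density=dens, xmin=-half, ymin=-half, resolution=res, bandwidth=sig
    )
    ud.sigma = sig
    return ud
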