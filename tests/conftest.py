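import logging

import numpy as np
import pandas as pd
import pytest

from puptrack.bathymetry import BathymetryConfig, make_bathymetry
from puptrack.simulate import CohortParams, simulate_study
from puptrack.trips import ColonyGeometry

logging.getLogger("puptrack").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bathy():
    return make_bathymetry(BathymetryConfig(), seed=1)


@pytest.fixture(scope="session")
def colony():
    return ColonyGeometry()


@pytest.fixture(scope="session")
def small_study(bathy):
    """A 6-pup synthetic study shared across tests (deterministic)."""
    return simulate_study(bathy, CohortParams(n_pups=6), seed=42)


def make_fixes(times_h, lons, lats, n_sat=9, residual=1.0, animal="X1",
               tag_haulout=False):
    """Handcrafted fix stream helper (hours from an arbitrary origin)."""
    t0 = pd.Timestamp("2016-02-01")
    n = len(times_h)
    return pd.DataFrame({
        "id": animal,
        "time": [t0 + pd.Timedelta(hours=float(h)) for h in times_h],
        "lon": np.asarray(lons, dtype=float),
        "lat": np.asarray(lats, dtype=float),
        "n_sat": np.full(n, n_sat) if np.isscalar(n_sat) else np.asarray(n_sat),
        "residual": (np.full(n, residual) if np.isscalar(residual)
                     else np.asarray(residual)),
        "tag_haulout": (np.full(n, tag_haulout) if np.isscalar(tag_haulout)
                        else np.asarray(tag_haulout)),
    })
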