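import numpy as np
import pandas as pd
import pytest

from migvar.geo import ProjectionSpec
from migvar.synthetic import PopulationConfig, generate_population


@pytest.fixture(scope="session")
def proj():
    return ProjectionSpec(lon_0=2.0, lat_0=52.0)


@pytest.fixture(scope="session")
def small_population():
    """8 individuals spanning short to long migration distances, 2-3 years."""
    cfg = PopulationConfig(n_individuals=8, years_per_individual=(2, 3), seed=11)
    fixes, truth = generate_population(cfg)
    return cfg, fixes, truth


def make_fixes(x, y, start="2020-01-01", freq="1h"):
    """Projected fix frame from raw planar coordinates (test helper)."""
    x = np.asarray(x, dtype=float)
    ts = pd.date_range(start, periods=len(x), freq=freq, tz="UTC")
    return pd.DataFrame({"timestamp": ts, "x": x, "y": np.asarray(y, dtype=float)})
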