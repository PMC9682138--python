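import numpy as np
import pandas as pd
import pytest
import xarray as xr

import stabdim as sd


def grid(values, start="2000-01-01", freq="MS", name="series", units="1"):
    """Wrap a (pixel, time) array as the gridded container the package uses."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    time = pd.date_range(start, periods=values.shape[1], freq=freq)
    return xr.DataArray(
        values,
        dims=("pixel", "time"),
        coords={"pixel": np.arange(values.shape[0]), "time": time},
        name=name,
        attrs={"units": units},
    )


@pytest.fixture(scope="session")
def small_landscape():
    return sd.make_landscape(3, 2, 10, seed=1)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact two-period scenario shared by the slower integration tests."""
    return sd.generate_scenario(
        seed=7, n_counties=3, types_per_county=2, pixels_per_group=35
    )
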