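import numpy as np
import pandas as pd
import pytest

from foodshed import (
    LandCoverGrid,
    LandType,
    generate_consumption,
    load_default_conversion_table,
)
from foodshed.footprint import packaged_data


@pytest.fixture(scope="session")
def conversion_table():
    """The shipped table of printed conversion coefficients."""
    return load_default_conversion_table()


@pytest.fixture(scope="session")
def prd_profile():
    profile, _ = generate_consumption("prd_like")
    return profile


@pytest.fixture(scope="session")
def regional_results_table():
    """Printed per-city demand/radius/SSR table for the nine-city region."""
    with packaged_data("prd_regional_demand.csv").open() as fh:
        return pd.read_csv(fh)


def make_fraction_grid(
    n: int, cell_size_m: float, fraction: float, seed: int
) -> LandCoverGrid:
    """Random grid with an exact count of arable cells (rank assignment)."""
    rng = np.random.default_rng(seed)
    field = rng.random((n, n))
    k = int(round(fraction * n * n))
    codes = np.zeros(n * n, dtype=np.int8)
    codes[np.argsort(field.ravel())[:k]] = 1  # arable code
    return LandCoverGrid(codes.reshape(n, n), cell_size_m=cell_size_m)


def uniform_grid(n: int, cell_size_m: float, land_type=LandType.ARABLE):
    code = {LandType.ARABLE: 1, LandType.HORTICULTURAL: 2, LandType.WATERS: 3}[
        land_type
    ]
    return LandCoverGrid(
        np.full((n, n), code, dtype=np.int8), cell_size_m=cell_size_m
    )
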