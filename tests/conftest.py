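import numpy as np
import pytest

from marshca import ClassScheme, LandscapeGrid
from marshca import reference as R


@pytest.fixture
def scheme() -> ClassScheme:
    return R.YANCHENG_SCHEME


@pytest.fixture
def grid_factory(scheme):
    """Build a LandscapeGrid from a raw integer lattice with study defaults."""

    def make(values, date=1985, cell_size=30.0, baseline_edge="north", sch=None):
        return LandscapeGrid(
            values=np.asarray(values),
            cell_size=cell_size,
            date=date,
            scheme=sch or scheme,
            baseline_edge=baseline_edge,
        )

    return make


@pytest.fixture
def random_grid(scheme, grid_factory):
    """Seeded random map over the three dynamic marsh classes."""

    def make(rows=20, cols=20, seed=0, codes=(R.PHRAGMITES, R.SUAEDA, R.MUDFLAT),
             date=1985):
        rng = np.random.default_rng(seed)
        vals = rng.choice(codes, size=(rows, cols))
        return grid_factory(vals, date=date)

    return make
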