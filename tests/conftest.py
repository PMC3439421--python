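"""Shared fixtures: small grids and stacks built programmatically."""

import numpy as np
import pytest

from sdmsense import EnvStack, GridSpec


@pytest.fixture
def grid10() -> GridSpec:
    """A 10×10 planar grid with unit cells, north edge at y=10."""
    return GridSpec(n_rows=10, n_cols=10, x_origin=0.0, y_origin=10.0, cell_size=1.0)


@pytest.fixture
def stack10(grid10) -> EnvStack:
    """Two smooth deterministic layers on the 10×10 grid, fully valid."""
    r, c = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
    layer1 = (c - 4.5) / 4.5
    layer2 = (r - 4.5) / 4.5
    return EnvStack(
        grid=grid10,
        layer_names=["env1", "env2"],
        values=np.stack([layer1, layer2]).astype(float),
        valid_mask=np.ones((10, 10), dtype=bool),
    )
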