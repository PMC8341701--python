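import numpy as np
import pytest

import oxyvoxel as ov


@pytest.fixture(scope="session")
def params():
    """Published defaults (1 mm^2 voxel, 201x201 grid)."""
    return ov.default_params()


@pytest.fixture(scope="session")
def desk_params():
    """Reduced 400x400 um voxel (81x81 grid) for fast dynamic tests."""
    return ov.default_params(domain=(-200.0, 200.0, -200.0, 200.0))


@pytest.fixture(scope="session")
def desk_tissue(desk_params):
    """A relaxed mid-density tissue on the desk-scale voxel, with its masks
    and stationary field (shared across tests; treat as read-only)."""
    comp = ov.TissueComposition(3.5, 55, 30)
    layout = ov.resolve_overlaps(ov.sample_layout(comp, desk_params, seed=11),
                                 desk_params)
    masks = ov.build_indicator_masks(layout, desk_params)
    field, report = ov.stabilize(layout, desk_params, masks=masks)
    assert report.converged
    return layout, masks, field, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
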