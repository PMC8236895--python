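import numpy as np
import pytest

from aucseg import (
    CohortRanges,
    PhantomSpec,
    SegConfig,
    evaluate_case,
    generate_phantom,
    run_pipeline,
)
from aucseg.synthetic_data import TumorGeometry


@pytest.fixture(scope="session")
def phantom():
    """Standard one-tumor phantom at the default noise level."""
    return generate_phantom(PhantomSpec(noise_sd=0.02, seed=0))


@pytest.fixture(scope="session")
def noisefree_phantom():
    return generate_phantom(PhantomSpec(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def open_rim_phantom():
    """Phantom whose enhancing rim has a 30-degree gap: the failure mode
    of connected-component necrosis segmentation."""
    spec = PhantomSpec(tumors=(TumorGeometry(rim_gap_deg=30.0),), noise_sd=0.02, seed=1)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def two_tumor_phantom():
    """Two disjoint tumors along the z axis, with matching disjoint ROI boxes."""
    geom = dict(edema_radius=8.0, rim_outer_radius=6.0, rim_inner_radius=4.0)
    spec = PhantomSpec(
        tumors=(
            TumorGeometry(center=(16.0, 31.5, 31.5), **geom),
            TumorGeometry(center=(47.0, 31.5, 31.5), **geom),
        ),
        noise_sd=0.02,
        seed=2,
    )
    boxes = [(6, 26, 21, 42, 21, 42), (37, 57, 21, 42, 21, 42)]
    return generate_phantom(spec), boxes


@pytest.fixture(scope="session")
def default_run(phantom):
    """Default GMM pipeline output on the standard phantom."""
    case, truth, _ = phantom
    labels, masks = run_pipeline(case, SegConfig())
    metrics = {m.region: m for m in evaluate_case(labels, truth)}
    return labels, masks, metrics


def region_dice(labels, truth):
    return {m.region: m.dice for m in evaluate_case(labels, truth)}
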