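import numpy as np
import pytest

from flexsite import (
    DetectionConfig,
    FixtureSpec,
    detect_fields,
    find_sites,
    generate,
)
from flexsite.decision import run_pipeline


@pytest.fixture(scope="session")
def det_cfg():
    return DetectionConfig()


@pytest.fixture(scope="session")
def gated():
    """Gated-cavity fixture: (structure, truth)."""
    return generate(FixtureSpec(kind="gated_cavity"))


@pytest.fixture(scope="session")
def gated_detection(gated, det_cfg):
    s, _ = gated
    grid = detect_fields(s, det_cfg)
    return grid, find_sites(grid, det_cfg)


@pytest.fixture(scope="session")
def gated_pocket_site(gated, gated_detection):
    """The designed surface-pocket site (the fixture also carries a shallow
    surface groove where the open rotamer docks)."""
    import numpy as np

    _, truth = gated
    _, sites = gated_detection
    return min(
        sites,
        key=lambda s: float(np.linalg.norm(s.centroid - truth.mouth_center)),
    )


@pytest.fixture(scope="session")
def sphere5():
    return generate(FixtureSpec(kind="spherical_cavity", radius=5.0))


@pytest.fixture(scope="session")
def sphere5_detection(sphere5, det_cfg):
    s, _ = sphere5
    grid = detect_fields(s, det_cfg)
    return grid, find_sites(grid, det_cfg)


@pytest.fixture(scope="session")
def hemi5():
    return generate(FixtureSpec(kind="hemispherical_pocket", radius=5.0))


@pytest.fixture(scope="session")
def gated_records(gated):
    """Full pipeline on the gated fixture (the expensive end-to-end run)."""
    s, _ = gated
    return run_pipeline("gated_cavity", structure=s)


@pytest.fixture(scope="session")
def deep_records():
    s, truth = generate(FixtureSpec(kind="deep_pocket"))
    return run_pipeline("deep_pocket", structure=s), truth
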