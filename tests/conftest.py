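import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper module

from pefscan.architecture import TriadNodes
from pefscan.search_stats import calibrate
from pefscan.synthetic_fixtures import build_dii_fixture_model, build_motif_panel

PANEL_SEED = 7


@pytest.fixture(scope="session")
def ef_panel():
    """A calibrated five-model EF-hand panel (shared; building is the
    expensive part of most integration tests)."""
    return build_motif_panel(seed=PANEL_SEED)


@pytest.fixture(scope="session")
def dii_setup():
    """(model, calibration, consensus, TriadNodes) for a synthetic
    catalytic-domain profile with a C/H/N triad."""
    model, consensus, nodes = build_dii_fixture_model(seed=3)
    calib = calibrate(model, n_samples=1000, seed=301)
    return model, calib, consensus, TriadNodes(nodes=nodes)
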