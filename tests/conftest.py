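import numpy as np
import pytest

from methpanel import CallerConfig, QmspRecord, build_fixtures
from methpanel.simulate import CohortSpec, DiscoverySpec, generate_discovery_data


@pytest.fixture(scope="session")
def fixture_set():
    return build_fixtures()


@pytest.fixture()
def caller_config():
    return CallerConfig(marker_cutoffs={"Septin9": 38.0, "Epo": 38.0, "MT1A": 38.0})


@pytest.fixture()
def record():
    """A QC-valid record with one detected and one undetected marker."""
    return QmspRecord(
        sample_id="s1",
        group="ec_stage1",
        actb_ct=28.0,
        marker_cts={"Septin9": 30.0, "Epo": None, "MT1A": 40.0},
        cfdna_ng_ml=5.0,
    )


@pytest.fixture(scope="session")
def small_discovery():
    """A compact planted-signal discovery matrix shared across tests."""
    spec = DiscoverySpec(
        n_regions=200, n_dmr=5, n_tumor=30, n_adjacent=30, n_wbc=30,
        n_plasma_case=40, n_plasma_control=40, seed=11,
    )
    matrix, planted = generate_discovery_data(spec)
    return spec, matrix, planted
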