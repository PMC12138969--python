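import numpy as np
import pytest

from trstools.records import ToxicityRecord
from trstools.synthetic import write_fixture_suite


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """A full synthetic CSV suite plus config, written once per session."""
    root = tmp_path_factory.mktemp("suite")
    return write_fixture_suite(root, seed=7, noise_sd_log=0.15)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(**overrides) -> ToxicityRecord:
    base = dict(
        species_name="gammarus test",
        taxon_class="Malacostraca",
        phylum="Arthropoda",
        medium="freshwater",
        endpoint="LC50",
        effect_type="acute",
        concentration=100.0,
        duration=4.0,
        purity_pct=99.0,
        quality_pct=90.0,
        source_id="t1",
    )
    base.update(overrides)
    return ToxicityRecord(**base)
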