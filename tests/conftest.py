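import warnings

import pytest

from plastocomp.junctions import detect_inverted_repeat
from plastocomp.synthetic import SynthConfig, generate_plastome


@pytest.fixture(scope="session")
def small_setup():
    """A miniature quadripartite genome with the default planted content."""
    cfg = SynthConfig(lsc_len=12_000, irb_len=4_000, ssc_len=3_000, seed=2)
    record, truth = generate_plastome(cfg)
    return cfg, record, truth


@pytest.fixture(scope="session")
def small_record(small_setup):
    return small_setup[1]


@pytest.fixture(scope="session")
def small_truth(small_setup):
    return small_setup[2]


@pytest.fixture(scope="session")
def small_partition(small_record):
    return detect_inverted_repeat(small_record.sequence)


@pytest.fixture(autouse=True)
def _quiet_overlap_warnings():
    # IR-boundary-spanning genes legitimately overlap their mirror fragments
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="overlapping genes")
        yield
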