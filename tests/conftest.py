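import numpy as np
import pytest

import hifupwm as hp
from hifupwm.config import RunConfig
from hifupwm.pipeline import run_comparison


F0 = 1.1e6


@pytest.fixture(scope="session")
def transducer():
    return hp.TransducerModel()


@pytest.fixture(scope="session")
def water_stack():
    return hp.MediumStack((hp.Layer("water", 1482.0, 1000.0, 0.0, 2.0, 0.080),))


@pytest.fixture(scope="session")
def default_stack():
    return hp.MediumStack()


@pytest.fixture
def bilevel_waveform():
    return hp.synthesize(
        hp.ExcitationSpec(scheme="bilevel", sample_rate=F0 * 256, n_cycles=10)
    )


@pytest.fixture
def hrpwm_waveform():
    return hp.synthesize(
        hp.ExcitationSpec(scheme="hrpwm", modulation_index=0.70,
                          sample_rate=F0 * 256, n_cycles=10)
    )


@pytest.fixture(scope="session")
def comparison_report():
    """One full scaled-down (0.5 mm) three-scheme comparison, shared by the
    acceptance tests; ~10 s of compute."""
    return run_comparison(RunConfig())
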