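import numpy as np
import pytest

from somnoscope import (
    PATTERNS,
    EpochSynthesisParams,
    StagerConfig,
    build_model,
    make_canonical_template,
    refine_filter_bank,
)
from somnoscope.templates import default_refinement_specs

FS = 100.0
KERNEL_LEN = 100


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def refined_bank():
    bank = [make_canonical_template(p, FS, KERNEL_LEN / FS) for p in PATTERNS]
    return refine_filter_bank(bank, default_refinement_specs(KERNEL_LEN))


@pytest.fixture(scope="session")
def untrained_model(refined_bank):
    """Template-initialized stager; template filters are exact canonical
    kernels, free filters random from a fixed seed."""
    config = StagerConfig(n_template_filters=7, n_free_filters=3, kernel_len=KERNEL_LEN, seed=7)
    return build_model(config, refined_bank)


@pytest.fixture
def default_params():
    return EpochSynthesisParams()


@pytest.fixture
def clean_params():
    return EpochSynthesisParams(noise_sd=0.0)
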