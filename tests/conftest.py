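import dataclasses

import numpy as np
import pytest

from cmfp.synthetic import (
    ModalitySpec,
    SyntheticParams,
    default_ppmi_like_params,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default PPMI-like cohort draw, shared across tests."""
    cohort, truth = generate_cohort(default_ppmi_like_params(), seed=42)
    return cohort, truth


@pytest.fixture(scope="session")
def small_two_modal_cohort():
    """A small cohort with two complementary-signal modalities (w_s = 0)."""
    params = SyntheticParams(
        n=90,
        n_pos=54,
        shared_weight=0.0,
        modalities={
            "modA": ModalitySpec(8, 3, loading=1.0, private_weight=0.7),
            "modB": ModalitySpec(8, 3, loading=1.0, private_weight=0.7),
        },
    )
    cohort, truth = generate_cohort(params, seed=7)
    return cohort, truth


@pytest.fixture()
def complementary_params():
    """Default cohort shape with the shared risk component switched off."""
    return dataclasses.replace(default_ppmi_like_params(), shared_weight=0.0)
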