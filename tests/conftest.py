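import dataclasses

import pytest

from vitdmr.config import paper_like_config
from vitdmr.preprocess import log_transform_skewed
from vitdmr.synthetic import generate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = dataclasses.replace(
        paper_like_config(seed=7), n_subjects=600, exclusion_rates=(0.0, 0.0)
    )
    return generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    bundle, _ = small_bundle
    return log_transform_skewed(bundle.cohort)
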