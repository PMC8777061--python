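import numpy as np
import pandas as pd
import pytest

from gmqn import build_reference, compute_beta, normalize_pipeline
from gmqn.scenarios import reference_cohort


@pytest.fixture(scope="session")
def ref_cohort():
    """Clean 8-sample cohort used to fit the shared test reference."""
    return reference_cohort(6)


@pytest.fixture(scope="session")
def annotation(ref_cohort):
    return ref_cohort[1]


@pytest.fixture(scope="session")
def reference(ref_cohort):
    samples, ann, _ = ref_cohort
    return build_reference(samples, ann)


@pytest.fixture(scope="session")
def as_beta_matrix():
    """Callable building a probes x samples beta matrix for one pipeline arm."""

    def _build(samples, ann=None, ref=None, method=None):
        if method is None:
            cols = {s.sample_id: compute_beta(s).values for s in samples}
        else:
            cols = {
                s.sample_id: normalize_pipeline(s, ann, ref, method=method).values
                for s in samples
            }
        return pd.DataFrame(cols)

    return _build


@pytest.fixture
def tiny_annotation():
    return pd.DataFrame(
        {
            "design_type": ["I", "I", "II", "II"],
            "channel": ["red", "green", "none", "none"],
            "chromosome": ["chr1", "chr1", "chr2", "chr2"],
            "position": [100, 105, 500, 1500],
            "probe_cpg_count": [1, 2, 3, 1],
        },
        index=pd.Index(["cgA", "cgB", "cgC", "cgD"], name="probe_id"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
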